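"""Kinetic scheme, parameter conversions, and the analytic propagator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from hemekin import core
from hemekin.core import (
    ConformerMixture,
    MicroRates,
    PhenoParams,
    StateVector,
    deoxy_fraction,
    k_obs_saturation,
    micro_from_pheno,
    pheno_from_micro,
    propagate,
    slow_eigenvalue,
)
from hemekin.errors import LockedHexacoordinationError, NoGeminateChannelError

LJGLB11 = PhenoParams(k_on_co=1.2, k_on_h=67, k_off_h=27, f_gem=0.09, k_gem=9.2e7)

log_rate = st.floats(min_value=-2, max_value=8).map(lambda e: 10.0**e)


class TestConversions:
    def test_micro_from_pheno_ljglb11(self):
        m = micro_from_pheno(LJGLB11)
        assert m.k_gem_rebind == pytest.approx(8.28e6)
        assert m.k_escape == pytest.approx(8.372e7)
        assert m.k_solvent_rebind == pytest.approx(13.33, rel=1e-3)

    def test_no_escape_limit(self):
        m = micro_from_pheno(PhenoParams(k_on_co=5, k_on_h=1, k_off_h=1, f_gem=1.0, k_gem=1e7))
        assert m.k_gem_rebind == pytest.approx(1e7)
        assert m.k_escape == 0.0
        assert m.k_solvent_rebind == pytest.approx(5.0)
        p = pheno_from_micro(MicroRates(1, 0, m.k_solvent_rebind, 1, 1))
        assert p.k_on_co == pytest.approx(5.0)
        assert p.f_gem == 1.0

    def test_pheno_from_micro_matches_published_row(self):
        p = pheno_from_micro(MicroRates(8.28e6, 8.372e7, 13.33, 67, 27))
        assert p.k_on_co == pytest.approx(1.2, rel=1e-3)
        assert p.k_h == pytest.approx(2.48, abs=5e-3)
        assert p.f_h == pytest.approx(0.71, abs=5e-3)

    def test_his_pair_equilibrium(self):
        kh, fh = core.hexacoordination_summary(111, 57)
        assert kh == pytest.approx(1.95, abs=5e-3)
        assert fh == pytest.approx(0.66, abs=5e-3)

    def test_roundtrip_identity_on_all_rows(self, table1):
        for name, params in table1.items():
            comps = params.components if isinstance(params, ConformerMixture) else [(1.0, params)]
            for _, p in comps:
                p2 = pheno_from_micro(micro_from_pheno(p))
                for attr in ("k_on_co", "k_on_h", "k_off_h", "f_gem", "k_gem"):
                    assert getattr(p2, attr) == pytest.approx(getattr(p, attr), rel=1e-9), name

    def test_no_geminate_channel_error(self):
        with pytest.raises(NoGeminateChannelError):
            micro_from_pheno(PhenoParams(k_on_co=1.0, k_on_h=1, k_off_h=1, f_gem=0.0, k_gem=1e7))

    def test_locked_hexacoordination_error(self):
        p = PhenoParams(k_on_co=1.0, k_on_h=10.0, k_off_h=0.0, f_gem=0.1, k_gem=1e7)
        with pytest.raises(LockedHexacoordinationError):
            p.k_h


class TestKobs:
    def test_hand_evaluated_value(self):
        assert k_obs_saturation(1.2, 67, 27, 10) == pytest.approx(27 * 12 / 106)

    def test_zero_co(self):
        assert k_obs_saturation(5.0, 100, 10, 0.0) == 0.0

    def test_saturates_at_koff_h(self):
        assert k_obs_saturation(1.2, 67, 27, 1e9) == pytest.approx(27.0, rel=1e-5)

    def test_monotone_in_co_and_kon_h(self):
        co = np.linspace(1, 1000, 50)
        k = k_obs_saturation(1.2, 67, 27, co)
        assert np.all(np.diff(k) > 0)
        kon_h = np.linspace(1, 2000, 50)
        vals = [k_obs_saturation(1.2, kh, 27, 100) for kh in kon_h]
        assert np.all(np.diff(vals) < 0)

    def test_negative_co_rejected(self):
        with pytest.raises(ValueError):
            k_obs_saturation(1.2, 67, 27, -1.0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(k_on_co=st.floats(0.01, 100), k_on_h=log_rate, k_off_h=log_rate,
           co=st.floats(1, 1000))
    def test_det_trace_bounds_slow_eigenvalue(self, k_on_co, k_on_h, k_off_h, co):
        """The det/trace approximation never exceeds the exact slow rate."""
        approx = k_obs_saturation(k_on_co, k_on_h, k_off_h, co)
        exact = slow_eigenvalue(k_on_co, k_on_h, k_off_h, co)
        assert approx <= exact * (1 + 1e-12) + 1e-12


class TestStateVector:
    def test_sum_must_be_one(self):
        with pytest.raises(ValueError):
            StateVector(bound=0.5, docked=0.4)

    def test_his_equilibrium_populations(self):
        s = StateVector.his_equilibrium(LJGLB11)
        assert s.hexa == pytest.approx(LJGLB11.f_h)
        assert s.penta == pytest.approx(1 - LJGLB11.f_h)


class TestPropagate:
    def test_absorbing_state(self):
        pops = propagate(StateVector.all_docked(), LJGLB11, 200.0, np.geomspace(1e-9, 50, 200))
        assert pops["bound"][-1] == pytest.approx(1.0, abs=1e-9)
        assert deoxy_fraction(pops)[-1] == pytest.approx(0.0, abs=1e-9)

    def test_geminate_branching_fraction(self):
        """Rebinding during the geminate phase alone equals F_gem."""
        # ~30 geminate lifetimes, before any solvent rebinding matters
        t = np.array([30 / LJGLB11.k_gem])
        pops = propagate(StateVector.all_docked(), LJGLB11, 200.0, t)
        assert pops["bound"][0] == pytest.approx(LJGLB11.f_gem, rel=1e-3)

    @pytest.mark.parametrize("name,co", [("LjGlb1-1", 200.0), ("LjGlb1-2", 800.0),
                                         ("LjGlb1-1 C78S", 50.0)])
    def test_agrees_with_stiff_integrator(self, table1, name, co):
        """Eigen-solution matches an independent stiff ODE solve to 1e-6."""
        micro = core._as_micro_mixture(table1[name])[0][1]
        times = np.geomspace(1e-8, 10, 60)
        pops = propagate(StateVector.all_docked(), micro, co, times)
        M = core._rate_matrix(micro, co)
        sol = solve_ivp(lambda t, x: M @ x, (0, times[-1]), [0, 1, 0, 0],
                        t_eval=times, method="Radau", rtol=1e-10, atol=1e-13)
        for i, key in enumerate(("bound", "docked", "penta", "hexa")):
            assert np.abs(pops[key] - sol.y[i]).max() < 1e-6

    def test_mixture_is_weighted_sum(self, table1):
        mix = table1["LjGlb2"]
        times = np.geomspace(1e-8, 10, 100)
        pops = propagate(StateVector.all_docked(), mix, 200.0, times)
        parts = [propagate(StateVector.all_docked(), rates, 200.0, times)
                 for _, rates in mix.components]
        combined = sum(w * p["bound"] for (w, _), p in zip(mix.components, parts))
        np.testing.assert_allclose(pops["bound"], combined, atol=1e-12)

    def test_non_monotone_grid_rejected(self):
        with pytest.raises(ValueError):
            propagate(StateVector.all_docked(), LJGLB11, 200.0, [1e-6, 1e-7])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(k1=log_rate, k2=log_rate, km2=st.floats(0.01, 100),
           kon=log_rate, koff=log_rate, co=st.floats(1, 1000))
    def test_population_conservation(self, k1, k2, km2, kon, koff, co):
        """Populations sum to 1 to 1e-9 across ten decades of rates."""
        m = MicroRates(k1, k2, km2, kon, koff)
        times = np.geomspace(1e-9, 10, 40)
        pops = propagate(StateVector.all_docked(), m, co, times)
        total = pops["bound"] + pops["docked"] + pops["penta"] + pops["hexa"]
        assert np.abs(total - 1.0).max() < 1e-9
        for key in ("bound", "docked", "penta", "hexa"):
            assert np.all(pops[key] > -1e-9)


class TestMixtureContainer:
    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            ConformerMixture(components=((0.5, LJGLB11), (0.6, LJGLB11)))

    def test_shared_attribute_passthrough(self, table1):
        mix = table1["LjGlb1-2 C79S"]
        assert mix.f_gem == 0.46
        with pytest.raises(AttributeError):
            mix.k_on_h  # differs between conformers
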