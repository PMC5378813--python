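"""Multi-exponential fitting and phase classification on photolysis ladders."""

import numpy as np
import pytest

from hemekin import lfp, synth
from hemekin.core import PhenoParams
from hemekin.errors import AmbiguousAssignmentError, UnderdeterminedError
from hemekin.lfp import (
    ExpFitResult,
    classify_phases,
    estimate_geminate,
    estimate_kon_co,
    fit_multiexp,
)
from hemekin.synth import Trace, make_lfp_trace

CO_LADDER = (50, 100, 200, 300, 800)


def synthetic_exp_trace(amps, rates, t=None):
    if t is None:
        t = np.geomspace(1e-8, 10, 400)
    y = np.exp(-np.outer(t, np.asarray(rates))) @ np.asarray(amps)
    return Trace(kind="lfp", times=t, signal=y)


class TestFitMultiexp:
    def test_single_exponential_recovery(self):
        trace = synthetic_exp_trace([1.0], [100.0])
        fit = fit_multiexp(trace, 1)
        assert fit.rates[0] == pytest.approx(100.0, rel=1e-6)
        assert fit.amplitudes[0] == pytest.approx(1.0, rel=1e-6)

    def test_noiseless_residual_is_negligible(self):
        trace = make_lfp_trace(PhenoParams(1.2, 67, 27, 0.09, 9.2e7), 200.0)
        fit = fit_multiexp(trace, 3)
        assert fit.ssr < 1e-10  # signal scale is 1

    def test_fastest_rate_is_geminate_rate(self, table1):
        """At high [CO] the fastest fitted rate matches the published k_gem."""
        trace = make_lfp_trace(table1["LjGlb1-1"], 800.0)
        fit = fit_multiexp(trace, 3)
        assert fit.rates[0] == pytest.approx(9.2e7, rel=1e-3)

    def test_two_bimolecular_rates_for_two_conformers(self, table1):
        """LjGlb2's middle rates reflect its two CO association constants."""
        trace = make_lfp_trace(table1["LjGlb2"], 200.0)
        fit = fit_multiexp(trace, 4)
        ratio = fit.rates[1] / fit.rates[2]
        assert ratio == pytest.approx(10.71 / 3.79, rel=0.05)

    def test_ssr_non_increasing_in_components(self, table1):
        trace = make_lfp_trace(table1["LjGlb1-1"], 200.0)
        ssrs = [fit_multiexp(trace, n).ssr for n in (1, 2, 3)]
        assert ssrs[1] <= ssrs[0] * (1 + 1e-9) + 1e-25
        assert ssrs[2] <= ssrs[1] * (1 + 1e-9) + 1e-25

    def test_too_few_points_rejected(self):
        trace = synthetic_exp_trace([1.0], [100.0], t=np.geomspace(1e-6, 1, 20))
        with pytest.raises(ValueError):
            fit_multiexp(trace, 3)


def _ladder_fits(params, co_values=CO_LADDER, n=3):
    traces = [make_lfp_trace(params, c) for c in co_values]
    return [fit_multiexp(t, n) for t in traces]


class TestClassifyPhases:
    def test_three_phase_ladder(self, table1):
        fits = _ladder_fits(table1["LjGlb1-1"])
        assignment = classify_phases(fits, CO_LADDER)
        assert assignment.labels[0] == ["geminate", "bimolecular", "his_decay"]

    def test_two_conformer_ladder_has_two_bimolecular_phases(self, table1):
        co = (100, 300, 800)
        fits = _ladder_fits(table1["LjGlb2"], co, n=4)
        assignment = classify_phases(fits, co)
        assert assignment.labels[0] == [
            "geminate", "bimolecular", "bimolecular_2", "his_decay"]

    def test_spurious_constant_component_is_outlier(self):
        """A [CO]-independent mid component matching no phase is an impurity."""
        co = np.array([50.0, 100.0, 200.0, 400.0])
        fits = []
        for c in co:
            fits.append(ExpFitResult(
                amplitudes=np.array([0.1, 0.5, 0.05, 0.35]),
                rates=np.array([1e7, 10.0 * c, 5000.0, 67 * c / (c + 90)]),
                ssr=0.0, n_components=4,
            ))
        assignment = classify_phases(fits, co)
        labels = assignment.labels[0]
        assert labels[0] == "geminate"
        assert labels[-1] == "his_decay"
        assert "outlier" in labels

    def test_requires_three_concentrations(self, table1):
        fits = _ladder_fits(table1["LjGlb1-1"], (100, 200))
        with pytest.raises(UnderdeterminedError):
            classify_phases(fits, (100, 200))

    def test_non_invariant_fastest_component_raises(self):
        co = np.array([50.0, 100.0, 200.0])
        fits = [ExpFitResult(amplitudes=np.array([0.5, 0.5]),
                             rates=np.array([1e4 * c, 67 * c / (c + 90)]),
                             ssr=0.0, n_components=2) for c in co]
        with pytest.raises(AmbiguousAssignmentError):
            classify_phases(fits, co)


class TestKonCoEstimate:
    def test_exactly_proportional_rates(self):
        co = np.array([50.0, 100.0, 200.0, 400.0])
        fits = [ExpFitResult(amplitudes=np.array([0.1, 0.6, 0.3]),
                             rates=np.array([1e7, 5.0 * c, 67 * c / (c + 90)]),
                             ssr=0.0, n_components=3) for c in co]
        assignment = classify_phases(fits, co)
        est = estimate_kon_co(assignment, fits, co)
        assert est.slope == pytest.approx(5.0)
        assert est.intercept == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("name,expected", [("LjGlb1-1", 1.2), ("LjGlb1-2", 29.0)])
    def test_recovers_published_association_constant(self, table1, name, expected):
        fits = _ladder_fits(table1[name])
        assignment = classify_phases(fits, CO_LADDER)
        est = estimate_kon_co(assignment, fits, CO_LADDER)
        assert est.slope == pytest.approx(expected, rel=0.02)

    def test_noise_robust_median_recovery(self, table1):
        """Median k_on,CO across noisy replicates stays within 5% (bias check)."""
        slopes = []
        for seed in range(20):
            traces = [make_lfp_trace(table1["LjGlb1-1"], c, noise_sd=0.005, seed=seed * 10 + i)
                      for i, c in enumerate(CO_LADDER)]
            fits = [fit_multiexp(t, 3, n_starts=6) for t in traces]
            try:
                assignment = classify_phases(fits, CO_LADDER)
                slopes.append(estimate_kon_co(assignment, fits, CO_LADDER).slope)
            except AmbiguousAssignmentError:
                continue
        assert len(slopes) >= 15
        assert np.median(slopes) == pytest.approx(1.2, rel=0.05)


class TestGeminateEstimate:
    def test_full_geminate_rebinding(self):
        co = np.array([50.0, 100.0, 200.0])
        fits = [ExpFitResult(amplitudes=np.array([0.98, 0.01, 0.01]),
                             rates=np.array([1e7, 5.0 * c, 20 * c / (c + 90)]),
                             ssr=0.0, n_components=3) for c in co]
        assignment = classify_phases(fits, co)
        est = estimate_geminate(assignment, fits)
        assert est.f_gem == pytest.approx(0.98)
        assert est.k_gem == pytest.approx(1e7)

    @pytest.mark.parametrize("name,f_gem,k_gem", [
        ("LjGlb1-1", 0.09, 9.2e7),
        ("LjGlb1-2", 0.27, 7.6e7),
    ])
    def test_recovers_published_geminate_parameters(self, table1, name, f_gem, k_gem):
        fits = _ladder_fits(table1[name])
        assignment = classify_phases(fits, CO_LADDER)
        est = estimate_geminate(assignment, fits)
        assert est.f_gem == pytest.approx(f_gem, rel=0.01)
        assert est.k_gem == pytest.approx(k_gem, rel=0.01)

    def test_mutant_mixture_geminate_amplitude(self, table1):
        """The C79S mutant's geminate phase carries 46% of the rebinding."""
        fits = _ladder_fits(table1["LjGlb1-2 C79S"])
        assignment = classify_phases(fits, CO_LADDER)
        est = estimate_geminate(assignment, fits)
        assert est.f_gem == pytest.approx(0.46, rel=0.01)
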