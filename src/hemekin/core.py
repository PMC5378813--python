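"""Four-state CO-rebinding kinetics of hexacoordinate hemoglobins.

The scheme couples four species of a ferrous globin after photolysis of its
CO adduct::

    HbCO  <--k-1--  Hb:CO  --k2-->  Hb_p + CO  <--kon,H/koff,H-->  Hb_h
                      ^                 |
                      +---- k-2 [CO] ---+

``Hb:CO`` is the ligand parked in a docking site inside the protein matrix
(geminate rebinding with rate k_-1, escape to solvent with k_2), ``Hb_p`` is
the pentacoordinate deoxy protein that rebinds CO from solvent with the
bimolecular rate k_-2 (pseudo-first-order at fixed [CO]), and ``Hb_h`` is the
bis-histidyl hexacoordinate species formed and lost with k_on,H / k_off,H.

The phenomenological observables are related to the microscopic rates by

    k_on,CO = k_-2 k_-1 / (k_-1 + k_2)        (bimolecular CO association)
    F_gem   = k_-1 / (k_-1 + k_2)             (geminate amplitude fraction)
    k_gem   = k_-1 + k_2                      (apparent geminate rate)
    K_H     = k_on,H / k_off,H                (His coordination equilibrium)
    F_H     = K_H / (1 + K_H)                 (equilibrium 6c fraction)

and the apparent slow CO-binding rate after rapid mixing saturates as

    k_obs = k_off,H k_on,CO [CO] / (k_on,H + k_off,H + k_on,CO [CO]).

Units package-wide: time s, concentrations uM, first-order rates s^-1,
bimolecular rates uM^-1 s^-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
from scipy.linalg import expm

from .errors import LockedHexacoordinationError, NoGeminateChannelError

__all__ = [
    "MicroRates",
    "PhenoParams",
    "ConformerMixture",
    "StateVector",
    "micro_from_pheno",
    "pheno_from_micro",
    "k_obs_saturation",
    "slow_eigenvalue",
    "propagate",
    "deoxy_fraction",
    "ParamsLike",
]

#: relative gap below which eigenvalues are treated as degenerate
_DEGENERACY_RTOL = 1e-9
#: conservation error that triggers the expm fallback
_CONSERVATION_TOL = 1e-10


@dataclass(frozen=True)
class MicroRates:
    """Microscopic rate constants of the four-state scheme.

    Parameters
    ----------
    k_gem_rebind : float
        k_-1, geminate rebinding from the docking site, s^-1.
    k_escape : float
        k_2, ligand escape from the docking site to solvent, s^-1.
    k_solvent_rebind : float
        k_-2, bimolecular re-entry from solvent, uM^-1 s^-1.
    k_on_h, k_off_h : float
        Distal-His association / dissociation rates, s^-1.
    """

    k_gem_rebind: float
    k_escape: float
    k_solvent_rebind: float
    k_on_h: float
    k_off_h: float

    def __post_init__(self):
        for name in ("k_gem_rebind", "k_escape", "k_solvent_rebind", "k_on_h", "k_off_h"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.k_gem_rebind + self.k_escape <= 0:
            raise ValueError("k_gem_rebind + k_escape must be positive")


@dataclass(frozen=True)
class PhenoParams:
    """Phenomenological parameterization of a globin's CO kinetics.

    ``k_h`` (K_H) and ``f_h`` (F_H) are derived properties, so the identities
    K_H = k_on,H/k_off,H and F_H = K_H/(1+K_H) hold by construction.
    """

    k_on_co: float  # uM^-1 s^-1
    k_on_h: float  # s^-1
    k_off_h: float  # s^-1
    f_gem: float  # dimensionless, [0, 1]
    k_gem: float  # s^-1

    def __post_init__(self):
        if not 0.0 <= self.f_gem <= 1.0:
            raise ValueError(f"f_gem must be in [0, 1], got {self.f_gem}")
        for name in ("k_on_co", "k_on_h", "k_off_h", "k_gem"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def k_h(self) -> float:
        """His coordination equilibrium constant K_H = k_on,H / k_off,H."""
        if self.k_off_h == 0:
            raise LockedHexacoordinationError(
                "k_off,H = 0: fully locked hexacoordination, K_H undefined"
            )
        return self.k_on_h / self.k_off_h

    @property
    def f_h(self) -> float:
        """Equilibrium hexacoordinate fraction F_H = K_H / (1 + K_H)."""
        kh = self.k_h
        return kh / (1.0 + kh)

    @property
    def f_p(self) -> float:
        """Equilibrium pentacoordinate fraction, 1 - F_H."""
        return 1.0 - self.f_h


ParamsLike = Union[MicroRates, PhenoParams, "ConformerMixture"]


@dataclass(frozen=True)
class ConformerMixture:
    """Weighted mixture of independently reacting conformers.

    Proteins whose bimolecular phase needs two exponentials (two conformations
    coexisting in equilibrium, e.g. LjGlb2) are modeled as one or two
    non-interconverting components; the weight partitions the initial
    population. Components may be :class:`MicroRates` or :class:`PhenoParams`.

    Attributes shared by every component (e.g. ``f_gem`` when all conformers
    have the same geminate amplitude) are readable directly on the mixture.
    """

    components: tuple  # of (weight, MicroRates | PhenoParams)

    def __post_init__(self):
        comps = tuple((float(w), r) for w, r in self.components)
        object.__setattr__(self, "components", comps)
        if not 1 <= len(comps) <= 2:
            raise ValueError("mixture must have 1 or 2 components")
        weights = [w for w, _ in comps]
        if any(not 0.0 <= w <= 1.0 for w in weights):
            raise ValueError("weights must lie in [0, 1]")
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {sum(weights)}")

    @property
    def weights(self) -> tuple:
        return tuple(w for w, _ in self.components)

    def __getattr__(self, name):
        values = [getattr(rates, name) for _, rates in self.components]
        first = values[0]
        if all(v == first for v in values[1:]):
            return first
        raise AttributeError(
            f"'{name}' differs across conformers ({values}); access components directly"
        )


@dataclass(frozen=True)
class StateVector:
    """Populations of the four species (fractions summing to 1)."""

    bound: float = 0.0  # HbCO
    docked: float = 0.0  # Hb:CO
    penta: float = 0.0  # Hb_p
    hexa: float = 0.0  # Hb_h

    def __post_init__(self):
        vals = (self.bound, self.docked, self.penta, self.hexa)
        if any(not 0.0 <= v <= 1.0 for v in vals):
            raise ValueError(f"populations must lie in [0, 1], got {vals}")
        if abs(sum(vals) - 1.0) > 1e-9:
            raise ValueError(f"populations must sum to 1, got {sum(vals)}")

    @classmethod
    def all_docked(cls) -> "StateVector":
        """Post-photolysis initial condition (quantum yield 1)."""
        return cls(docked=1.0)

    @classmethod
    def his_equilibrium(cls, params: Union[PhenoParams, MicroRates]) -> "StateVector":
        """Deoxy protein equilibrated between 5c and 6c (pre-mixing state)."""
        if isinstance(params, MicroRates):
            kon, koff = params.k_on_h, params.k_off_h
        else:
            kon, koff = params.k_on_h, params.k_off_h
        if koff == 0:
            return cls(hexa=1.0)
        kh = kon / koff
        return cls(penta=1.0 / (1.0 + kh), hexa=kh / (1.0 + kh))

    def as_array(self) -> np.ndarray:
        return np.array([self.bound, self.docked, self.penta, self.hexa])


# ---------------------------------------------------------------------------
# parameter conversions
# ---------------------------------------------------------------------------

def micro_from_pheno(p: PhenoParams) -> MicroRates:
    """Invert the phenomenological parameterization to microscopic rates.

    k_-1 = F_gem k_gem, k_2 = (1 - F_gem) k_gem, k_-2 = k_on,CO / F_gem.
    """
    if p.f_gem == 0.0:
        if p.k_on_co > 0:
            raise NoGeminateChannelError(
                "F_gem = 0 with k_on,CO > 0: no geminate channel, k_-2 unidentifiable"
            )
        k_solvent = 0.0
    else:
        k_solvent = p.k_on_co / p.f_gem
    if p.k_gem <= 0:
        raise ValueError("k_gem must be positive to recover microscopic rates")
    return MicroRates(
        k_gem_rebind=p.f_gem * p.k_gem,
        k_escape=(1.0 - p.f_gem) * p.k_gem,
        k_solvent_rebind=k_solvent,
        k_on_h=p.k_on_h,
        k_off_h=p.k_off_h,
    )


def pheno_from_micro(m: MicroRates) -> PhenoParams:
    """Collapse microscopic rates to the phenomenological observables."""
    k_gem = m.k_gem_rebind + m.k_escape
    f_gem = m.k_gem_rebind / k_gem
    return PhenoParams(
        k_on_co=m.k_solvent_rebind * f_gem,
        k_on_h=m.k_on_h,
        k_off_h=m.k_off_h,
        f_gem=f_gem,
        k_gem=k_gem,
    )


def _as_micro_mixture(params: ParamsLike) -> list:
    """Normalize any parameter object to [(weight, MicroRates), ...]."""
    if isinstance(params, MicroRates):
        return [(1.0, params)]
    if isinstance(params, PhenoParams):
        return [(1.0, micro_from_pheno(params))]
    if isinstance(params, ConformerMixture):
        out = []
        for w, rates in params.components:
            if isinstance(rates, PhenoParams):
                rates = micro_from_pheno(rates)
            out.append((w, rates))
        return out
    raise TypeError(f"unsupported parameter object: {type(params)!r}")


# ---------------------------------------------------------------------------
# apparent rates
# ---------------------------------------------------------------------------

def k_obs_saturation(k_on_co: float, k_on_h: float, k_off_h: float, co: float):
    """Apparent slow CO-binding rate after rapid mixing.

    k_obs = k_off,H k_on,CO [CO] / (k_on,H + k_off,H + k_on,CO [CO]).
    Saturates at k_off,H for [CO] -> infinity; His dissociation becomes
    rate-limiting.  Accepts scalar or array [CO]; returns the same shape.
    """
    co = np.asarray(co, dtype=float)
    if np.any(co < 0):
        raise ValueError("[CO] must be >= 0")
    x = k_on_co * co
    denom = k_on_h + k_off_h + x
    if np.any(denom <= 0):
        raise ValueError("k_on,H + k_off,H + k_on,CO [CO] must be positive")
    out = k_off_h * x / denom
    return out if out.ndim else float(out)


def slow_eigenvalue(k_on_co: float, k_on_h: float, k_off_h: float, co: float) -> float:
    """Exact slow decay rate of the effective 2x2 rebind/hexacoordination system.

    The det/trace approximation (:func:`k_obs_saturation`) is a lower bound on this
    value for all parameter sets.
    """
    x = k_on_co * co
    tr = x + k_on_h + k_off_h
    det = x * k_off_h
    disc = tr * tr - 4.0 * det
    # cancellation-free root: 2 det / (tr + sqrt(disc))
    denom = tr + math.sqrt(max(disc, 0.0))
    return 2.0 * det / denom if denom > 0 else 0.0


# ---------------------------------------------------------------------------
# forward propagation
# ---------------------------------------------------------------------------

def _rate_matrix(m: MicroRates, co: float) -> np.ndarray:
    """Generator of the linear system, state order (bound, docked, penta, hexa)."""
    a = m.k_solvent_rebind * co
    kg = m.k_gem_rebind + m.k_escape
    return np.array(
        [
            [0.0, m.k_gem_rebind, 0.0, 0.0],
            [0.0, -kg, a, 0.0],
            [0.0, m.k_escape, -(a + m.k_on_h), m.k_off_h],
            [0.0, 0.0, m.k_on_h, -m.k_off_h],
        ]
    )


def _propagate_eigen(A: np.ndarray, d0: np.ndarray, times: np.ndarray):
    """Closed-form solution d(t) = V exp(L t) V^-1 d0, or None if ill-posed."""
    w, V = np.linalg.eig(A)
    if np.abs(w.imag).max() > 1e-9 * max(np.abs(w.real).max(), 1.0):
        return None
    w = w.real
    V = V.real
    # near-degenerate eigenvalues make V numerically defective
    if np.linalg.cond(V) > 1.0 / _DEGENERACY_RTOL:
        return None
    try:
        c = np.linalg.solve(V, d0)
    except np.linalg.LinAlgError:
        return None
    # exponents are <= 0 up to rounding; clip stray positives at rounding level
    w = np.minimum(w, 0.0)
    return V @ (c[:, None] * np.exp(np.outer(w, times)))


def _propagate_expm(A: np.ndarray, d0: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Matrix-exponential fallback, exact for the linear system (slower)."""
    X = np.empty((A.shape[0], times.size))
    for j, t in enumerate(times):
        X[:, j] = expm(A * t) @ d0
    return X


def propagate(
    s0: StateVector,
    params: ParamsLike,
    co: float,
    times: Sequence[float],
) -> dict:
    """Propagate state populations at fixed [CO] (pseudo-first-order contract).

    Solves the linear kinetics analytically by eigen-decomposition of the
    4x4 generator (the system is stiff: rates span ~10 decades, so
    time-stepping is avoided).  Conformers of a mixture propagate
    independently from the same initial condition and are weight-summed.

    Returns a dict with keys ``times, bound, docked, penta, hexa`` (ndarrays).
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise ValueError("times must be a non-empty 1-D grid")
    if np.any(times < 0) or np.any(np.diff(times) <= 0):
        raise ValueError("times must be non-negative and strictly increasing")
    if co < 0:
        raise ValueError("[CO] must be >= 0")

    x0 = s0.as_array()
    total = np.zeros((4, times.size))
    for weight, micro in _as_micro_mixture(params):
        # the bound state is absorbing (zero column), so the deoxy block
        # evolves autonomously and bound is its exact complement
        A = _rate_matrix(micro, co)[1:, 1:]
        D = _propagate_eigen(A, x0[1:], times)
        if D is None or np.abs(D.sum(axis=0)).max() > x0.sum() + _CONSERVATION_TOL:
            D = _propagate_expm(A, x0[1:], times)
        X = np.vstack([x0.sum() - D.sum(axis=0), D])
        total += weight * X
    return {
        "times": times,
        "bound": total[0],
        "docked": total[1],
        "penta": total[2],
        "hexa": total[3],
    }


def deoxy_fraction(populations: dict) -> np.ndarray:
    """Fraction of deoxy molecules: everything not CO-bound (docked + 5c + 6c).

    This is the quantity monitored optically in flash photolysis (normalized
    absorption change at the deoxy Soret band).
    """
    return populations["docked"] + populations["penta"] + populations["hexa"]


def hexacoordination_summary(k_on_h: float, k_off_h: float) -> tuple:
    """(K_H, F_H) from the His association/dissociation rate pair."""
    if k_off_h == 0:
        raise LockedHexacoordinationError("k_off,H = 0: locked 6c state")
    kh = k_on_h / k_off_h
    return kh, kh / (1.0 + kh)
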