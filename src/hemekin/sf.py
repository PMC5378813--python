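"""Stopped-flow analysis: biexponential CO-binding fits and the k_obs([CO])
saturation fit.

After rapid mixing of deoxy protein with CO, the pentacoordinate fraction
binds in a fast bimolecular step (rate k_on,CO [CO]) while the hexacoordinate
fraction must first release the distal His, giving a slow phase whose
apparent rate saturates at k_off,H:

    dA(t)  = -A_T (F_P e^{-k_on,CO [CO] t} + F_H e^{-k_obs t})
    k_obs  = k_off,H k_on,CO [CO] / (k_on,H + k_off,H + k_on,CO [CO])

Per-[CO] traces are fitted with the biexponential (F_P + F_H = 1 enforced;
it is implied by the total amplitude at t = 0), then the (k_obs, [CO]) pairs
are fitted with the saturation expression holding k_on,CO fixed at the
flash-photolysis value, yielding k_on,H and k_off,H with standard errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import lmfit
import numpy as np

from . import core
from .core import hexacoordination_summary  # re-exported module surface
from .errors import (
    UnderdeterminedError,
    UnidentifiableParameterWarning,
    UnresolvablePhasesWarning,
)
from .synth import Trace

__all__ = [
    "SfPoint",
    "HexaSummary",
    "fit_biexponential",
    "fit_kobs_saturation",
    "hexacoordination_summary",
]


@dataclass
class SfPoint:
    """Biexponential fit of one stopped-flow trace."""

    co_uM: float
    k_fast: float  # s^-1, carries k_on,CO [CO]
    k_obs: float  # s^-1, slow 6c-limited phase
    f_p: float  # pentacoordinate fraction
    f_h: float  # hexacoordinate fraction (1 - f_p)
    a_t: float  # total absorbance change, AU
    ssr: float = 0.0
    degenerate: bool = False  # phases not separable (near-equal rates or f_p ~ 0/1)


def _biexp_model(t, a_t, f_p, k_fast, k_obs):
    return -a_t * (f_p * np.exp(-k_fast * t) + (1.0 - f_p) * np.exp(-k_obs * t))


def fit_biexponential(
    trace: Trace,
    f_sum_constrained: bool = True,
    ratio_starts: Sequence[float] = (3.0, 10.0, 100.0, 1000.0),
) -> SfPoint:
    """Fit the biexponential binding model to a stopped-flow trace.

    The two fractions are constrained to sum to one by default (set
    ``f_sum_constrained=False`` to fit them independently, in which case
    ``f_p`` is the fitted fast fraction of the total amplitude).  The faster
    rate is always reported as ``k_fast``.  If the two rates come out within
    10% of each other the phases are not resolvable and the point is flagged
    (with a warning).
    """
    if trace.kind != "stopped_flow":
        raise ValueError("fit_biexponential expects a stopped-flow trace")
    if trace.co_uM is None:
        raise ValueError("trace must carry its [CO]")
    t = trace.times - trace.times[0]
    y = trace.signal
    scale = max(abs(y[0]), abs(y).max())

    # slow-rate guess from the tail's log-linear decay
    tail = slice(len(t) // 2, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        logy = np.log(np.abs(y[tail]))
    ok = np.isfinite(logy)
    k_slow0 = 1.0
    if ok.sum() > 2:
        slope = np.polyfit(t[tail][ok], logy[ok], 1)[0]
        if slope < 0:
            k_slow0 = -slope

    best = None
    for ratio in ratio_starts:
        params = lmfit.Parameters()
        params.add("a_t", value=scale, min=1e-12 * scale)
        params.add("f_p", value=0.5, min=0.0, max=1.0)
        params.add("k_obs", value=k_slow0, min=1e-12)
        params.add("ratio", value=ratio, min=1.0 + 1e-9)
        params.add("k_fast", expr="k_obs * ratio")
        if not f_sum_constrained:
            params.add("f_h_free", value=0.5, min=0.0, max=2.0)

        def resid(p):
            if f_sum_constrained:
                return _biexp_model(t, p["a_t"], p["f_p"], p["k_fast"], p["k_obs"]) - y
            model = -p["a_t"] * (
                p["f_p"] * np.exp(-p["k_fast"] * t)
                + p["f_h_free"] * np.exp(-p["k_obs"] * t)
            )
            return model - y

        try:
            out = lmfit.minimize(resid, params, method="leastsq", xtol=1e-15, ftol=1e-15)
        except Exception:
            continue
        if best is None or out.chisqr < best.chisqr:
            best = out
    if best is None:
        raise UnderdeterminedError("biexponential fit failed from all starts")

    p = best.params
    k_fast, k_obs = float(p["k_fast"]), float(p["k_obs"])
    f_p = float(p["f_p"])
    f_h = 1.0 - f_p if f_sum_constrained else float(p["f_h_free"])
    degenerate = False
    if k_fast < 1.1 * k_obs:
        degenerate = True
        warnings.warn(
            f"fast/slow rates within 10% ({k_fast:.4g} vs {k_obs:.4g}); "
            "phases not resolvable",
            UnresolvablePhasesWarning,
            stacklevel=2,
        )
    if min(f_p, f_h) < 1e-3:
        degenerate = True  # effectively single-exponential
    return SfPoint(
        co_uM=trace.co_uM,
        k_fast=k_fast,
        k_obs=k_obs,
        f_p=f_p,
        f_h=f_h,
        a_t=float(p["a_t"]),
        ssr=float(best.chisqr),
        degenerate=degenerate,
    )


@dataclass
class HexaSummary:
    """Hexacoordination parameters from the k_obs([CO]) saturation fit."""

    k_on_h: float
    k_off_h: float
    k_h: float
    f_h: float
    k_on_h_se: float = np.nan
    k_off_h_se: float = np.nan
    k_h_se: float = np.nan
    f_h_se: float = np.nan


def fit_kobs_saturation(points: Sequence[SfPoint], k_on_co_fixed: float) -> HexaSummary:
    """Fit the k_obs saturation curve with k_on,CO held at the photolysis value.

    Nonlinear least squares over the (co, k_obs) pairs with k_on,H and
    k_off,H free; K_H and F_H are derived with first-order propagated
    standard errors (covariance included).  A relative standard error above
    100% on k_off,H indicates a non-saturating dataset and triggers a
    warning.
    """
    co = np.array([pt.co_uM for pt in points], dtype=float)
    kobs = np.array([pt.k_obs for pt in points], dtype=float)
    if len(set(co.tolist())) < 3:
        raise UnderdeterminedError("need >= 3 distinct [CO] values to fit the saturation curve")
    if k_on_co_fixed <= 0:
        raise ValueError("k_on_co_fixed must be positive")

    x = k_on_co_fixed * co
    koff0 = 1.05 * kobs.max()
    # invert the model at the median point for a k_on,H starting value
    i = len(co) // 2
    kon0 = max(x[i] * koff0 / max(kobs[i], 1e-12) - x[i] - koff0, 1e-3)

    params = lmfit.Parameters()
    params.add("k_on_h", value=kon0, min=0.0)
    params.add("k_off_h", value=koff0, min=1e-12)

    def resid(p):
        return core.k_obs_saturation(k_on_co_fixed, p["k_on_h"], p["k_off_h"], co) - kobs

    out = lmfit.minimize(resid, params, method="leastsq", xtol=1e-15, ftol=1e-15)
    kon = float(out.params["k_on_h"])
    koff = float(out.params["k_off_h"])
    se_on = out.params["k_on_h"].stderr or np.nan
    se_off = out.params["k_off_h"].stderr or np.nan
    if np.isfinite(se_off) and se_off > koff:
        warnings.warn(
            "k_off,H standard error exceeds its value: k_obs does not "
            "saturate over this [CO] range",
            UnidentifiableParameterWarning,
            stacklevel=2,
        )

    kh = kon / koff
    fh = kh / (1.0 + kh)
    kh_se = fh_se = np.nan
    if out.covar is not None and out.covar.shape == (2, 2):
        grad = np.array([1.0 / koff, -kon / koff**2])
        var = float(grad @ out.covar @ grad)
        kh_se = np.sqrt(max(var, 0.0))
        fh_se = kh_se / (1.0 + kh) ** 2
    return HexaSummary(
        k_on_h=kon, k_off_h=koff, k_h=kh, f_h=fh,
        k_on_h_se=float(se_on), k_off_h_se=float(se_off),
        k_h_se=kh_se, f_h_se=fh_se,
    )
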