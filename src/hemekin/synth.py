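"""Synthetic trace generation for the three experiment kinds.

Emulates (a) laser-flash-photolysis CO-rebinding traces over many decades of
time at several CO concentrations, (b) 2-second stopped-flow absorbance
relaxations, and (c) NO-electrode consumption traces with a donor release
phase followed by globin-driven consumption.  Every generator is
deterministic given its seed, and noiseless output matches the analytic
kinetics exactly, so the downstream fitting stages are testable end to end
without any instrument data.
"""

from __future__ import annotations

import importlib.resources
import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import yaml

from . import core
from .core import ConformerMixture, ParamsLike, PhenoParams, StateVector

__all__ = [
    "Trace",
    "NodAssayConfig",
    "default_lfp_grid",
    "make_lfp_trace",
    "make_sf_trace",
    "make_nod_trace",
    "table1_fixtures",
    "write_trace_csv",
    "read_trace_csv",
]

TRACE_KINDS = ("lfp", "stopped_flow", "nod")

#: default additive noise, as a fraction of full scale (no noise level is
#: published for the reference experiments; this is a stand-in)
DEFAULT_NOISE_SD = 0.005


@dataclass
class Trace:
    """A time-signal series with experiment metadata.

    ``signal`` holds deoxy fraction (lfp), delta-absorbance at 414 nm
    (stopped_flow) or [NO] in uM (nod).
    """

    kind: str
    times: np.ndarray  # s
    signal: np.ndarray
    co_uM: Optional[float] = None
    noise_sd: float = 0.0
    seed: Optional[int] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in TRACE_KINDS:
            raise ValueError(f"kind must be one of {TRACE_KINDS}, got {self.kind!r}")
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.times.shape != self.signal.shape or self.times.ndim != 1:
            raise ValueError("times and signal must be 1-D arrays of equal length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def default_lfp_grid(t_min: float = 1e-8, t_max: float = 10.0, per_decade: int = 60) -> np.ndarray:
    """Log-spaced time grid spanning the photolysis experiment's dynamic range."""
    n_dec = np.log10(t_max / t_min)
    n = int(round(n_dec * per_decade)) + 1
    return np.geomspace(t_min, t_max, n)


def _add_noise(signal: np.ndarray, noise_sd: float, seed: Optional[int]) -> np.ndarray:
    if noise_sd == 0:
        return signal
    rng = np.random.default_rng(seed)
    return signal + rng.normal(0.0, noise_sd, size=signal.shape)


def make_lfp_trace(
    params: ParamsLike,
    co: float,
    grid: Optional[np.ndarray] = None,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
) -> Trace:
    """Simulate a flash-photolysis rebinding trace (deoxy fraction vs time).

    All molecules start in the docked state (photolysis quantum yield 1);
    i.i.d. Gaussian noise of standard deviation ``noise_sd`` is added.
    """
    if grid is None:
        grid = default_lfp_grid()
    pops = core.propagate(StateVector.all_docked(), params, co, grid)
    signal = core.deoxy_fraction(pops)
    return Trace(
        kind="lfp",
        times=grid,
        signal=_add_noise(signal, noise_sd, seed),
        co_uM=co,
        noise_sd=noise_sd,
        seed=seed,
    )


def _sf_model_signal(params: ParamsLike, co: float, times: np.ndarray, a_t: float) -> np.ndarray:
    """Biexponential stopped-flow model: fast 5c binding + slow 6c-limited binding.

    dA(t) = -A_T (F_P e^{-k_on,CO [CO] t} + F_H e^{-k_obs t}), with k_obs the
    saturating apparent rate; conformers are weight-summed.
    """
    if isinstance(params, ConformerMixture):
        comps = [(w, r if isinstance(r, PhenoParams) else core.pheno_from_micro(r))
                 for w, r in params.components]
    else:
        p = params if isinstance(params, PhenoParams) else core.pheno_from_micro(params)
        comps = [(1.0, p)]
    signal = np.zeros_like(times)
    for w, p in comps:
        k_fast = p.k_on_co * co
        k_obs = core.k_obs_saturation(p.k_on_co, p.k_on_h, p.k_off_h, co)
        signal += w * (p.f_p * np.exp(-k_fast * times) + p.f_h * np.exp(-k_obs * times))
    return -a_t * signal


def make_sf_trace(
    params: ParamsLike,
    co: float,
    duration: float = 2.0,
    a_t: float = 0.1,
    dead_time: float = 0.0,
    n_points: int = 1000,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
    full_scheme: bool = False,
) -> Trace:
    """Simulate a stopped-flow absorbance relaxation after rapid CO mixing.

    By default the trace follows the biexponential model form exactly, so
    model-matched round trips through the stopped-flow fitter are exact.
    ``full_scheme=True`` instead propagates the four-state scheme from the
    His-coordination equilibrium, for robustness studies of the det/trace
    approximation behind the apparent-rate expression.
    """
    if not duration > dead_time >= 0:
        raise ValueError("need duration > dead_time >= 0")
    times = np.linspace(dead_time, duration, n_points)
    if full_scheme:
        micro = core._as_micro_mixture(params)
        signal = np.zeros_like(times)
        for w, m in micro:
            s0 = StateVector.his_equilibrium(m)
            pops = core.propagate(s0, m, co, times)
            signal += w * core.deoxy_fraction(pops)
        signal = -a_t * signal
    else:
        signal = _sf_model_signal(params, co, times, a_t)
    return Trace(
        kind="stopped_flow",
        times=times,
        signal=_add_noise(signal, noise_sd, seed),
        co_uM=co,
        noise_sd=noise_sd,
        seed=seed,
        meta={"a_t": a_t, "dead_time": dead_time, "full_scheme": full_scheme},
    )


@dataclass
class NodAssayConfig:
    """NO-consumption assay layout: donor release, plateau, then Hb addition.

    The donor releases NO linearly for ``release_duration`` seconds up to
    ``plateau_no`` (about 6 uM for DEA, 2 uM for GSNO); at ``t_add`` the
    oxyferrous globin (``hb_conc``) is added and NO decays pseudo-first-order
    with rate k_nod * [Hb].  Ferric protein has no dioxygenase activity, so
    ``ferric=True`` leaves the plateau flat.
    """

    donor: str = "DEA"
    release_duration: float = 240.0  # s
    plateau_no: Optional[float] = None  # uM; donor-dependent default
    hb_conc: float = 1.0  # uM
    t_add: float = 300.0  # s
    k_nod: float = 0.1  # uM^-1 s^-1, effective electrode-scale constant
    ferric: bool = False

    def __post_init__(self):
        if self.donor not in ("DEA", "GSNO"):
            raise ValueError("donor must be 'DEA' or 'GSNO'")
        if self.plateau_no is None:
            self.plateau_no = 6.0 if self.donor == "DEA" else 2.0
        for name in ("release_duration", "plateau_no", "hb_conc", "k_nod"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.t_add < self.release_duration:
            warnings.warn(
                "Hb added before NO release has stabilized; initial-rate "
                "estimates will mix release and consumption",
                UserWarning,
                stacklevel=2,
            )


def make_nod_trace(
    cfg: NodAssayConfig,
    grid: Optional[np.ndarray] = None,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
) -> Trace:
    """Simulate an NO-electrode trace for the dioxygenase assay.

    The consuming globin is treated as not depleted (oxyferrous Hb in excess
    relative to the NO consumed on the observation window).
    """
    if grid is None:
        # 5 Hz electrode sampling, 5 min of consumption after addition
        span = cfg.t_add + 300.0
        grid = np.linspace(0.0, span, int(span * 5) + 1)
    grid = np.asarray(grid, dtype=float)
    rise = np.minimum(grid / cfg.release_duration, 1.0) if cfg.release_duration > 0 else 1.0
    signal = cfg.plateau_no * np.asarray(rise, dtype=float) * np.ones_like(grid)
    k = 0.0 if cfg.ferric else cfg.k_nod * cfg.hb_conc
    after = grid >= cfg.t_add
    signal[after] = signal[after] * np.exp(-k * (grid[after] - cfg.t_add))
    return Trace(
        kind="nod",
        times=grid,
        signal=_add_noise(signal, noise_sd, seed),
        noise_sd=noise_sd,
        seed=seed,
        meta={
            "donor": cfg.donor,
            "t_add": cfg.t_add,
            "hb_conc": cfg.hb_conc,
            "k_nod": cfg.k_nod,
            "ferric": cfg.ferric,
            "plateau_no": cfg.plateau_no,
        },
    )


# ---------------------------------------------------------------------------
# bundled parameter sets
# ---------------------------------------------------------------------------

def _entry_to_params(entry: dict):
    keys = ("k_on_co", "k_on_h", "k_off_h", "f_gem", "k_gem")
    if "conformers" in entry:
        comps = tuple(
            (c["weight"], PhenoParams(**{k: float(c[k]) for k in keys}))
            for c in entry["conformers"]
        )
        return ConformerMixture(components=comps)
    return PhenoParams(**{k: float(entry[k]) for k in keys})


def table1_fixtures(path: Optional[Union[str, Path]] = None) -> dict:
    """Published rate constants of the six globins, keyed by protein name.

    Returns :class:`PhenoParams` for single-conformer proteins and
    :class:`ConformerMixture` for LjGlb1-2 C79S (equal weights, the split is
    not published) and LjGlb2 (70%/30%).
    """
    if path is None:
        ref = importlib.resources.files("hemekin").joinpath("data/table1.yaml")
        raw = yaml.safe_load(ref.read_text())
    else:
        raw = yaml.safe_load(Path(path).read_text())
    return {name: _entry_to_params(entry) for name, entry in raw.items()}


def table1_reported(path: Optional[Union[str, Path]] = None) -> dict:
    """Published K_H / F_H values as printed, for consistency checks.

    Maps protein name to a ``reported`` dict, or a list of per-conformer
    dicts for the two-conformer proteins.
    """
    if path is None:
        ref = importlib.resources.files("hemekin").joinpath("data/table1.yaml")
        raw = yaml.safe_load(ref.read_text())
    else:
        raw = yaml.safe_load(Path(path).read_text())
    out = {}
    for name, entry in raw.items():
        if "conformers" in entry:
            out[name] = [c["reported"] for c in entry["conformers"]]
        else:
            out[name] = entry["reported"]
    return out


# ---------------------------------------------------------------------------
# CSV round trip
# ---------------------------------------------------------------------------

_META_FIELDS = ("kind", "co_uM", "noise_sd", "seed")


def write_trace_csv(trace: Trace, path: Union[str, Path]) -> None:
    """Write a trace with a comment-prefixed metadata header.

    Floats are written with repr precision so the round trip is exact.
    """
    buf = io.StringIO()
    buf.write(f"# kind={trace.kind}\n")
    if trace.co_uM is not None:
        buf.write(f"# co_uM={trace.co_uM!r}\n")
    buf.write(f"# noise_sd={trace.noise_sd!r}\n")
    if trace.seed is not None:
        buf.write(f"# seed={trace.seed}\n")
    for key, value in sorted(trace.meta.items()):
        buf.write(f"# meta.{key}={value!r}\n")
    buf.write("time_s,signal\n")
    for t, y in zip(trace.times, trace.signal):
        buf.write(f"{float(t)!r},{float(y)!r}\n")
    Path(path).write_text(buf.getvalue())


def _parse_meta_value(text: str):
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            pass
    if text in ("True", "False"):
        return text == "True"
    return text.strip("'\"")


def read_trace_csv(path: Union[str, Path]) -> Trace:
    """Read a trace written by :func:`write_trace_csv`."""
    header: dict = {}
    meta: dict = {}
    times, signal = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line.lstrip("# ").partition("=")
                if key.startswith("meta."):
                    meta[key[5:]] = _parse_meta_value(value)
                else:
                    header[key] = value
            elif not line.startswith("time_s"):
                t, _, y = line.partition(",")
                times.append(float(t))
                signal.append(float(y))
    return Trace(
        kind=header.get("kind", "lfp"),
        times=np.array(times),
        signal=np.array(signal),
        co_uM=float(header["co_uM"]) if "co_uM" in header else None,
        noise_sd=float(header.get("noise_sd", 0.0)),
        seed=int(header["seed"]) if "seed" in header else None,
        meta=meta,
    )
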