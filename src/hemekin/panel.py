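"""Cross-globin comparisons: predicted apparent CO-binding rates and the
k_on,H vs k_off,H correlation across class 1 non-symbiotic hemoglobins.

The regression of k_on,H on k_off,H through the origin interprets its slope
as an aggregate His-coordination equilibrium constant K_H for the family.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd
from scipy import stats

from . import core
from .errors import UnderdeterminedError

__all__ = ["GlobinPanel", "PanelRegression", "predict_kobs_panel", "regress_kon_koff"]

PANEL_COLUMNS = ["name", "k_on_co", "k_on_h", "k_off_h", "source"]


@dataclass
class GlobinPanel:
    """Table of globins with their three CO-binding rate constants.

    Backed by a pandas DataFrame with columns
    ``name, k_on_co, k_on_h, k_off_h, source``.  Literature entries for
    non-Lotus globins are user-supplied (their values live in the cited
    papers); :meth:`template` gives an empty frame to populate.
    """

    table: pd.DataFrame

    def __post_init__(self):
        df = pd.DataFrame(self.table)
        missing = [c for c in PANEL_COLUMNS[:-1] if c not in df.columns]
        if missing:
            raise ValueError(f"panel missing columns {missing}")
        if "source" not in df.columns:
            df["source"] = ""
        if df["name"].duplicated().any():
            raise ValueError("panel names must be unique")
        for col in ("k_on_co", "k_on_h", "k_off_h"):
            if (df[col] <= 0).any():
                raise ValueError(f"{col} must be positive for every row")
        self.table = df[PANEL_COLUMNS].reset_index(drop=True)

    @classmethod
    def from_records(cls, records: Iterable[Union[dict, tuple]]) -> "GlobinPanel":
        rows = []
        for rec in records:
            if isinstance(rec, dict):
                rows.append(rec)
            else:
                rows.append(dict(zip(PANEL_COLUMNS, rec)))
        return cls(pd.DataFrame(rows))

    @classmethod
    def template(cls) -> pd.DataFrame:
        """Empty literature-panel template (populate and pass to the constructor)."""
        return pd.DataFrame(columns=PANEL_COLUMNS)

    def __len__(self):
        return len(self.table)


@dataclass
class PanelRegression:
    """k_on,H ~ k_off,H regression summary; the slope is an aggregate K_H."""

    slope: float
    slope_se: float
    r: float  # Pearson correlation of the rate pair
    intercept: float = 0.0
    through_origin: bool = True


def predict_kobs_panel(panel: GlobinPanel, co: float) -> pd.DataFrame:
    """Apparent CO-binding rate for every panel member at the given [CO].

    Returns a DataFrame (name, k_obs) sorted by k_obs descending.
    """
    df = panel.table.copy()
    df["k_obs"] = [
        core.k_obs_saturation(r.k_on_co, r.k_on_h, r.k_off_h, co) for r in df.itertuples()
    ]
    return df[["name", "k_obs"]].sort_values("k_obs", ascending=False).reset_index(drop=True)


def regress_kon_koff(panel: GlobinPanel, through_origin: bool = True) -> PanelRegression:
    """Least-squares regression of k_on,H on k_off,H across the panel.

    Through the origin by default, since the slope is read as an equilibrium
    constant; set ``through_origin=False`` for the intercept-allowed fit.
    The Pearson correlation is reported either way.
    """
    if len(panel) < 3:
        raise UnderdeterminedError("need >= 3 panel rows for the regression")
    x = panel.table["k_off_h"].to_numpy(dtype=float)
    y = panel.table["k_on_h"].to_numpy(dtype=float)
    r = stats.pearsonr(x, y)[0]
    if through_origin:
        slope = float(x @ y / (x @ x))
        resid = y - slope * x
        dof = len(x) - 1
        slope_se = float(np.sqrt((resid @ resid) / dof / (x @ x)))
        return PanelRegression(slope=slope, slope_se=slope_se, r=r)
    lin = stats.linregress(x, y)
    return PanelRegression(
        slope=lin.slope, slope_se=lin.stderr, r=r,
        intercept=lin.intercept, through_origin=False,
    )
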