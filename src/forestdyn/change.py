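"""Annualized, standardized, composite and acceleration statistics of change.

Change between two censuses is expressed per plot as the average annual
difference of each indicator.  For mapping, changes are standardized by the
maximum absolute plot-level change of each indicator, so the strongest change
has magnitude 1 while signs are preserved.  Composite change averages the
standardized changes of a group of indicators (structure or composition).
With three censuses, the acceleration of change is the landscape-mean annual
change of the second period minus that of the first; positive values mean
the indicator is changing faster in the later period.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .indicators import COMPOSITION_INDICATORS, INDICATORS, STRUCTURE_INDICATORS
from .inventory import InventoryDataset

__all__ = [
    "annualized_change",
    "standardize_changes",
    "composite_change",
    "acceleration_summary",
    "elevation_stratified_summary",
]

GROUPS = {"structure": list(STRUCTURE_INDICATORS), "composition": list(COMPOSITION_INDICATORS)}


def annualized_change(indicators: pd.DataFrame, dataset: InventoryDataset,
                      census_a: str, census_b: str) -> pd.DataFrame:
    """Per-plot (value_b - value_a) / (year_b - year_a) for every indicator.

    ``indicators`` is the (plot_id, census_id)-indexed indicator table.
    """
    year_a = dataset.census_year(census_a)
    year_b = dataset.census_year(census_b)
    if year_b == year_a:
        raise ZeroDivisionError(f"censuses {census_a} and {census_b} share the year {year_a}")
    a = indicators.xs(census_a, level="census_id")
    b = indicators.xs(census_b, level="census_id")
    return (b - a) / (year_b - year_a)


def standardize_changes(changes: pd.DataFrame) -> pd.DataFrame:
    """Divide each indicator's changes by its maximum absolute change across plots.

    An indicator with no change anywhere is left as zeros.
    """
    out = changes.copy()
    for col in out.columns:
        m = out[col].abs().max()
        if m > 0:
            out[col] = out[col] / m
    return out


def composite_change(standardized: pd.DataFrame, group: str) -> pd.Series:
    """Per-plot mean of one group's standardized changes (hot-spot composite)."""
    if group not in GROUPS:
        raise KeyError(f"unknown indicator group {group!r}; expected one of {sorted(GROUPS)}")
    return standardized[GROUPS[group]].mean(axis=1)


def acceleration_summary(indicators: pd.DataFrame, dataset: InventoryDataset) -> pd.DataFrame:
    """Landscape-level change-rate table for a three-census dataset.

    Columns: mean and SD of the per-plot annual change in each period, their
    difference (period2 - period1; positive = acceleration), the difference
    of absolute mean rates, and each period's mean annual change relative to
    the landscape-mean indicator value at the first census (% per year).
    """
    if len(dataset.census_years) != 3:
        raise ValueError("acceleration requires exactly 3 censuses")
    c1, c2, c3 = dataset.census_ids
    p1 = annualized_change(indicators, dataset, c1, c2)
    p2 = annualized_change(indicators, dataset, c2, c3)
    baseline = indicators.xs(c1, level="census_id").mean()
    rows = []
    for ind in INDICATORS:
        m1, m2 = p1[ind].mean(), p2[ind].mean()
        rows.append({
            "indicator": ind,
            "mean_change_p1": m1,
            "sd_change_p1": p1[ind].std(ddof=1),
            "mean_change_p2": m2,
            "sd_change_p2": p2[ind].std(ddof=1),
            "difference": m2 - m1,
            "abs_rate_difference": abs(m2) - abs(m1),
            "relative_change_p1_pct": 100.0 * m1 / baseline[ind] if baseline[ind] else np.nan,
            "relative_change_p2_pct": 100.0 * m2 / baseline[ind] if baseline[ind] else np.nan,
        })
    return pd.DataFrame(rows).set_index("indicator")


def elevation_stratified_summary(changes: pd.DataFrame, plots: pd.DataFrame,
                                 threshold_m: float = 1400.0) -> pd.DataFrame:
    """Mean change below/above an elevation threshold and their difference.

    The 1400 m default separates montane from subalpine forest.  An empty
    stratum yields NaN means and an undefined (NaN) difference.
    """
    elev = plots.set_index("plot_id")["elevation_m"].reindex(changes.index)
    below = changes[elev < threshold_m]
    above = changes[elev >= threshold_m]
    out = pd.DataFrame({
        "mean_below": below.mean(),
        "mean_above": above.mean(),
        "n_below": len(below),
        "n_above": len(above),
    })
    out["difference"] = out["mean_below"] - out["mean_above"]
    return out
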