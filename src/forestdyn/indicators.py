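"""Plot-level indicators of forest structure and composition.

Four structural indicators — basal area (m2 ha-1), stand density (n ha-1),
density of large trees (dbh > 50 cm, n ha-1), and the expansion-weighted
standard deviation of dbh (cm) — and five compositional ones: the basal-area
shares (%) of conifers and of early-seral, late-seral and rare species, plus
the effective species number (Hill number of order 1, the exponential of
Shannon entropy of basal-area proportions).

All quantities are per-hectare via the per-tree expansion factor, so mixed
plot designs are handled uniformly.  An empty plot-census yields zeros
(including an effective species number of 0, the natural empty-set limit).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .inventory import InventoryDataset

__all__ = [
    "STRUCTURE_INDICATORS",
    "COMPOSITION_INDICATORS",
    "INDICATORS",
    "basal_area_per_tree",
    "structure_indicators",
    "composition_indicators",
    "indicator_table",
]

LARGE_TREE_DBH_CM = 50.0  # strict: dbh > 50 counts

STRUCTURE_INDICATORS = ("basal_area", "stand_density", "large_trees", "sd_dbh")
COMPOSITION_INDICATORS = (
    "conifer_share",
    "early_seral_share",
    "late_seral_share",
    "rare_seral_share",
    "effective_species_n",
)
INDICATORS = STRUCTURE_INDICATORS + COMPOSITION_INDICATORS


def basal_area_per_tree(dbh_cm: np.ndarray) -> np.ndarray:
    """Cross-sectional stem area in m2 for dbh in cm: pi * (dbh/200)^2."""
    return np.pi * (np.asarray(dbh_cm, dtype=float) / 200.0) ** 2


def structure_indicators(dbh_cm, expansion_factor) -> dict:
    """Structural indicators for the trees of one plot-census."""
    dbh = np.asarray(dbh_cm, dtype=float)
    w = np.asarray(expansion_factor, dtype=float)
    if (w <= 0).any():
        raise ValueError("expansion factors must be positive")
    if dbh.size == 0:
        return {k: 0.0 for k in STRUCTURE_INDICATORS}
    density = float(w.sum())
    basal_area = float((w * basal_area_per_tree(dbh)).sum())
    large = float(w[dbh > LARGE_TREE_DBH_CM].sum())
    mean_dbh = float((w * dbh).sum() / density)
    sd_dbh = float(np.sqrt((w * (dbh - mean_dbh) ** 2).sum() / density))
    return {
        "basal_area": basal_area,
        "stand_density": density,
        "large_trees": large,
        "sd_dbh": sd_dbh,
    }


def composition_indicators(dbh_cm, expansion_factor, species_code, species: pd.DataFrame) -> dict:
    """Compositional indicators (basal-area based) for one plot-census.

    ``species`` is the trait table indexed by species_code with columns
    ``conifer`` (bool) and ``seral_class``.
    """
    dbh = np.asarray(dbh_cm, dtype=float)
    w = np.asarray(expansion_factor, dtype=float)
    codes = pd.Index(species_code)
    if dbh.size == 0:
        return {k: 0.0 for k in COMPOSITION_INDICATORS}
    unknown = set(codes) - set(species.index)
    if unknown:
        raise KeyError(f"species code(s) missing from the trait table: {sorted(unknown)}")
    ba = w * basal_area_per_tree(dbh)
    total = ba.sum()
    traits = species.loc[codes]
    conifer = ba[traits["conifer"].to_numpy()].sum()
    seral = traits["seral_class"].to_numpy()
    shares = {
        "conifer_share": 100.0 * conifer / total,
        "early_seral_share": 100.0 * ba[seral == "early"].sum() / total,
        "late_seral_share": 100.0 * ba[seral == "late"].sum() / total,
        "rare_seral_share": 100.0 * ba[seral == "rare"].sum() / total,
    }
    by_species = pd.Series(ba).groupby(codes).sum()
    p = (by_species / total).to_numpy()
    p = p[p > 0]
    shannon = float(-(p * np.log(p)).sum())
    shares["effective_species_n"] = float(np.exp(shannon))
    return {k: float(v) for k, v in shares.items()}


def indicator_table(dataset: InventoryDataset) -> pd.DataFrame:
    """All nine indicators for every (plot, census), empty plot-censuses included.

    Returns a DataFrame indexed by (plot_id, census_id).
    """
    index = pd.MultiIndex.from_product(
        [dataset.plots["plot_id"], dataset.census_ids], names=["plot_id", "census_id"]
    )
    out = pd.DataFrame(0.0, index=index, columns=list(INDICATORS))
    for (plot, census), grp in dataset.trees.groupby(["plot_id", "census_id"], sort=False):
        row = structure_indicators(grp["dbh_cm"], grp["expansion_factor"])
        row.update(
            composition_indicators(
                grp["dbh_cm"], grp["expansion_factor"], grp["species_code"], dataset.species
            )
        )
        out.loc[(plot, census)] = pd.Series(row)
    return out
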