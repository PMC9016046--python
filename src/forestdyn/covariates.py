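"""Candidate drivers of forest change: legacy, disturbance, climate and site.

Builds the 30-covariate driver table, one row per (plot, period):

* legacy (4): development stage (8-class stand-in classifier), total basal
  area, dominant (90th-percentile) tree age, and divergence from the
  potential natural vegetation (PNV) — all dated at the period's first census;
* disturbance (2): management zone and per-period disturbance occurrence;
* climate (15): period anomalies of mean daily temperature, daily
  precipitation and daily solar radiation for the four meteorological seasons
  (DJF/MAM/JJA/SON) and annually, each relative to the full-record mean;
* site (9): elevation, aspect class, and the 3x3-neighborhood terrain indices
  roughness (max - min of the 9 cells), TRI (mean absolute elevation
  difference to the 8 neighbors) and TPI (elevation minus neighbor mean),
  plus sand and clay fractions, effective soil depth and soil type.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import RasterGrid
from .indicators import basal_area_per_tree, structure_indicators
from .inventory import InventoryDataset

__all__ = [
    "ClimateSeries",
    "TerrainIndices",
    "terrain_indices",
    "climate_anomalies",
    "legacy_covariates",
    "assemble_driver_table",
    "DRIVER_COLUMNS",
    "DRIVER_CATEGORIES",
    "DEVELOPMENT_STAGES",
]

CLIMATE_VARS = ("tmean", "psum", "rad")
SEASON_MONTHS = {
    "winter": (12, 1, 2),
    "spring": (3, 4, 5),
    "summer": (6, 7, 8),
    "autumn": (9, 10, 11),
}
CLIMATE_COLUMNS = [
    f"{var}_{season}" for var in CLIMATE_VARS for season in (*SEASON_MONTHS, "annual")
]

LEGACY_COLUMNS = ["development_stage", "total_basal_area", "stand_age", "pnv_divergence"]
DISTURBANCE_COLUMNS = ["management_zone", "disturbance_occurrence"]
SITE_COLUMNS = [
    "elevation", "aspect_class", "roughness", "tri", "tpi",
    "sand", "clay", "soil_depth", "soil_type",
]
DRIVER_COLUMNS = LEGACY_COLUMNS + DISTURBANCE_COLUMNS + CLIMATE_COLUMNS + SITE_COLUMNS

DRIVER_CATEGORIES = {
    **{c: "legacy" for c in LEGACY_COLUMNS},
    **{c: "disturbance" for c in DISTURBANCE_COLUMNS},
    **{c: "climate" for c in CLIMATE_COLUMNS},
    **{c: "site" for c in SITE_COLUMNS},
}

DEVELOPMENT_STAGES = (
    "gap_regeneration", "establishment", "early_optimum", "mid_optimum",
    "late_optimum", "plenter", "terminal", "decay",
)

# quadratic-mean-dbh bands (cm), stem-density floor (n/ha) and dbh coefficient
# of variation used by the stand-in development-stage classifier
STAGE_THRESHOLDS = {
    "min_density": 50.0,
    "qmd_establishment": 15.0,
    "qmd_early": 25.0,
    "qmd_mid": 35.0,
    "qmd_late": 45.0,
    "cv_plenter": 0.55,
    "density_decay": 150.0,
}


@dataclass
class ClimateSeries:
    """Daily climate per plot: arrays shaped (n_plots, n_days)."""

    plot_ids: list
    dates: pd.DatetimeIndex
    tmean: np.ndarray
    precip: np.ndarray
    rad: np.ndarray

    def __post_init__(self) -> None:
        n = (len(self.plot_ids), len(self.dates))
        for name in ("tmean", "precip", "rad"):
            arr = getattr(self, name)
            if arr.shape != n:
                raise ValueError(f"{name} has shape {arr.shape}, expected {n}")

    def to_frame(self) -> pd.DataFrame:
        """Long-format (plot_id, date, tmean, precip, rad) table."""
        n_p, n_d = len(self.plot_ids), len(self.dates)
        return pd.DataFrame({
            "plot_id": np.repeat(self.plot_ids, n_d),
            "date": np.tile(self.dates, n_p),
            "tmean": self.tmean.ravel(),
            "precip": self.precip.ravel(),
            "rad": self.rad.ravel(),
        })


@dataclass
class TerrainIndices:
    roughness: RasterGrid
    tri: RasterGrid
    tpi: RasterGrid
    aspect_class: np.ndarray  # string lattice shaped like the DEM


def _neighbor_stack(values: np.ndarray) -> np.ndarray:
    """3-D stack of the 8 neighbor lattices, NaN beyond the border."""
    padded = np.full((values.shape[0] + 2, values.shape[1] + 2), np.nan)
    padded[1:-1, 1:-1] = values
    shifts = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]
    return np.stack([
        padded[1 + di:padded.shape[0] - 1 + di, 1 + dj:padded.shape[1] - 1 + dj]
        for di, dj in shifts
    ])


def terrain_indices(dem: RasterGrid, flat_slope: float = 1e-6) -> TerrainIndices:
    """Roughness, TRI, TPI and aspect class from a DEM.

    Indices use the 3x3 neighborhood; border cells fall back to the neighbors
    that exist.  Aspect is the compass direction of steepest descent,
    discretized into the 8 cardinal/intercardinal classes, or ``flat`` when
    the slope magnitude is below ``flat_slope`` (m/m).
    """
    if dem.nrows < 3 or dem.ncols < 3:
        raise ValueError("terrain indices require a DEM of at least 3 x 3 cells")
    z = dem.values
    neigh = _neighbor_stack(z)
    with np.errstate(invalid="ignore"):
        nmax = np.fmax(np.nanmax(neigh, axis=0), z)
        nmin = np.fmin(np.nanmin(neigh, axis=0), z)
        roughness = nmax - nmin
        tri = np.nanmean(np.abs(neigh - z), axis=0)
        tpi = z - np.nanmean(neigh, axis=0)

    # steepest descent: rows run north->south, so d/drow = -d/dy
    dz_drow, dz_dcol = np.gradient(z, dem.cellsize_m)
    east, north = -dz_dcol, dz_drow
    slope = np.hypot(east, north)
    bearing = np.degrees(np.arctan2(east, north)) % 360.0
    classes = np.array(["N", "NE", "E", "SE", "S", "SW", "W", "NW"])
    aspect = classes[(np.round(bearing / 45.0).astype(int)) % 8].astype(object)
    aspect[slope < flat_slope] = "flat"

    def _grid(v):
        return RasterGrid(v, dem.xll_m, dem.yll_m, dem.cellsize_m, dem.nodata_value)

    return TerrainIndices(_grid(roughness), _grid(tri), _grid(tpi), aspect)


def _season_of(months: np.ndarray) -> dict[str, np.ndarray]:
    masks = {s: np.isin(months, m) for s, m in SEASON_MONTHS.items()}
    masks["annual"] = np.ones_like(months, dtype=bool)
    return masks


def climate_anomalies(series: ClimateSeries, census_years) -> pd.DataFrame:
    """Seasonal and annual climate anomalies per plot and period.

    A period spans the calendar years from one census year up to (excluding)
    the next; the reference span covers all years between the first and last
    census.  The anomaly is the period's mean daily value minus the reference
    mean, so day-count-weighted anomalies sum to zero over the periods.
    """
    years = list(census_years)
    y0, y_end = years[0], years[-1]
    dates = series.dates
    expected = pd.date_range(f"{y0}-01-01", f"{y_end - 1}-12-31", freq="D")
    missing = expected.difference(dates)
    if len(missing) > 0:
        raise ValueError(
            f"daily series does not cover the reference span; {len(missing)} missing "
            f"date(s) starting at {missing[0].date()}"
        )
    sel = dates.isin(expected)
    months = np.asarray(dates.month)
    yrs = np.asarray(dates.year)
    season_masks = _season_of(months)
    ref_mask = sel.copy()

    rows = []
    for p_idx, (ya, yb) in enumerate(zip(years[:-1], years[1:]), start=1):
        period_mask = sel & (yrs >= ya) & (yrs < yb)
        row = {}
        for var in CLIMATE_VARS:
            arr = getattr(series, {"tmean": "tmean", "psum": "precip", "rad": "rad"}[var])
            for season, smask in season_masks.items():
                pm = period_mask & smask
                rm = ref_mask & smask
                row[f"{var}_{season}"] = arr[:, pm].mean(axis=1) - arr[:, rm].mean(axis=1)
        df = pd.DataFrame(row, index=pd.Index(series.plot_ids, name="plot_id"))
        df["period"] = f"p{p_idx}"
        rows.append(df)
    out = pd.concat(rows).set_index("period", append=True)
    return out[CLIMATE_COLUMNS]


def _weighted_percentile_nearest_rank(values: np.ndarray, weights: np.ndarray, q: float) -> float:
    """Nearest-rank percentile of a weighted empirical distribution."""
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cum = np.cumsum(w)
    target = q * cum[-1]
    return float(v[np.searchsorted(cum, target)])


def classify_development_stage(dbh_cm, expansion_factor, thresholds=STAGE_THRESHOLDS) -> str:
    """Simplified 8-stage stand-development classifier.

    Approximates the classical development-stage typology from quadratic mean
    diameter (QMD) bands, stem density, and the dbh coefficient of variation
    (high variation in mature stands -> plenter/uneven-aged).  This is a
    documented stand-in, not a reimplementation of any published decision tree.
    """
    dbh = np.asarray(dbh_cm, dtype=float)
    w = np.asarray(expansion_factor, dtype=float)
    t = thresholds
    if dbh.size == 0 or w.sum() < t["min_density"]:
        return "gap_regeneration"
    density = w.sum()
    qmd = float(np.sqrt((w * dbh ** 2).sum() / density))
    mean_dbh = (w * dbh).sum() / density
    cv = float(np.sqrt((w * (dbh - mean_dbh) ** 2).sum() / density) / mean_dbh)
    if qmd < t["qmd_establishment"]:
        return "establishment"
    if cv > t["cv_plenter"] and qmd >= t["qmd_early"]:
        return "plenter"
    if qmd < t["qmd_early"]:
        return "early_optimum"
    if qmd < t["qmd_mid"]:
        return "mid_optimum"
    if qmd < t["qmd_late"]:
        return "late_optimum"
    return "terminal" if density >= t["density_decay"] else "decay"


def legacy_covariates(dataset: InventoryDataset, census_id: str) -> pd.DataFrame:
    """Legacy covariates per plot, valued at one census.

    stand_age is the nearest-rank 90th percentile of expansion-weighted tree
    ages; pnv_divergence (%) is max(0, (0.5 - s) / 0.5) * 100 with s the
    basal-area share of the plot's PNV-dominant species, so a stand meeting
    the 50% expectation scores 0 and total PNV absence scores 100.  Treeless
    plots score stage gap_regeneration, age 0 and divergence 100.
    """
    trees = dataset.trees[dataset.trees["census_id"] == census_id]
    pnv = dataset.plots.set_index("plot_id")["pnv_dominants"].astype(str).str.split(";").apply(set)
    rows = {}
    grouped = dict(tuple(trees.groupby("plot_id", sort=False)))
    for plot_id in dataset.plots["plot_id"]:
        grp = grouped.get(plot_id)
        if grp is None or len(grp) == 0:
            rows[plot_id] = {
                "development_stage": "gap_regeneration",
                "total_basal_area": 0.0, "stand_age": 0.0, "pnv_divergence": 100.0,
            }
            continue
        dbh = grp["dbh_cm"].to_numpy()
        w = grp["expansion_factor"].to_numpy(dtype=float)
        ba = w * basal_area_per_tree(dbh)
        has_age = grp["age_years"].notna().to_numpy()
        if has_age.any():
            age = _weighted_percentile_nearest_rank(
                grp["age_years"].to_numpy(dtype=float)[has_age], w[has_age], 0.9
            )
        else:
            age = 0.0
        share = ba[grp["species_code"].isin(pnv.loc[plot_id]).to_numpy()].sum() / ba.sum()
        rows[plot_id] = {
            "development_stage": classify_development_stage(dbh, w),
            "total_basal_area": structure_indicators(dbh, w)["basal_area"],
            "stand_age": age,
            "pnv_divergence": max(0.0, (0.5 - share) / 0.5) * 100.0,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "plot_id"
    return out


def assemble_driver_table(dataset: InventoryDataset, terrain: TerrainIndices,
                          anomalies: pd.DataFrame, dem: RasterGrid) -> pd.DataFrame:
    """Join the four driver groups into the 30-column (plot, period) table.

    Legacy covariates are valued at each period's first census; site
    covariates are static; disturbance occurrence is the plot's per-period
    flag.  Raises if any component leaves missing values behind.
    """
    plots = dataset.plots.set_index("plot_id")
    x, y = plots["x_m"].to_numpy(), plots["y_m"].to_numpy()
    site = pd.DataFrame({
        "elevation": plots["elevation_m"],
        "aspect_class": plots["aspect_class"],
        "roughness": terrain.roughness.sample(x, y),
        "tri": terrain.tri.sample(x, y),
        "tpi": terrain.tpi.sample(x, y),
        "sand": plots["sand_pct"],
        "clay": plots["clay_pct"],
        "soil_depth": plots["soil_depth_cm"],
        "soil_type": plots["soil_type"],
    }, index=plots.index)

    n_periods = len(dataset.census_years) - 1
    frames = []
    for p in range(1, n_periods + 1):
        period = f"p{p}"
        legacy = legacy_covariates(dataset, dataset.census_ids[p - 1])
        dist = pd.DataFrame({
            "management_zone": plots["zone"],
            "disturbance_occurrence": plots[f"disturbed_p{p}"].astype(bool),
        }, index=plots.index)
        clim = anomalies.xs(period, level="period")
        df = pd.concat([legacy, dist, clim, site], axis=1)
        df["period"] = period
        frames.append(df)
    out = pd.concat(frames).set_index("period", append=True)
    out = out[DRIVER_COLUMNS]
    if out.isna().any().any():
        bad = out.columns[out.isna().any()].tolist()
        raise ValueError(f"driver table has missing values in column(s): {bad}")
    return out
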