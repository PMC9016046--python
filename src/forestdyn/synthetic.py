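"""Synthetic mountain landscape and three-census inventory with known truth.

Generates a virtual calcareous-Alps-like landscape — smooth random terrain,
spatially autocorrelated soil fields, elevation-banded potential natural
vegetation — places permanent plots on a 200 x 100 m grid below the
timberline, synthesizes daily plot climate with an elevational lapse rate and
a prescribed warming step between the two inter-census periods, and runs a
simple annual demographic simulation (growth, mortality, recruitment) whose
rates respond positively to temperature anomalies and are dampened by stand
basal area.  Every imposed effect is recorded in :class:`SyntheticTruth`, so
downstream estimators can be checked against known ground truth.

The simulator is a statistical fixture generator, not an ecological model:
it reproduces the *structure* real inventories exhibit (spatial
autocorrelation, driver effects, accelerating change), not calibrated
demography of any real forest.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage

from .covariates import ClimateSeries, terrain_indices
from .grids import RasterGrid

__all__ = [
    "SyntheticTruth",
    "LandscapeBundle",
    "SimulationParams",
    "SPECIES_TABLE",
    "generate_terrain",
    "place_plots",
    "generate_climate",
    "simulate_inventory",
    "generate_scene",
]

CENSUS_YEARS = (1984, 1996, 2011)

# 8-species pool: conifers (spruce/fir/larch/stone-pine analogues) and
# broadleaves, with early/late/rare seral labels
SPECIES_TABLE = pd.DataFrame(
    {
        "conifer": [True, True, True, True, False, False, False, False],
        "seral_class": ["late", "late", "early", "rare", "late", "other", "early", "rare"],
    },
    index=pd.Index(["PA", "AA", "LD", "PC", "FS", "AC", "SA", "UG"], name="species_code"),
)

SOIL_TYPES = ("rendzina", "poor_brown", "rich_brown", "gleyic")

# species-specific growth response to a +1 degC temperature anomaly (on the
# log scale, before scaling by truth.conifer_temp_effect): warming shifts the
# competitive balance toward (late/rare) broadleaves and away from conifers
# and early-seral species
SPECIES_TEMP_SENSITIVITY = {
    "PA": -0.4, "AA": 0.0, "LD": -0.7, "PC": -0.1,
    "FS": 0.7, "AC": 0.3, "SA": -0.4, "UG": 0.9,
}


@dataclass
class SyntheticTruth:
    """Effects imposed by the simulator, recorded exactly as used."""

    seed: int
    temp_effect: float = 2.0            # growth/recruitment multiplier exp(temp_effect * T anomaly)
    legacy_damping: float = 0.8         # multiplier exp(-legacy_damping * BA / 40 m2/ha)
    conifer_temp_effect: float = 2.0    # scale of the per-species growth sensitivity to warming
    elevation_conifer_gradient: float = 1.0  # logit of conifer recruit share per 150 m elevation
    warming_step: float = 0.21          # degC, second period minus first period mean temperature
    census_years: tuple = CENSUS_YEARS
    field_variograms: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class LandscapeBundle:
    dem: RasterGrid
    sand: RasterGrid
    clay: RasterGrid
    soil_depth: RasterGrid
    soil_type: np.ndarray   # string lattice shaped like the DEM
    pnv: np.ndarray         # per-cell frozenset of PNV-dominant species codes
    truth: SyntheticTruth
    plots: pd.DataFrame | None = None


@dataclass
class SimulationParams:
    """Demographic rate constants of the annual simulator (free parameters)."""

    initial_density_mean: float = 22.0   # trees per 500 m2 plot at the first census
    growth_rate_cm: float = 0.55         # baseline annual dbh increment, cm
    growth_noise_cm: float = 0.06
    mortality_rate: float = 0.004        # baseline annual mortality probability
    mortality_density: float = 0.008     # added at BA = 60 m2/ha
    disturbance_kill_frac: float = 0.35  # fraction killed in a disturbed plot's event year
    recruitment_rate: float = 0.55       # baseline recruits per plot per year
    recruit_cap_cm: float = 10.0         # recruits enter with dbh in [6, cap]
    ba_ref: float = 40.0                 # m2/ha scale of the legacy damping term
    expansion_factor: float = 20.0       # 500 m2 plots
    burn_in_years: int = 15              # pre-census spin-up to demographic quasi-equilibrium


def _correlated_field(shape, sigma_cells: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian random field from smoothed white noise.

    Smoothing white noise with a Gaussian kernel of scale ``sigma_cells``
    yields a Gaussian-family variogram with range 2 * sigma_cells cells.
    """
    noise = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(noise, sigma_cells, mode="reflect")
    return (f - f.mean()) / f.std()


def pnv_for_elevation(elev_m: float) -> frozenset:
    """Elevation-banded PNV dominants: beech low, mixed montane, conifer subalpine."""
    if elev_m < 900:
        return frozenset({"FS"})
    if elev_m < 1400:
        return frozenset({"PA", "FS", "AA"})
    return frozenset({"PA", "LD", "PC"})


def generate_terrain(extent_m=(3600.0, 1800.0), seed: int = 0, cellsize_m: float = 10.0,
                     elevation_range=(600.0, 2100.0), n_bumps: int = 24,
                     soil_range_m: float = 400.0) -> LandscapeBundle:
    """Random smooth terrain with correlated soil fields and a PNV map.

    The DEM is a superposition of randomly placed Gaussian bumps rescaled
    exactly to ``elevation_range``; sand/clay/soil-depth combine an elevation
    trend with unit-variance correlated noise whose variogram (Gaussian
    family) is recorded in the returned truth.
    """
    width, height = extent_m
    if width < 1000 or height < 1000:
        raise ValueError("extent must be at least 1 x 1 km")
    if width < cellsize_m or height < cellsize_m:
        raise ValueError("extent smaller than one DEM cell")
    rng = np.random.default_rng(seed)
    ncols = int(round(width / cellsize_m))
    nrows = int(round(height / cellsize_m))
    x = (np.arange(ncols) + 0.5) * cellsize_m
    y = (nrows - np.arange(nrows) - 0.5) * cellsize_m
    xx, yy = np.meshgrid(x, y)

    z = np.zeros((nrows, ncols))
    for _ in range(n_bumps):
        cx, cy = rng.uniform(0, width), rng.uniform(0, height)
        amp = rng.uniform(-1.0, 1.0)
        scale = rng.uniform(0.15, 0.5) * min(width, height)
        z += amp * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * scale ** 2))
    lo, hi = elevation_range
    z = lo + (z - z.min()) * (hi - lo) / (z.max() - z.min())

    sigma_cells = soil_range_m / (2.0 * cellsize_m)
    fields = {name: _correlated_field((nrows, ncols), sigma_cells, rng)
              for name in ("sand", "clay", "depth", "type")}
    variograms = {
        name: {"family": "Gaussian", "nugget": 0.0, "sill": 1.0, "range_m": soil_range_m}
        for name in fields
    }

    sand = np.clip(45.0 + 13.0 * fields["sand"], 5.0, 85.0)
    clay = np.clip(20.0 + 6.0 * fields["clay"], 2.0, np.minimum(95.0 - sand, 60.0))
    depth = np.clip(45.0 - 0.015 * (z - lo) + 15.0 * fields["depth"], 5.0, 120.0)
    # soil types: shallow rendzina high up, gleyic in wet (high clay-noise) spots
    t = fields["type"]
    soil_type = np.full(z.shape, "poor_brown", dtype=object)
    soil_type[t > 0.8] = "gleyic"
    soil_type[(t <= 0.8) & (t < -0.6)] = "rich_brown"
    soil_type[z > lo + 0.55 * (hi - lo)] = "rendzina"

    pnv = np.frompyfunc(pnv_for_elevation, 1, 1)(z)

    def grid(v):
        return RasterGrid(np.asarray(v, dtype=float), 0.0, 0.0, cellsize_m)

    truth = SyntheticTruth(seed=seed, field_variograms=variograms)
    return LandscapeBundle(grid(z), grid(sand), grid(clay), grid(depth),
                           soil_type, pnv, truth)


def place_plots(bundle: LandscapeBundle, dx_m: float = 200.0, dy_m: float = 100.0,
                timberline_m: float = 1700.0, managed_fraction: float = 0.25,
                disturbed_fraction: float = 0.05, seed: int | None = None) -> pd.DataFrame:
    """Plots at the systematic grid nodes below the timberline.

    Each plot inherits elevation, aspect and soils from the underlying DEM
    cell.  The management zone is the western ``managed_fraction`` of the
    extent; per-period disturbance patches are random rectangles covering
    roughly ``disturbed_fraction`` of the plots.
    """
    dem = bundle.dem
    if seed is None:
        seed = bundle.truth.seed + 1
    rng = np.random.default_rng(seed)
    width = dem.ncols * dem.cellsize_m
    height = dem.nrows * dem.cellsize_m
    xs = np.arange(dem.xll_m, dem.xll_m + width + 1e-9, dx_m)
    ys = np.arange(dem.yll_m, dem.yll_m + height + 1e-9, dy_m)
    gx, gy = np.meshgrid(xs, ys)
    gx, gy = gx.ravel(), gy.ravel()

    terr = terrain_indices(dem)
    elev = dem.sample(gx, gy)
    keep = elev < timberline_m
    gx, gy, elev = gx[keep], gy[keep], elev[keep]
    row, col = dem.cell_index(gx, gy)
    row = np.clip(row, 0, dem.nrows - 1)
    col = np.clip(col, 0, dem.ncols - 1)

    n = len(gx)
    plots = pd.DataFrame({
        "plot_id": [f"P{i + 1:04d}" for i in range(n)],
        "x_m": gx,
        "y_m": gy,
        "elevation_m": elev,
        "aspect_class": terr.aspect_class[row, col],
        "zone": np.where(gx < dem.xll_m + managed_fraction * width, "managed", "strict"),
        "sand_pct": bundle.sand.values[row, col],
        "clay_pct": bundle.clay.values[row, col],
        "soil_depth_cm": bundle.soil_depth.values[row, col],
        "soil_type": bundle.soil_type[row, col],
        "pnv_dominants": [";".join(sorted(s)) for s in bundle.pnv[row, col]],
    })
    for period in ("p1", "p2"):
        flag = np.zeros(n, dtype=bool)
        target = disturbed_fraction * n
        while flag.sum() < target:
            cx, cy = rng.uniform(0, width), rng.uniform(0, height)
            w, h = rng.uniform(200, 600), rng.uniform(100, 400)
            flag |= (np.abs(gx - cx) < w / 2) & (np.abs(gy - cy) < h / 2)
        plots[f"disturbed_{period}"] = flag
    bundle.plots = plots
    return plots


def generate_climate(plots: pd.DataFrame, census_years=CENSUS_YEARS, seed: int = 0,
                     warming_step: float = 0.21, lapse_rate: float = -0.0065,
                     plot_trend_sd: float = 0.5, season_jitter_sd: float = 0.35,
                     daily_noise_sd: float = 1.5) -> ClimateSeries:
    """Daily temperature, precipitation and radiation per plot.

    Temperature = base + lapse * elevation + seasonal sinusoid + a warming
    step applied from the second period on + daily noise.  The step varies
    smoothly between plots (mean exactly ``warming_step``, SD
    ``plot_trend_sd``) and carries independent per-season jitter, so the
    annual anomaly is the cleanest expression of the imposed trend.
    """
    rng = np.random.default_rng(seed)
    y0, y1, y2 = census_years
    dates = pd.date_range(f"{y0}-01-01", f"{y2 - 1}-12-31", freq="D")
    doy = np.asarray(dates.dayofyear)
    in_p2 = np.asarray(dates.year) >= y1
    month = np.asarray(dates.month)
    season_idx = np.select(
        [np.isin(month, (12, 1, 2)), np.isin(month, (3, 4, 5)), np.isin(month, (6, 7, 8))],
        [0, 1, 2], default=3,
    )
    elev = plots["elevation_m"].to_numpy()
    n_p, n_d = len(plots), len(dates)

    # smooth across the plot grid: low-frequency mixture of sinusoids in x/y
    x = plots["x_m"].to_numpy()
    y = plots["y_m"].to_numpy()
    smooth = np.zeros(n_p)
    for _ in range(6):
        kx, ky = rng.normal(0, 2 * np.pi / 1500.0, size=2)
        smooth += rng.normal(0, 1) * np.sin(kx * x + ky * y + rng.uniform(0, 2 * np.pi))
    smooth = (smooth - smooth.mean()) / (smooth.std() or 1.0)
    trend = warming_step + plot_trend_sd * smooth
    trend = trend - trend.mean() + warming_step          # landscape mean is exact
    season_jitter = rng.normal(0.0, season_jitter_sd, size=(n_p, 4))
    season_jitter -= season_jitter.mean(axis=0, keepdims=True)

    seasonal = 8.5 * np.sin(2 * np.pi * (doy - 105) / 365.25)
    base = 7.0 + lapse_rate * (elev - 600.0)
    tmean = (
        base[:, None]
        + seasonal[None, :]
        + (trend[:, None] + season_jitter[:, season_idx]) * in_p2[None, :]
        + rng.normal(0.0, daily_noise_sd, size=(n_p, n_d))
    ).astype(np.float32)

    p_season = np.array([3.6, 4.6, 6.2, 4.4])  # mm/day by season
    precip = rng.gamma(0.6, 1.0, size=(n_p, n_d)).astype(np.float32)
    precip *= (p_season[season_idx] / 0.6).astype(np.float32)[None, :]
    rad_seasonal = 11.0 + 8.0 * np.sin(2 * np.pi * (doy - 105) / 365.25)
    rad = (rad_seasonal[None, :] + rng.normal(0, 2.5, size=(n_p, n_d))).astype(np.float32)
    np.clip(rad, 0.1, None, out=rad)

    return ClimateSeries(list(plots["plot_id"]), dates, tmean, precip, rad)


def _annual_anomaly(climate: ClimateSeries) -> tuple[np.ndarray, np.ndarray]:
    """(years, anomaly matrix plots x years): annual mean T minus full-record mean."""
    years = np.asarray(climate.dates.year)
    uyears = np.unique(years)
    starts = np.searchsorted(years, uyears)
    sums = np.add.reduceat(climate.tmean.astype(float), starts, axis=1)
    counts = np.add.reduceat(np.ones_like(years, dtype=float), starts)
    annual = sums / counts
    return uyears, annual - climate.tmean.mean(axis=1, dtype=float)[:, None]


def _initial_stand(elev: float, params: SimulationParams, truth: SyntheticTruth,
                   rng: np.random.Generator):
    n0 = rng.poisson(params.initial_density_mean * np.exp(-(elev - 600.0) / 2500.0))
    dbh = 6.0 + rng.gamma(1.8, 9.0, size=n0)
    p_con = _logistic(truth.elevation_conifer_gradient * (elev - 1100.0) / 150.0, 0.30, 0.95)
    conifer = rng.random(n0) < p_con
    species = np.where(
        conifer,
        rng.choice(["PA", "AA", "LD", "PC"], size=n0,
                   p=_conifer_mix(elev)),
        rng.choice(["FS", "AC", "SA", "UG"], size=n0, p=[0.62, 0.22, 0.10, 0.06]),
    )
    age = np.clip(dbh * 3.0 + rng.normal(0, 12, size=n0), 8, None).round()
    return dbh, species.astype(object), age


def _conifer_mix(elev: float) -> list:
    high = _logistic((elev - 1400.0) / 150.0, 0.0, 1.0)
    p = np.array([0.58, 0.22 * (1 - high) + 0.05, 0.12, 0.05 + 0.25 * high])
    return list(p / p.sum())


def _logistic(x, lo=0.0, hi=1.0):
    return lo + (hi - lo) / (1.0 + np.exp(-x))


def simulate_inventory(bundle: LandscapeBundle, climate: ClimateSeries,
                       truth: SyntheticTruth, seed: int | None = None,
                       params: SimulationParams = SimulationParams()):
    """Annual growth/mortality/recruitment loop with censuses at the truth years.

    Growth and recruitment are multiplied by exp(temp_effect * annual
    temperature anomaly) and by exp(-legacy_damping * BA / ba_ref); conifer
    growth carries an extra exp(-conifer_temp_effect * anomaly) penalty and
    the conifer share of recruits falls with warming and rises with
    elevation.  Mortality rises with stand basal area, and each disturbed
    plot loses ``disturbance_kill_frac`` of its stems in one random year of
    the flagged period.  Returns an :class:`~forestdyn.inventory.InventoryDataset`.
    """
    from .inventory import InventoryDataset

    if bundle.plots is None:
        raise ValueError("place_plots must be called before simulate_inventory")
    if seed is None:
        seed = truth.seed + 2
    rng = np.random.default_rng(seed)
    plots = bundle.plots
    y0, y1, y2 = truth.census_years
    years_axis, anom = _annual_anomaly(climate)
    year_col = {y: i for i, y in enumerate(years_axis)}

    records = {"plot_id": [], "census_id": [], "species_code": [],
               "dbh_cm": [], "age_years": []}

    def take_census(plot_id, census_id, dbh, species, age):
        live = dbh >= 6.0
        records["plot_id"].extend([plot_id] * int(live.sum()))
        records["census_id"].extend([census_id] * int(live.sum()))
        records["species_code"].extend(species[live])
        records["dbh_cm"].extend(np.round(dbh[live], 2))
        records["age_years"].extend(age[live].astype(int))

    ef = params.expansion_factor
    sensitivity = SPECIES_TEMP_SENSITIVITY
    for p_idx, plot in enumerate(plots.itertuples(index=False)):
        dbh, species, age = _initial_stand(plot.elevation_m, params, truth, rng)
        dist_year = {
            "p1": rng.integers(y0, y1) if plot.disturbed_p1 else None,
            "p2": rng.integers(y1, y2) if plot.disturbed_p2 else None,
        }
        for year in range(y0 - params.burn_in_years, y2):
            if year == y0:
                take_census(plot.plot_id, "c1", dbh, species, age)
            elif year == y1:
                take_census(plot.plot_id, "c2", dbh, species, age)
            a = anom[p_idx, year_col[year]] if year >= y0 else 0.0
            ba = ef * np.sum(np.pi * (dbh / 200.0) ** 2)
            damp = np.exp(-truth.legacy_damping * ba / params.ba_ref)
            boost = np.exp(truth.temp_effect * a)

            if len(dbh) > 0:
                sens = np.array([sensitivity[s] for s in species])
                sp_mod = np.exp(truth.conifer_temp_effect * sens * a)
                # diameter increment grows with tree size: dominant trees pull away
                size_f = 0.45 + 0.55 * (1.0 - np.exp(-(dbh - 6.0) / 25.0))
                inc = (params.growth_rate_cm * boost * damp * sp_mod * size_f
                       + rng.normal(0, params.growth_noise_cm, size=len(dbh)))
                dbh = dbh + np.maximum(inc, 0.02)
                # warm anomalies also tilt mortality against temperature-
                # sensitive species (conifers), shifting basal-area shares
                p_mort = (params.mortality_rate + params.mortality_density * (ba / 60.0)) \
                    * np.exp(-truth.conifer_temp_effect * sens * a)
                dead = rng.random(len(dbh)) < np.minimum(p_mort, 0.9)
                if year in (dist_year["p1"], dist_year["p2"]):
                    dead |= rng.random(len(dbh)) < params.disturbance_kill_frac
                dbh, species, age = dbh[~dead], species[~dead], age[~dead]

            lam = params.recruitment_rate * boost * damp
            n_rec = rng.poisson(lam)
            if n_rec:
                rec_dbh = np.minimum(6.0 + rng.exponential(0.8, size=n_rec),
                                     params.recruit_cap_cm)
                logit = (truth.elevation_conifer_gradient * (plot.elevation_m - 1100.0) / 150.0
                         - truth.conifer_temp_effect * a)
                p_con = _logistic(logit, 0.15, 0.9)
                rec_con = rng.random(n_rec) < p_con
                rec_sp = np.where(
                    rec_con,
                    rng.choice(["PA", "AA", "LD", "PC"], size=n_rec, p=_conifer_mix(plot.elevation_m)),
                    rng.choice(["FS", "AC", "SA", "UG"], size=n_rec, p=[0.55, 0.25, 0.12, 0.08]),
                )
                dbh = np.concatenate([dbh, rec_dbh])
                species = np.concatenate([species, rec_sp.astype(object)])
                age = np.concatenate([age, np.full(n_rec, 10.0)])
            age = age + 1
        take_census(plot.plot_id, "c3", dbh, species, age)

    trees = pd.DataFrame(records)
    trees["expansion_factor"] = ef
    return InventoryDataset(truth.census_years, trees, plots.copy(), SPECIES_TABLE.copy())


def generate_scene(seed: int = 0, extent_m=(3600.0, 1800.0), truth: SyntheticTruth | None = None,
                   params: SimulationParams = SimulationParams(), warming_step: float | None = None,
                   timberline_m: float = 1700.0):
    """Full default scene: terrain, plots, climate, inventory.

    Returns (dataset, climate, bundle).  All randomness derives from ``seed``.
    """
    bundle = generate_terrain(extent_m, seed=seed)
    if truth is not None:
        truth.field_variograms = bundle.truth.field_variograms
        truth.seed = seed
        bundle.truth = truth
    if warming_step is not None:
        bundle.truth.warming_step = warming_step
    place_plots(bundle, timberline_m=timberline_m)
    climate = generate_climate(bundle.plots, bundle.truth.census_years, seed=seed + 10,
                               warming_step=bundle.truth.warming_step)
    dataset = simulate_inventory(bundle, climate, bundle.truth)
    return dataset, climate, bundle
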