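"""End-to-end orchestration: indicators -> change -> maps -> acceleration -> drivers.

:func:`run_pipeline` executes the full analysis on either a synthetic scene or
user-supplied tables, writes every stage's outputs under an output directory,
and returns a machine-readable run report (also written as ``report.json``).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import change as change_mod
from . import covariates as cov_mod
from . import drivers as drv_mod
from . import geostats
from . import indicators as ind_mod
from . import synthetic as synth_mod
from .grids import write_raster_ascii
from .inventory import read_inventory, write_inventory

log = logging.getLogger("forestdyn")

__all__ = ["PipelineConfig", "run_pipeline", "fit_driver_models", "aggregate_by_group"]


@dataclass
class PipelineConfig:
    outdir: str = "forestdyn_out"
    seed: int = 0
    synthetic: bool = True
    # input tables (required when synthetic = False)
    trees_csv: str | None = None
    plots_csv: str | None = None
    species_csv: str | None = None
    climate_csv: str | None = None
    census_years: tuple = synth_mod.CENSUS_YEARS
    timberline_m: float = 1700.0
    elevation_threshold_m: float = 1400.0
    kriging_cellsize_m: float = 100.0
    variogram_bins: int = 15
    extent_m: tuple = (3600.0, 1800.0)
    warming_step: float = 0.21
    brt_learning_rate: float = 0.2
    brt_max_trees: int = 45
    brt_depth: int = 3
    brt_bag_fraction: float = 0.5
    brt_folds: int = 10
    write_climate_csv: bool = False

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**data)
        cfg.census_years = tuple(cfg.census_years)
        cfg.extent_m = tuple(cfg.extent_m)
        return cfg

    def brt_config(self) -> drv_mod.BRTConfig:
        return drv_mod.BRTConfig(
            learning_rate=self.brt_learning_rate, tree_depth=self.brt_depth,
            bag_fraction=self.brt_bag_fraction, max_trees=self.brt_max_trees,
            n_folds=self.brt_folds, seed=self.seed,
        )


def _load_climate_csv(path) -> cov_mod.ClimateSeries:
    df = pd.read_csv(path, parse_dates=["date"])
    pivots = {v: df.pivot(index="plot_id", columns="date", values=v) for v in ("tmean", "precip", "rad")}
    t = pivots["tmean"]
    return cov_mod.ClimateSeries(list(t.index), pd.DatetimeIndex(t.columns),
                                 *(pivots[v].to_numpy() for v in ("tmean", "precip", "rad")))


def fit_driver_models(driver_table: pd.DataFrame, per_period: dict, plots: pd.DataFrame,
                      brt: drv_mod.BRTConfig) -> tuple[dict, dict, dict]:
    """Backward-selected BRT models for every (indicator, period) response.

    Returns (fits, selection paths, Moran's I of final-model residuals), each
    keyed by (indicator, period).
    """
    coords = plots[["x_m", "y_m"]].to_numpy()
    fits, paths, morans = {}, {}, {}
    for period in sorted({p for _, p in driver_table.index}):
        X = driver_table.xs(period, level="period").loc[plots["plot_id"]]
        for ind in ind_mod.INDICATORS:
            y = per_period[period][ind].reindex(plots["plot_id"]).to_numpy()
            log.info("BRT backward selection: %s %s", ind, period)
            path, fit = drv_mod.backward_select(X, y, brt)
            fits[(ind, period)] = fit
            paths[(ind, period)] = path
            I, _ = drv_mod.morans_i(fit.residuals, coords)
            morans[(ind, period)] = I
    return fits, paths, morans


def aggregate_by_group(fits: dict) -> dict:
    """Variance-explained-weighted importances for structural / compositional / all models."""
    groups = {
        "structural": [k for k in fits if k[0] in ind_mod.STRUCTURE_INDICATORS],
        "compositional": [k for k in fits if k[0] in ind_mod.COMPOSITION_INDICATORS],
        "overall": list(fits),
    }
    return {
        name: drv_mod.aggregate_importance({k: fits[k] for k in keys},
                                           cov_mod.DRIVER_COLUMNS, cov_mod.DRIVER_CATEGORIES)
        for name, keys in groups.items()
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every analysis stage; returns (and writes) the run report."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "census_years": list(config.census_years),
                    "stages": {}, "outputs": []}

    def _write_csv(df: pd.DataFrame, name: str, **kw) -> None:
        df.to_csv(out / name, **kw)
        report["outputs"].append(name)

    t0 = time.time()
    stage = "data_model_io"
    try:
        if config.synthetic:
            stage = "synthetic_landscape"
            log.info("generating synthetic scene (seed=%d)", config.seed)
            dataset, climate, bundle = synth_mod.generate_scene(
                seed=config.seed, extent_m=config.extent_m,
                warming_step=config.warming_step, timberline_m=config.timberline_m,
            )
            write_inventory(dataset, out / "trees.csv", out / "plots.csv", out / "species.csv")
            report["outputs"] += ["trees.csv", "plots.csv", "species.csv"]
            write_raster_ascii(bundle.dem, out / "dem.asc")
            report["outputs"].append("dem.asc")
            with open(out / "truth.json", "w") as fh:
                json.dump(bundle.truth.to_dict(), fh, indent=2)
            report["outputs"].append("truth.json")
            if config.write_climate_csv:
                _write_csv(climate.to_frame(), "climate.csv", index=False)
            dem = bundle.dem
        else:
            for name in ("trees_csv", "plots_csv", "species_csv", "climate_csv"):
                if getattr(config, name) is None:
                    raise FileNotFoundError(f"config.{name} is required when synthetic = false")
            dataset, vrep = read_inventory(config.trees_csv, config.plots_csv,
                                           config.species_csv, config.census_years)
            if not vrep.ok:
                raise ValueError(f"invalid inventory: {vrep}")
            climate = _load_climate_csv(config.climate_csv)
            from .grids import read_raster_ascii
            dem = read_raster_ascii(Path(config.plots_csv).parent / "dem.asc")
        report["n_plots"] = int(len(dataset.plots))
        report["n_tree_records"] = int(len(dataset.trees))

        stage = "indicators"
        log.info("computing indicator table (%d plots)", len(dataset.plots))
        indicators = ind_mod.indicator_table(dataset)
        _write_csv(indicators, "indicators.csv")

        stage = "change_stats"
        c1, c2, c3 = dataset.census_ids
        full = change_mod.annualized_change(indicators, dataset, c1, c3)
        std = change_mod.standardize_changes(full)
        per_period = {
            "p1": change_mod.annualized_change(indicators, dataset, c1, c2),
            "p2": change_mod.annualized_change(indicators, dataset, c2, c3),
        }
        composites = pd.DataFrame({
            g: change_mod.composite_change(std, g) for g in ("structure", "composition")
        })
        accel = change_mod.acceleration_summary(indicators, dataset)
        strata = change_mod.elevation_stratified_summary(std, dataset.plots,
                                                         config.elevation_threshold_m)
        _write_csv(full, "changes.csv")
        _write_csv(std, "changes_standardized.csv")
        _write_csv(composites, "composites.csv")
        _write_csv(accel, "acceleration_summary.csv")
        _write_csv(strata, "elevation_strata.csv")
        report["stages"]["acceleration"] = accel.reset_index().to_dict(orient="records")
        report["stages"]["elevation_strata"] = (
            strata["difference"].round(6).to_dict()
        )

        stage = "geostats"
        coords = dataset.plots[["x_m", "y_m"]].to_numpy()
        grid = geostats.prediction_grid(coords, config.kriging_cellsize_m)
        vg_rows, patt_rows = [], []
        for ind in ind_mod.INDICATORS:
            rasters = {}
            for period, table in per_period.items():
                z = table[ind].reindex(dataset.plots["plot_id"]).to_numpy()
                if np.allclose(z, 0):
                    log.warning("all-zero change field %s %s: emitting zero raster", ind, period)
                    raster = geostats.RasterGrid(np.zeros(grid.values.shape), grid.xll_m,
                                                 grid.yll_m, grid.cellsize_m)
                    model = None
                else:
                    emp = geostats.empirical_semivariogram(coords, z, config.variogram_bins)
                    model = geostats.fit_variogram(emp)
                    raster = geostats.ordinary_kriging(coords, z, model, grid=grid)
                rasters[period] = raster
                fname = f"change_{ind}_{period}.asc"
                write_raster_ascii(raster, out / fname)
                report["outputs"].append(fname)
                if model is not None:
                    vg_rows.append({
                        "indicator": ind, "period": period, "family": model.family,
                        "nugget": model.nugget, "partial_sill": model.partial_sill,
                        "range_m": model.range_m, "kappa": model.kappa,
                        "effective_range_m": model.effective_range(), "fit_error": model.fit_error,
                    })
            rmse, congruence = geostats.compare_patterns(rasters["p1"], rasters["p2"])
            patt_rows.append({"indicator": ind, "rmse": rmse, "congruence_pct": congruence})
        _write_csv(pd.DataFrame(vg_rows), "variogram_models.csv", index=False)
        pattern = pd.DataFrame(patt_rows).set_index("indicator")
        _write_csv(pattern, "pattern_comparison.csv")
        report["stages"]["pattern_comparison"] = pattern.round(6).to_dict(orient="index")

        # hot-spot composites of standardized full-span change
        for g in ("structure", "composition"):
            z = composites[g].reindex(dataset.plots["plot_id"]).to_numpy()
            emp = geostats.empirical_semivariogram(coords, z, config.variogram_bins)
            raster = geostats.ordinary_kriging(coords, z, geostats.fit_variogram(emp), grid=grid)
            write_raster_ascii(raster, out / f"hotspot_{g}.asc")
            report["outputs"].append(f"hotspot_{g}.asc")

        stage = "covariates"
        terr = cov_mod.terrain_indices(dem)
        anomalies = cov_mod.climate_anomalies(climate, dataset.census_years)
        driver_table = cov_mod.assemble_driver_table(dataset, terr, anomalies, dem)
        _write_csv(driver_table, "drivers.csv")

        stage = "driver_attribution"
        brt = config.brt_config()
        fits, paths, morans = fit_driver_models(driver_table, per_period, dataset.plots, brt)
        agg = aggregate_by_group(fits)
        importance = pd.DataFrame({f"{n}_pct": a.covariate_pct for n, a in agg.items()})
        categories = pd.DataFrame({f"{n}_pct": a.category_pct for n, a in agg.items()})
        _write_csv(importance.rename_axis("covariate"), "drivers_importance.csv")
        _write_csv(categories.rename_axis("category"), "categories.csv")
        morans_df = pd.DataFrame(
            [{"indicator": k[0], "period": k[1], "morans_i": v} for k, v in morans.items()]
        )
        _write_csv(morans_df, "morans_i.csv", index=False)
        with open(out / "selection_paths.json", "w") as fh:
            json.dump({f"{k[0]}|{k[1]}": {"steps": [[list(s), r] for s, r in p.steps],
                                          "best_index": p.best_index}
                       for k, p in paths.items()}, fh, indent=2)
        report["outputs"].append("selection_paths.json")
        report["stages"]["importance_category"] = categories.round(3).to_dict()
        report["stages"]["importance_top5"] = {
            n: a.covariate_pct.sort_values(ascending=False).head(5).round(3).to_dict()
            for n, a in agg.items()
        }
        report["stages"]["cv_variance_explained_mean"] = float(
            np.mean([f.cv_variance_explained for f in fits.values()])
        )
        report["stages"]["morans_i_range"] = [float(morans_df["morans_i"].min()),
                                              float(morans_df["morans_i"].max())]
    except Exception as exc:
        log.error("pipeline failed in stage %s: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report["runtime_s"] = round(time.time() - t0, 2)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    report["outputs"].append("report.json")
    return report
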