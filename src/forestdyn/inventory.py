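"""Inventory data model, CSV readers/writers, and dataset validation.

The pipeline operates on repeated measurements of fixed-area permanent plots:
every stem with dbh >= 6 cm is recorded at each census together with its
species and an expansion factor (stems per hectare represented; 20 for a
500 m2 plot).  Plot descriptors carry location, terrain, soil, protection
zone, the species expected under potential natural vegetation (PNV), and
per-period disturbance flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "TreeRecord",
    "PlotDescriptor",
    "InventoryDataset",
    "SchemaError",
    "ValidationReport",
    "DBH_THRESHOLD_CM",
    "ASPECT_CLASSES",
    "SERAL_CLASSES",
    "read_inventory",
    "write_inventory",
    "validate_inventory",
]

DBH_THRESHOLD_CM = 6.0
DEFAULT_EXPANSION_FACTOR = 20.0  # 10000 m2/ha / 500 m2 plot

ASPECT_CLASSES = ("N", "NE", "E", "SE", "S", "SW", "W", "NW", "flat")
SERAL_CLASSES = ("early", "late", "rare", "other")

TREE_COLUMNS = ["plot_id", "census_id", "species_code", "dbh_cm", "age_years", "expansion_factor"]
PLOT_COLUMNS = [
    "plot_id", "x_m", "y_m", "elevation_m", "aspect_class", "zone",
    "sand_pct", "clay_pct", "soil_depth_cm", "soil_type", "pnv_dominants",
    "disturbed_p1", "disturbed_p2",
]
SPECIES_COLUMNS = ["species_code", "conifer", "seral_class"]


class SchemaError(ValueError):
    """A table is missing a required column or violates referential integrity."""


@dataclass(frozen=True)
class TreeRecord:
    """One measured stem at one census."""

    plot_id: str
    census_id: str
    species_code: str
    dbh_cm: float
    age_years: int | None = None
    expansion_factor: float = DEFAULT_EXPANSION_FACTOR


@dataclass(frozen=True)
class PlotDescriptor:
    """Static description of one permanent sample plot."""

    plot_id: str
    x_m: float
    y_m: float
    elevation_m: float
    aspect_class: str
    zone: str
    sand_pct: float
    clay_pct: float
    soil_depth_cm: float
    soil_type: str
    pnv_dominants: frozenset
    disturbed: dict = field(default_factory=dict)


@dataclass
class InventoryDataset:
    """Trees, plots and species traits for a sequence of censuses.

    ``trees`` and ``plots`` are DataFrames with the documented column sets;
    ``species`` is indexed by species_code with boolean ``conifer`` and a
    ``seral_class`` in {early, late, rare, other}.  ``census_years`` maps
    position to calendar year; census ids are ``c1, c2, ...`` in that order.
    """

    census_years: tuple
    trees: pd.DataFrame
    plots: pd.DataFrame
    species: pd.DataFrame

    @property
    def census_ids(self) -> list[str]:
        return [f"c{i + 1}" for i in range(len(self.census_years))]

    def census_year(self, census_id: str) -> int:
        return self.census_years[self.census_ids.index(census_id)]

    def tree_records(self):
        for row in self.trees.itertuples(index=False):
            yield TreeRecord(row.plot_id, row.census_id, row.species_code,
                             row.dbh_cm,
                             None if pd.isna(row.age_years) else int(row.age_years),
                             row.expansion_factor)

    def plot_descriptors(self):
        for row in self.plots.itertuples(index=False):
            yield PlotDescriptor(
                row.plot_id, row.x_m, row.y_m, row.elevation_m, row.aspect_class,
                row.zone, row.sand_pct, row.clay_pct, row.soil_depth_cm, row.soil_type,
                frozenset(str(row.pnv_dominants).split(";")),
                {"p1": bool(row.disturbed_p1), "p2": bool(row.disturbed_p2)},
            )


@dataclass
class ValidationReport:
    violations: list = field(default_factory=list)
    rejected_trees: int = 0

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, kind: str, message: str) -> None:
        self.violations.append((kind, message))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        if self.ok:
            return "dataset valid"
        return "\n".join(f"[{k}] {m}" for k, m in self.violations)


def _require_columns(df: pd.DataFrame, columns, table: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{table} is missing column(s): {missing}")


def read_inventory(tree_table_path, plot_table_path, species_table_path,
                   census_years) -> tuple[InventoryDataset, ValidationReport]:
    """Read and validate an inventory from the three CSV tables.

    Tree rows below the 6 cm caliper threshold are rejected (counted in the
    report) rather than failing the read, mirroring field protocols where
    sub-threshold stems are simply out of the sampling population.
    """
    trees = pd.read_csv(tree_table_path, dtype={"plot_id": str, "census_id": str, "species_code": str})
    plots = pd.read_csv(plot_table_path, dtype={"plot_id": str})
    species = pd.read_csv(species_table_path, dtype={"species_code": str})
    _require_columns(trees, TREE_COLUMNS, "tree table")
    _require_columns(plots, PLOT_COLUMNS, "plot table")
    _require_columns(species, SPECIES_COLUMNS, "species table")

    undersized = trees["dbh_cm"] < DBH_THRESHOLD_CM
    rejected = int(undersized.sum())
    trees = trees.loc[~undersized].reset_index(drop=True)

    orphans = sorted(set(trees["plot_id"]) - set(plots["plot_id"]))
    if orphans:
        raise SchemaError(f"tree table references unknown plot_id(s): {orphans[:10]}")

    species = species.set_index("species_code")
    species["conifer"] = species["conifer"].astype(bool)
    dataset = InventoryDataset(tuple(census_years), trees, plots, species)
    report = validate_inventory(dataset)
    report.rejected_trees = rejected
    return dataset, report


def write_inventory(dataset: InventoryDataset, tree_table_path, plot_table_path,
                    species_table_path) -> None:
    dataset.trees.to_csv(tree_table_path, index=False, columns=TREE_COLUMNS)
    dataset.plots.to_csv(plot_table_path, index=False, columns=PLOT_COLUMNS)
    dataset.species.reset_index().to_csv(species_table_path, index=False, columns=SPECIES_COLUMNS)


def validate_inventory(dataset: InventoryDataset) -> ValidationReport:
    """Check every data-model invariant; returns an empty report iff valid."""
    rep = ValidationReport()
    years = dataset.census_years
    if len(years) < 2:
        rep.add("census", "at least 2 censuses are required for change analysis")
    if any(b <= a for a, b in zip(years, years[1:])):
        rep.add("census", f"census years must be strictly increasing, got {years}")

    trees, plots, species = dataset.trees, dataset.plots, dataset.species

    bad_dbh = trees["dbh_cm"] < DBH_THRESHOLD_CM
    if bad_dbh.any():
        rep.add("tree", f"{int(bad_dbh.sum())} tree(s) below the {DBH_THRESHOLD_CM} cm dbh threshold")
    if (trees["expansion_factor"] <= 0).any():
        rep.add("tree", "non-positive expansion factor(s)")
    if trees["age_years"].notna().any() and (trees["age_years"].dropna() < 0).any():
        rep.add("tree", "negative tree age(s)")

    orphan_plots = sorted(set(trees["plot_id"]) - set(plots["plot_id"]))
    if orphan_plots:
        rep.add("referential", f"trees reference unknown plot_id(s): {orphan_plots[:10]}")
    unknown_species = sorted(set(trees["species_code"]) - set(species.index))
    if unknown_species:
        rep.add("referential", f"trees reference unknown species_code(s): {unknown_species[:10]}")
    valid_census = set(dataset.census_ids)
    bad_census = sorted(set(trees["census_id"]) - valid_census)
    if bad_census:
        rep.add("referential", f"unknown census_id(s): {bad_census}")

    if (plots["sand_pct"] + plots["clay_pct"] > 100).any():
        rep.add("plot", "sand_pct + clay_pct exceeds 100 for some plot(s)")
    if (plots["soil_depth_cm"] < 0).any():
        rep.add("plot", "negative soil depth(s)")
    bad_aspect = sorted(set(plots["aspect_class"]) - set(ASPECT_CLASSES))
    if bad_aspect:
        rep.add("plot", f"unknown aspect class(es): {bad_aspect}")
    empty_pnv = plots["pnv_dominants"].astype(str).str.strip() == ""
    if empty_pnv.any():
        rep.add("plot", f"{int(empty_pnv.sum())} plot(s) with empty pnv_dominants")

    bad_seral = sorted(set(species["seral_class"]) - set(SERAL_CLASSES))
    if bad_seral:
        rep.add("species", f"unknown seral class(es): {bad_seral}")
    if species.index.duplicated().any():
        rep.add("species", "duplicate species_code entries")
    return rep
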