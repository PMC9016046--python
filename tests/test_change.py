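import numpy as np
import pandas as pd
import pytest

from forestdyn import change
from forestdyn.indicators import INDICATORS, indicator_table
from forestdyn.inventory import InventoryDataset


def _indicator_frame(values_by_census, plot_ids):
    """Build a (plot, census)-indexed indicator table from per-census matrices."""
    frames = []
    for census, vals in values_by_census.items():
        df = pd.DataFrame(vals, index=pd.Index(plot_ids, name="plot_id"),
                          columns=list(INDICATORS))
        df["census_id"] = census
        frames.append(df)
    return pd.concat(frames).set_index("census_id", append=True)


def _dataset_stub(census_years):
    return InventoryDataset(census_years, pd.DataFrame(columns=["plot_id"]),
                            pd.DataFrame(columns=["plot_id"]), pd.DataFrame())


def test_annualized_change_basic():
    tbl = _indicator_frame({"c1": [[20.0] * 9], "c2": [[26.0] * 9]}, ["A"])
    ds = _dataset_stub((1984, 1996))
    ch = change.annualized_change(tbl, ds, "c1", "c2")
    assert ch.loc["A", "basal_area"] == pytest.approx(0.5)


def test_unchanged_plot_zero():
    tbl = _indicator_frame({"c1": [[7.0] * 9], "c2": [[7.0] * 9]}, ["A"])
    ch = change.annualized_change(tbl, _dataset_stub((1984, 1996)), "c1", "c2")
    assert (ch.loc["A"] == 0).all()


def test_same_year_censuses_raise():
    tbl = _indicator_frame({"c1": [[1.0] * 9], "c2": [[2.0] * 9]}, ["A"])
    with pytest.raises(ZeroDivisionError):
        change.annualized_change(tbl, _dataset_stub((1984, 1984)), "c1", "c2")


def test_standardize_examples():
    df = pd.DataFrame({"basal_area": [0.5, -1.0, 0.25], "stand_density": [2.0, 4.0, 0.0]})
    out = change.standardize_changes(df)
    assert list(out["basal_area"]) == [0.5, -1.0, 0.25]
    assert list(out["stand_density"]) == [0.5, 1.0, 0.0]


def test_standardize_property(rng):
    for _ in range(20):
        df = pd.DataFrame(rng.normal(size=(30, 3)), columns=["a", "b", "c"])
        out = change.standardize_changes(df)
        for col in out:
            assert out[col].abs().max() == pytest.approx(1.0)
            # signs preserved
            assert (np.sign(out[col]) == np.sign(df[col])).all()
    zeros = pd.DataFrame({"a": [0.0, 0.0]})
    assert (change.standardize_changes(zeros)["a"] == 0).all()


def test_composite_change():
    df = pd.DataFrame([[0.2, 0.4, 0.6, 0.8] + [0.0] * 5], columns=list(INDICATORS))
    assert change.composite_change(df, "structure").iloc[0] == pytest.approx(0.5)
    assert change.composite_change(df * 0, "composition").iloc[0] == 0.0
    with pytest.raises(KeyError):
        change.composite_change(df, "both")


def test_composite_bounded(rng):
    df = pd.DataFrame(rng.uniform(-1, 1, size=(50, 9)), columns=list(INDICATORS))
    comp = change.composite_change(df, "composition")
    assert comp.between(-1, 1).all()


def _accel_fixture(mean_p1, mean_p2, n_plots=4):
    """Indicator table whose landscape-mean period rates equal the targets.

    Period lengths are 12 and 15 years (censuses 1984/1996/2011); plot values
    are spread around the mean so SDs are nonzero.
    """
    rng = np.random.default_rng(0)
    plot_ids = [f"P{i}" for i in range(n_plots)]
    offsets = rng.normal(0, 1, size=(n_plots, 9))
    offsets -= offsets.mean(axis=0)  # keep the landscape means exact
    base = np.full((n_plots, 9), 30.0)
    v1984 = base
    v1996 = v1984 + 12 * (np.asarray(mean_p1) + offsets)
    v2011 = v1996 + 15 * (np.asarray(mean_p2) + offsets)
    tbl = _indicator_frame({"c1": v1984, "c2": v1996, "c3": v2011}, plot_ids)
    return tbl, _dataset_stub((1984, 1996, 2011))


def test_acceleration_difference_worked_examples():
    """Acceleration = period-2 minus period-1 mean annual change.

    Worked examples: rates 0.342 -> 0.344 give +0.002; 2.136 -> 4.589 give
    +2.453 (basal-area and stand-density magnitudes of a recovering forest).
    """
    tbl, ds = _accel_fixture([0.342] * 9, [0.344] * 9)
    acc = change.acceleration_summary(tbl, ds)
    assert acc.loc["basal_area", "mean_change_p1"] == pytest.approx(0.342)
    assert acc.loc["basal_area", "difference"] == pytest.approx(0.002)
    tbl, ds = _accel_fixture([2.136] * 9, [4.589] * 9)
    acc = change.acceleration_summary(tbl, ds)
    assert acc.loc["stand_density", "difference"] == pytest.approx(2.453)
    # equal period rates -> zero difference
    tbl, ds = _accel_fixture([1.0] * 9, [1.0] * 9)
    assert change.acceleration_summary(tbl, ds)["difference"].abs().max() < 1e-12


def test_acceleration_identity(rng):
    """difference column equals mean_p2 - mean_p1 to machine precision."""
    tbl, ds = _accel_fixture(rng.normal(size=9), rng.normal(size=9), n_plots=8)
    acc = change.acceleration_summary(tbl, ds)
    np.testing.assert_allclose(
        acc["difference"], acc["mean_change_p2"] - acc["mean_change_p1"], atol=1e-14
    )


def test_acceleration_requires_three_censuses():
    tbl = _indicator_frame({"c1": [[1.0] * 9], "c2": [[2.0] * 9]}, ["A"])
    with pytest.raises(ValueError, match="3 censuses"):
        change.acceleration_summary(tbl, _dataset_stub((1984, 1996)))


def test_period_chaining_identity(rng):
    """Full-span annual change is the 12/27-15/27 weighted mean of period rates."""
    tbl, ds = _accel_fixture(rng.normal(size=9), rng.normal(size=9), n_plots=6)
    p1 = change.annualized_change(tbl, ds, "c1", "c2")
    p2 = change.annualized_change(tbl, ds, "c2", "c3")
    full = change.annualized_change(tbl, ds, "c1", "c3")
    np.testing.assert_allclose(full, (12 * p1 + 15 * p2) / 27, atol=1e-12)


def test_elevation_strata():
    ch = pd.DataFrame({"basal_area": [1.0, 0.0]}, index=pd.Index(["A", "B"], name="plot_id"))
    plots = pd.DataFrame({"plot_id": ["A", "B"], "elevation_m": [1000.0, 1600.0]})
    out = change.elevation_stratified_summary(ch, plots, 1400.0)
    assert out.loc["basal_area", "difference"] == pytest.approx(1.0)
    # empty stratum -> undefined difference
    plots_low = plots.assign(elevation_m=[1000.0, 1200.0])
    out = change.elevation_stratified_summary(ch, plots_low, 1400.0)
    assert np.isnan(out.loc["basal_area", "difference"])
    assert out.loc["basal_area", "n_above"] == 0


def test_elevation_stratified_recovers_imposed_effect():
    """Warming depresses conifer share most where shares are mixed (below the
    1400 m montane/subalpine line), so the below-minus-above difference of
    standardized conifer-share change is negative in >= 8 of 10 seeds."""
    from forestdyn import synthetic
    from forestdyn.indicators import indicator_table
    negatives = 0
    for seed in range(10):
        bundle = synthetic.generate_terrain((2000.0, 1000.0), seed=seed,
                                            elevation_range=(800.0, 1900.0))
        synthetic.place_plots(bundle)
        climate = synthetic.generate_climate(bundle.plots, seed=seed + 50)
        ds = synthetic.simulate_inventory(bundle, climate, bundle.truth)
        table = indicator_table(ds)
        std = change.standardize_changes(change.annualized_change(table, ds, "c1", "c3"))
        out = change.elevation_stratified_summary(std, ds.plots, 1400.0)
        negatives += out.loc["conifer_share", "difference"] < 0
    assert negatives >= 8


def test_annualized_matches_recomputation_from_trees(scene):
    """Annualized change equals brute-force recomputation from raw tree records."""
    dataset, _, _ = scene
    table = indicator_table(dataset)
    ch = change.annualized_change(table, dataset, "c1", "c2")
    sub = dataset.plots["plot_id"].iloc[:5]
    from forestdyn.indicators import structure_indicators
    for pid in sub:
        rows = {}
        for census in ("c1", "c2"):
            grp = dataset.trees[(dataset.trees["plot_id"] == pid)
                                & (dataset.trees["census_id"] == census)]
            rows[census] = structure_indicators(grp["dbh_cm"], grp["expansion_factor"])
        expected = (rows["c2"]["basal_area"] - rows["c1"]["basal_area"]) / 12.0
        assert ch.loc[pid, "basal_area"] == pytest.approx(expected, rel=1e-9)
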