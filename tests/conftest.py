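import numpy as np
import pandas as pd
import pytest

from forestdyn import synthetic
from forestdyn.inventory import InventoryDataset


@pytest.fixture
def toy_dataset() -> InventoryDataset:
    """Two plots, two censuses, three trees; hand-checkable numbers."""
    trees = pd.DataFrame({
        "plot_id": ["A", "A", "B"],
        "census_id": ["c1", "c2", "c1"],
        "species_code": ["PA", "PA", "FS"],
        "dbh_cm": [20.0, 26.0, 55.0],
        "age_years": [60, 72, 140],
        "expansion_factor": [20.0, 20.0, 20.0],
    })
    plots = pd.DataFrame({
        "plot_id": ["A", "B"],
        "x_m": [0.0, 200.0], "y_m": [0.0, 100.0],
        "elevation_m": [1000.0, 1600.0],
        "aspect_class": ["N", "flat"],
        "zone": ["strict", "managed"],
        "sand_pct": [40.0, 50.0], "clay_pct": [20.0, 15.0],
        "soil_depth_cm": [30.0, 20.0],
        "soil_type": ["rendzina", "poor_brown"],
        "pnv_dominants": ["PA;FS", "PA"],
        "disturbed_p1": [False, True], "disturbed_p2": [False, False],
    })
    species = synthetic.SPECIES_TABLE.copy()
    return InventoryDataset((1984, 1996), trees, plots, species)


@pytest.fixture(scope="session")
def scene():
    """One default synthetic scene shared by read-only tests."""
    return synthetic.generate_scene(seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
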