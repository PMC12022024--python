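import numpy as np
import pandas as pd
import pytest

import paintplus as pp
from paintplus.simulate import FeatureSpec


SMALL_FEATURES = tuple(
    FeatureSpec(name, median=m, mad=s)
    for name, m, s in [
        ("DNA_nucleus_intensity_mean", 500.0, 50.0),
        ("Mito_cytoplasm_intensity_mean", 350.0, 45.0),
        ("Lyso_cytoplasm_intensity_mean", 200.0, 28.0),
        ("Actin_cell_intensity_mean", 280.0, 36.0),
    ]
)


@pytest.fixture(scope="session")
def reference_layout():
    layout = pp.generate_plate_layout(seed=1)
    layout.validate_reference_design()
    return layout


@pytest.fixture(scope="session")
def small_screen(reference_layout):
    """Small synthetic screen: 4 features, 20 cells/well, 3 biological reps."""
    truth = pp.default_ground_truth(
        reference_layout, features=SMALL_FEATURES,
        actives={"C01": "Lyso", "C02": "Actin", "C03": "Mito"},
        cytotox={"C05": 10.0}, seed=7)
    cells = pp.generate_feature_table(
        reference_layout, truth, features=SMALL_FEATURES,
        n_cells_per_well=20, n_biol_reps=3, seed=7)
    return cells


@pytest.fixture(scope="session")
def small_wells(small_screen):
    z = pp.robust_z_cells(small_screen)
    wells = pp.aggregate_to_wells(z)
    return pp.flag_cytotoxic(wells)
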