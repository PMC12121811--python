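import numpy as np
import pytest

import landcarbon as lc
from landcarbon.io import LandUseClass


@pytest.fixture(scope="session")
def table1():
    return lc.load_fixture("table1_accounts")


@pytest.fixture(scope="session")
def table2():
    return lc.load_fixture("table2_matrix")


@pytest.fixture
def toy_rasters():
    """The hand-enumerable 3x3 pair: epoch1 -> epoch2 with known flows."""
    classes = (
        LandUseClass(1, "cultivated"), LandUseClass(2, "forest"),
        LandUseClass(4, "grassland"),
    )
    e1 = lc.LandUseRaster(
        np.array([[1, 1, 2], [1, 2, 2], [4, 4, 4]]), cell_area_km2=1.0,
        classes=classes,
    )
    e2 = lc.LandUseRaster(
        np.array([[1, 2, 2], [1, 2, 2], [4, 4, 1]]), cell_area_km2=1.0,
        classes=classes,
    )
    return e1, e2


@pytest.fixture
def two_class_impact_toy():
    """S=(100,200) km², eff=(500,250) g/m², a(A,B)=0.1, a(B,A)=0.05."""
    import pandas as pd

    matrix = lc.TransitionMatrix(
        np.array([[0.9, 0.1], [0.05, 0.95]]), class_order=("A", "B")
    )
    areas = pd.Series({"A": 100.0, "B": 200.0})
    eff = pd.Series({"A": 500.0, "B": 250.0})
    return areas, eff, matrix
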