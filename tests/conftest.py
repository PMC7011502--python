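import numpy as np
import pytest
import shapely

from geomaskd.district_assignment import DistrictMap
from geomaskd.synthetic_data import SyntheticConfig, generate_country


@pytest.fixture(scope="session")
def grid_map() -> DistrictMap:
    """3x3 grid of 30 km districts around (34E, 15S)."""
    return generate_country(SyntheticConfig(grid_nx=3, grid_ny=3, cell_km=30.0, seed=0))


@pytest.fixture(scope="session")
def two_district_map() -> DistrictMap:
    """Two 30 km districts sharing a long vertical boundary."""
    return generate_country(SyntheticConfig(grid_nx=2, grid_ny=1, cell_km=30.0, seed=0))


@pytest.fixture(scope="session")
def toy_rect_map() -> DistrictMap:
    """Four axis-aligned unit rectangles in degrees, for planar oracles."""
    return DistrictMap(
        [
            ("R00", "R00", shapely.box(0.0, 0.0, 1.0, 1.0)),
            ("R01", "R01", shapely.box(1.0, 0.0, 2.0, 1.0)),
            ("R10", "R10", shapely.box(0.0, 1.0, 1.0, 2.0)),
            ("R11", "R11", shapely.box(1.0, 1.0, 2.0, 2.0)),
        ]
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
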