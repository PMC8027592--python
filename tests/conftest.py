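import numpy as np
import pytest

from snowrsf.raster import GridRaster


@pytest.fixture
def flat_grid():
    """60x60 grid of zeros at 100 m resolution, origin at (0, 0)."""
    return GridRaster(np.zeros((60, 60)), 0.0, 0.0, 100.0)


@pytest.fixture
def toy3x3():
    """3x3 raster with distinct hand-set values for covariate lookups."""
    vals = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [7.0, 8.0, 9.0]])
    return GridRaster(vals, 0.0, 0.0, 10.0)


@pytest.fixture(scope="session")
def small_landscape():
    """A compact synthetic study system shared by slower tests."""
    import snowrsf as s

    dem = s.generate_dem(48, 48, 100.0, seed=7)
    canopy = s.generate_canopy(dem, seed=7)
    valley = dem.like((dem.values < 1300).astype(float))
    sites = s.place_feeding_sites(12, valley, 300.0, seed=7)
    dist = s.path_distance_3d(dem, sites)
    daily, labels = s.generate_snow_days(dem, 2014, seed=7)
    snow = s.monthly_mean_snow(daily, labels)
    return {
        "dem": dem, "canopy": canopy, "valley": valley,
        "sites": sites, "dist": dist, "snow": snow,
        "daily": daily, "labels": labels,
    }
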