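import numpy as np
import pytest
import xarray as xr

from defocarb import (AGBClimateModel, SyntheticConfig,
                      generate_observation_bundle, generate_region_masks,
                      make_field)


@pytest.fixture(scope="session")
def default_cfg():
    return SyntheticConfig(seed=0)


@pytest.fixture(scope="session")
def bundle(default_cfg):
    return generate_observation_bundle(default_cfg)


@pytest.fixture(scope="session")
def masks(default_cfg):
    return generate_region_masks(default_cfg)


@pytest.fixture(scope="session")
def default_curve(bundle):
    return AGBClimateModel.from_bundle(bundle).fit_moving_window()


@pytest.fixture
def small_field():
    """3x4 field with a known linear surface, for regrid/stats tests."""
    lat = np.array([-1.0, 0.0, 1.0])
    lon = np.array([10.0, 11.0, 12.0, 13.0])
    vals = 2.0 * lat[:, None] + 3.0 * lon[None, :]
    return make_field(vals, lat, lon, "f", units="1")


def annual_series(values_per_year, lat=None, lon=None):
    """Stack per-year constants into a (year, lat, lon) DataArray."""
    lat = np.array([0.0, 1.0]) if lat is None else lat
    lon = np.array([0.0, 1.0]) if lon is None else lon
    arr = np.array([np.full((len(lat), len(lon)), v, dtype=float)
                    for v in values_per_year])
    return xr.DataArray(arr, coords={"year": np.arange(len(values_per_year)),
                                     "lat": lat, "lon": lon},
                        dims=("year", "lat", "lon"))
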