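import numpy as np
import pytest

from greenflux import synth
from greenflux.raster import Grid2D, LANDUSE_CLASSES, LandUseGrid


@pytest.fixture(scope="session")
def small_cfg() -> synth.SyntheticConfig:
    """Desk-scale domain: 16x16 pixels, one synthetic year."""
    return synth.SyntheticConfig(grid_rows=16, grid_cols=16,
                                 start_year=2025, end_year=2025, seed=42)


@pytest.fixture(scope="session")
def climate(small_cfg):
    return synth.synth_climate(small_cfg)


@pytest.fixture(scope="session")
def link() -> synth.GroundTruthLink:
    return synth.GroundTruthLink(ndvi_noise_sd=0.02)


@pytest.fixture(scope="session")
def ndvi(climate, link):
    return synth.synth_ndvi(climate, link, seed=7)


@pytest.fixture(scope="session")
def landuse_pair(small_cfg):
    return synth.synth_landuse_pair(small_cfg)


@pytest.fixture()
def grid_factory():
    def make(values, nodata=None, **kw):
        return Grid2D(values=np.asarray(values), nodata=nodata, **kw)
    return make


@pytest.fixture()
def landuse_factory():
    def make(codes):
        return LandUseGrid(grid=Grid2D(values=np.asarray(codes, dtype=np.int32)),
                           legend=dict(LANDUSE_CLASSES))
    return make
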