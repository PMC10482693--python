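import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from wuimap.grid import GridSpec, LandCover, Raster, RasterKind

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_grid(n_rows=50, n_cols=50, pixel_size=10.0, origin=(0.0, None)) -> GridSpec:
    origin_x, origin_y = origin
    if origin_y is None:
        origin_y = n_rows * pixel_size
    return GridSpec(
        origin_x=origin_x, origin_y=origin_y, pixel_size=pixel_size,
        n_rows=n_rows, n_cols=n_cols, crs_id="TEST",
    )


@pytest.fixture
def grid50() -> GridSpec:
    return make_grid()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240117)


def landcover_raster(grid: GridSpec, codes: np.ndarray) -> Raster:
    return Raster(grid, codes.astype(np.uint8), RasterKind.LAND_COVER)


def constant_raster(grid: GridSpec, value: float, kind=RasterKind.CONTINUOUS) -> Raster:
    return Raster(grid, np.full(grid.shape, value, dtype=float), kind)
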