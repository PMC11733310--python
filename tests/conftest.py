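import numpy as np
import pytest

from batscape import ActivityRaster, Grid, PresenceScene


@pytest.fixture
def grid() -> Grid:
    return Grid(nrows=6, ncols=5, pixel_size=70.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_scenes(values_list, grid: Grid):
    return [PresenceScene(values=v, grid=grid) for v in values_list]


@pytest.fixture
def random_raster(grid, rng) -> ActivityRaster:
    n_scenes = 40
    counts = rng.integers(0, n_scenes + 1, size=grid.shape)
    return ActivityRaster(counts=counts, grid=grid, n_nights=10, n_scenes=n_scenes)
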