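import numpy as np
import pytest

from vinecwsi import SceneConfig, generate_scene
from vinecwsi.geodata import GridTransform, RasterGrid


@pytest.fixture
def small_config():
    """Small but non-trivial scene: quick to generate, exercises every stage."""
    return SceneConfig(n_rows=2, plants_per_row=3, point_density=150.0,
                       ground_point_density=15.0, cell_size=0.5, seed=11)


@pytest.fixture
def small_scene(small_config):
    return generate_scene(small_config)


@pytest.fixture
def default_scene():
    return generate_scene(SceneConfig(seed=5))


@pytest.fixture
def unit_transform():
    return GridTransform(x0=0.0, y0=4.0, dx=1.0, dy=1.0)


def make_raster(values, transform=None, crs="TEST/metric", nodata=float("nan")):
    values = np.asarray(values, dtype=float)
    if transform is None:
        transform = GridTransform(x0=0.0, y0=values.shape[0] * 1.0, dx=1.0, dy=1.0)
    return RasterGrid(values=values, transform=transform, crs_label=crs, nodata=nodata)


@pytest.fixture
def raster_factory():
    return make_raster
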