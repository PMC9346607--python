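import numpy as np
import pytest

from resistweed.raster import Affine, RasterGrid
from resistweed.synthetic import SceneConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_scene_config():
    """A desk-sized scene: 2 m x 2 m at coarsened GSDs, deterministic."""
    return SceneConfig(
        seed=7, density="moderate", plot_width_m=2.0, plot_height_m=2.0,
        ms_gsd=2.0, rgb_gsd=1.0,
    )


@pytest.fixture
def reflectance_grid(rng):
    """Random 5-band reflectance raster with a couple of nodata pixels."""
    vals = rng.uniform(0.01, 0.9, size=(5, 12, 10))
    vals[:, 0, 0] = np.nan
    return RasterGrid(
        values=vals,
        band_roles=("B", "G", "R", "RE", "NIR"),
        gsd=1.0,
        transform=Affine.north_up(0.0, 12.0, 1.0),
        value_kind="reflectance",
    )
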