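import numpy as np
import pytest

from greenexpo import Georef, Raster, SceneConfig, generate_city_scene
from greenexpo.grids import CityMask


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture(scope="session")
def clean_scene():
    """Small noiseless, cloud-free scene: downstream stages are exact."""
    cfg = SceneConfig(grid_rows=30, grid_cols=30, cloud_prob=0.0, noise_sd=0.0, seed=3)
    stacks, truth, mask = generate_city_scene(cfg)
    return cfg, stacks, truth, mask


@pytest.fixture(scope="session")
def default_scene():
    """Default study conditions: clouds and reflectance noise on."""
    cfg = SceneConfig(seed=5)
    stacks, truth, mask = generate_city_scene(cfg)
    return cfg, stacks, truth, mask


def make_raster(data, cell=100.0, year=None):
    data = np.asarray(data, dtype=float)
    return Raster(data, Georef(0.0, data.shape[0] * cell, cell), year)


def full_mask(raster):
    return CityMask(np.ones(raster.shape, bool), raster.georef)


@pytest.fixture
def raster_factory():
    return make_raster


@pytest.fixture
def mask_factory():
    return full_mask
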