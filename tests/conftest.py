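import numpy as np
import pytest

from canopystack.grids import GridSpec, Raster
from canopystack.synthdata import simulate_gaussian_field
from canopystack.variogram import VariogramModel


@pytest.fixture
def small_grid():
    return GridSpec(0.0, 0.0, 30.0, 20, 20)


@pytest.fixture
def spherical_model():
    return VariogramModel("spherical", 0.05, 1.0, 300.0)


@pytest.fixture
def gaussian_field(small_grid, spherical_model):
    return simulate_gaussian_field(small_grid, spherical_model, mean=10.0, seed=42)


@pytest.fixture
def scattered_obs():
    """Random points with a smooth deterministic surface value."""
    rng = np.random.default_rng(5)
    xy = rng.uniform(0, 600, (80, 2))
    z = np.sin(xy[:, 0] / 150.0) + 0.5 * np.cos(xy[:, 1] / 120.0)
    return xy, z
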