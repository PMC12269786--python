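import numpy as np
import pytest

from cachalot.synth import synth_bathymetry, synth_survey


@pytest.fixture(scope="session")
def shelf_grid():
    """Default shelf–slope bathymetry shared across tests."""
    grid, coastline = synth_bathymetry(120, 100, 250.0, seed=1)
    return grid, coastline


@pytest.fixture(scope="session")
def small_scene(shelf_grid):
    """A small noiseless survey scene (5 aggregations) with full truth."""
    grid, _ = shelf_grid
    return synth_survey(5, grid=grid, seed=11, n_individuals=16)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
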