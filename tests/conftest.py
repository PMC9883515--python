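import numpy as np
import pytest

from minflow import Grid, get_parameter_set


@pytest.fixture(scope="session")
def params():
    """Default full-model parameter set at a mid-range E:D ratio."""
    return get_parameter_set("denk2d")


@pytest.fixture(scope="session")
def grid1d():
    return Grid.line(256.0, 128)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_state(params, grid, rng, scale=None):
    """Random strictly positive FieldState on the grid."""
    from minflow.state import FieldState
    scale = scale or max(params.n_D_mean, 1.0) / 6.0
    a = rng.uniform(0.1, 1.0, size=(6, *grid.shape)) * scale
    return FieldState.from_array(a)
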