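import numpy as np
import pytest

from coastmap import GridGeometry, SimulationConfig, default_legend


@pytest.fixture(scope="session")
def legend():
    return default_legend()


@pytest.fixture
def small_config():
    """A fast, fully-featured simulation config for unit tests."""
    return SimulationConfig(nrows=80, ncols=80, seed=7)


@pytest.fixture
def geom_small():
    return GridGeometry(nrows=20, ncols=20, pixel_size=2.0)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
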