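import numpy as np
import pytest

from cropsuit.grids import GridSpec
from cropsuit.synthetic import LandscapeConfig, generate_landscape


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_grid():
    return GridSpec(origin_lon=-60.0, origin_lat=0.0, cell_size=0.5, n_rows=4, n_cols=5)


@pytest.fixture(scope="session")
def landscape():
    """One default 20x20 landscape shared across tests (seed 7)."""
    return generate_landscape(LandscapeConfig(seed=7))
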