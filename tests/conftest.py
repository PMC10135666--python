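import numpy as np
import pytest

from larvahsi import GridSpec, SyntheticConfig, reference_curves


@pytest.fixture
def grid():
    """Study-area grid used throughout: 113-115 E, 21-23 N at 0.25 deg."""
    return GridSpec(lon_origin=113.0, lat_origin=21.0, cell_size=0.25,
                    n_lon=8, n_lat=8)


@pytest.fixture(scope="session")
def published_curves():
    """The 15 published Gaussian SI curves (month x variable)."""
    return reference_curves()


@pytest.fixture
def synthetic_config():
    return SyntheticConfig(seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
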