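import numpy as np
import pytest

from bphvib import PopulationParams

SR = 8000


@pytest.fixture
def pop():
    """Default population parameters (reported field statistics)."""
    return PopulationParams()


@pytest.fixture
def quiet_pop():
    """Population parameters with background noise disabled."""
    return PopulationParams(noise_snr_db=None)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
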