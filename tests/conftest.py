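import numpy as np
import pytest

from fluctevo.synthetic_data import default_strain


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def strain():
    return default_strain("606P")


@pytest.fixture
def noiseless_strain():
    return default_strain("606P", od_noise_sd=0.0)
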