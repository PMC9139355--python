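import numpy as np
import pytest

from phymri.cohort import AcquisitionConfig, default_profiles, simulate_case


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture(scope="session")
def noiseless_config():
    return AcquisitionConfig(shape=(36, 36, 14), spacing=(1.0, 1.0, 3.0),
                             noise_sigma=0.0)


@pytest.fixture(scope="session")
def noisy_config():
    return AcquisitionConfig(shape=(36, 36, 14), spacing=(1.0, 1.0, 3.0))


@pytest.fixture(scope="session")
def noiseless_case(profiles, noiseless_config):
    return simulate_case(profiles["GBM"], noiseless_config, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
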