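import numpy as np
import pytest

from promkin import synthetic_data as sd


@pytest.fixture(scope="session")
def scenario():
    return sd.default_scenario(seed=0)


@pytest.fixture(scope="session")
def noisefree_dataset(scenario):
    """Analysis-level dataset with noise-free targets and protein regressors."""
    return sd.make_fit_dataset(scenario, regressors="proteins", noise_rel=0.0)


@pytest.fixture(scope="session")
def noisy_dataset(scenario):
    """Dataset at the study-like noise level (smooth replicate spread)."""
    return sd.make_fit_dataset(scenario, regressors="proteins", noise_rel=0.05, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
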