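import numpy as np
import pytest

from fcgam.regression import fit_mle
from fcgam.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def study1_data():
    """One study-1 dataset (n=500, theta=-1) with its truth sidecar."""
    return simulate_dataset(SimConfig.study1(theta0=-1.0, n=500, seed=7))


@pytest.fixture(scope="session")
def study1_fit(study1_data):
    """Constant-theta fit of the study-1 dataset, shared across tests."""
    data, _ = study1_data
    return fit_mle(data, data.default_spec("constant"), seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
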