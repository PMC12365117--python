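import numpy as np
import pytest

from chronode.simulate import DEFAULT_TIMES, SimulationSpec, simulate_logistic_matrix


@pytest.fixture(scope="session")
def times():
    return np.asarray(DEFAULT_TIMES)


@pytest.fixture(scope="session")
def noiseless_sim():
    """Small zero-noise logistic simulation shared across tests."""
    spec = SimulationSpec(seed=3, n_features=25, noise_sd_fraction=0.0)
    return simulate_logistic_matrix(spec)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
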