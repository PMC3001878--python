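import numpy as np
import pytest

from metabayes import (
    InversionOptions,
    ParameterPrior,
    SimulationConfig,
    ToyObserverConfig,
    simulate_observer,
    toy_perceptual_model,
    toy_response_model,
)


@pytest.fixture
def toy_config():
    """Study-condition observer: beta=2, k=0.01 (optimal n = 8), sigma=0.05."""
    return ToyObserverConfig(beta=2.0, k=0.01, sigma2=0.05**2)


@pytest.fixture
def toy_models(toy_config):
    return toy_perceptual_model(), toy_response_model(toy_config)


@pytest.fixture
def wide_prior():
    """Proper but weakly informative prior on (log beta, log k)."""
    return ParameterPrior(mean=np.zeros(2), covariance=np.diag([100.0, 100.0]),
                          names=("log_beta", "log_k"))


@pytest.fixture
def toy_data(toy_config):
    return simulate_observer(SimulationConfig(observer=toy_config, n_trials=60, seed=7))


@pytest.fixture
def fast_options():
    """Fewer starts for unit tests; acceptance tests use the defaults."""
    return InversionOptions(n_starts=2, seed=0, store_beliefs=False)
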