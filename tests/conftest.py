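import numpy as np
import pytest

from jointfc import ChainSettings, LinkFunction, ModelHyperparameters


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def hyper():
    """Default hyperparameters of the joint model."""
    return ModelHyperparameters()


@pytest.fixture
def constant_hyper():
    """Constant-link model: posterior factorizes into Beta x Dirichlet."""
    return ModelHyperparameters(link=LinkFunction(family="constant"))


@pytest.fixture
def fast_settings():
    """Short chains for unit tests that only need a working sampler."""
    return ChainSettings(n_iterations=2000, n_burnin=500, thin=10, seed=42)
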