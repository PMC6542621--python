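import numpy as np
import pytest
from hypothesis import settings

from memnet import build_parameters, build_layout, derive_constants
from memnet.network import init_state

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_params():
    return build_parameters({})


@pytest.fixture(scope="session")
def default_consts(default_params):
    return derive_constants(default_params)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_params():
    """A 10-neuron network for cheap dynamical tests."""
    return build_parameters({"n": 10, "n_P": 3, "n_Pex": 3})


@pytest.fixture
def small_state(small_params, rng):
    layout = build_layout(small_params)
    return layout, init_state(small_params, layout, rng)
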