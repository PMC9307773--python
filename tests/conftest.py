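import numpy as np
import pytest

from biofiltersim import preset


@pytest.fixture(scope="session")
def params_two_states():
    return preset("two_steady_states")


@pytest.fixture(scope="session")
def params_ramp():
    return preset("steady_increase")


@pytest.fixture(scope="session")
def params_experiment():
    return preset("biofilter_experiment")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
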