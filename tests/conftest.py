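import numpy as np
import pytest

from komaflux.network import load_fixture_model
from komaflux.synth import toy_branch_network, toy_branch_tracer


@pytest.fixture(scope="session")
def fixture_model():
    return load_fixture_model()


@pytest.fixture(scope="session")
def toy_net():
    return toy_branch_network()


@pytest.fixture(scope="session")
def toy_tracer():
    return toy_branch_tracer()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
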