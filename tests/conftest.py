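import numpy as np
import pytest

from motorlattice.parameters import get_preset


@pytest.fixture(scope="session")
def kinesin():
    return get_preset("kinesin1-processive")


@pytest.fixture(scope="session")
def ncd():
    return get_preset("ncd")


@pytest.fixture(scope="session")
def axonal():
    return get_preset("kinesin1-axonal")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
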