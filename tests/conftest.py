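import numpy as np
import pytest

from dbcnet import params as P
from dbcnet.network import NetworkSpec, build


@pytest.fixture(scope="session")
def dbc():
    return P.DBC


@pytest.fixture(scope="session")
def default_network():
    return build(NetworkSpec(rng_seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
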