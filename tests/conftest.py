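import numpy as np
import pytest

from segevo.fly import make_fly_network
from segevo.solver import steady_state


@pytest.fixture(scope="session")
def fly():
    return make_fly_network()


@pytest.fixture(scope="session")
def fly_ss(fly):
    return steady_state(fly)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
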