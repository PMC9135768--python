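import numpy as np
import pytest

from tadgaze import circuit_model as cm


@pytest.fixture(scope="session")
def default_network():
    return cm.build_default_network()


@pytest.fixture(scope="session")
def swim_sim(default_network):
    """One reference simulation (0.15 nA, 5 s) shared across tests."""
    return cm.simulate(default_network,
                       [cm.step_into_dins(0.15, duration_s=5.0)], 5.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
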