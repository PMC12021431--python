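import numpy as np
import pytest

import spikecode as sc


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def sos_stimulus():
    """A short 4+20 Hz sum-of-sines trace shared across tests."""
    return sc.generate_stimulus("sum_of_sines", 2000, seed=0, flow=4, fhigh=20)


@pytest.fixture(scope="session")
def small_net():
    return sc.build_network([8, 6, 4], seed=3)


@pytest.fixture(scope="session")
def trained_small(sos_stimulus):
    """A small trained 3-layer network (shared; training is deterministic)."""
    net = sc.build_network([20, 8, 12], seed=1)
    return sc.train_network(net, sos_stimulus,
                            training=sc.TrainingConfig(n_iter=60, seed=1))
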