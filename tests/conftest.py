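import numpy as np
import pytest

from sdqn.lif import LIFParams
from sdqn.network import ConvSpec, SpikingQNetwork


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def lif():
    return LIFParams(tau=2.0, v_th=0.5, v_reset=0.0)


@pytest.fixture
def tiny_net(lif):
    """Small conv+fc network for fast forward/backward tests."""
    net = SpikingQNetwork(
        input_shape=(2, 8, 8),
        conv=[ConvSpec(4, 3, 2), ConvSpec(3, 2, 1)],
        fc_hidden=6,
        n_actions=3,
        T=4,
        lif=lif,
        pbln=True,
    )
    net.init_weights(np.random.default_rng(7), scheme="gaussian", weight_var=0.3)
    return net
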