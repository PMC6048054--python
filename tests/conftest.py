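import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def flatten_params(params):
    return np.concatenate([p.ravel() for p in params])


def set_flat_params(net, flat):
    params = net.params
    out = []
    i = 0
    for p in params:
        out.append(np.asarray(flat[i : i + p.size]).reshape(p.shape))
        i += p.size
    net.set_params(out)
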