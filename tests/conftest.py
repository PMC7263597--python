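import numpy as np
import pytest

import horstein as H


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def uniform_state():
    return H.init_decoder(H.DecoderConfig(k=6, f0p=0.1, f1p=0.1))


def make_state(k=6, beta=0.0, f0p=0.1, f1p=0.1, prior=None):
    return H.init_decoder(H.DecoderConfig(k=k, beta=beta, f0p=f0p, f1p=f1p,
                                          prior=prior))


@pytest.fixture
def make_decoder():
    return make_state
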