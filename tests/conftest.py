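import numpy as np
import pytest

import stereomantis as sm


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_net():
    """A quickly trained network for qualitative plumbing tests."""
    return sm.train_saccade_network(preset="tiny", seed=7)


@pytest.fixture(scope="session")
def scaled_net():
    """The scaled-down preset network used for behavioural contracts.

    Trained once per session; several minutes on one CPU.
    """
    return sm.train_saccade_network(preset="scaled_down", seed=1)
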