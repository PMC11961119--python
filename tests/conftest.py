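import numpy as np
import pytest

from photoavoid import synth
from photoavoid.session_io import SessionConfig


@pytest.fixture(scope="session")
def avoidance_session():
    """One small, fully simulated avoidance session with ground truth."""
    cfg = SessionConfig(task="avoidance", n_trials=10, habituation_s=60.0)
    return synth.generate_session(cfg, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
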