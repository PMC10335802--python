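import numpy as np
import pytest

from eegloop.streams import SampleBlock
from eegloop.synth import SynthConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def config():
    """Small, fast synthetic-EEG configuration."""
    return SynthConfig(fs=256.0, n_channels=4, seed=7)


@pytest.fixture
def white_block(rng):
    """10 s of 4-channel white noise at 256 Hz."""
    fs = 256.0
    n = int(10 * fs)
    return SampleBlock(np.arange(n) / fs, rng.standard_normal((n, 4)))


def random_spd(rng, n, scale=1.0):
    """Random SPD matrix: A A^T + eps I."""
    A = rng.standard_normal((n, n))
    return scale * (A @ A.T + n * np.eye(n))
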