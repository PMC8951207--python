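import numpy as np
import pytest

from plinet.montage import Montage, default_montage
from plinet.preprocess import DEFAULT_BANDS, Recording


@pytest.fixture(scope="session")
def montage():
    return default_montage()


@pytest.fixture(scope="session")
def beta2():
    return DEFAULT_BANDS["beta2"]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_recording(data, fs=512.0, labels=None, neighbors=None):
    """Small helper: wrap an array in a Recording with an ad-hoc montage."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if labels is None:
        labels = [f"CH{i}" for i in range(data.shape[0])]
    if neighbors is None:
        neighbors = {}
    return Recording(data, fs, Montage(labels, neighbors))


@pytest.fixture(scope="session")
def sine_recording(montage):
    """20-channel recording: 10 Hz sine on all channels, 4 s at 512 Hz."""
    t = np.arange(4 * 512) / 512.0
    data = np.tile(np.sin(2 * np.pi * 10 * t), (20, 1))
    return Recording(data, 512.0, montage)
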