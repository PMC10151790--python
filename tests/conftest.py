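import numpy as np
import pytest

from earfeast.spikes import EventStream


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_stream(rng, n_channels=8, rate=0.05, n_samples=2000, fs=16000.0):
    """Random sparse spike raster with at most one spike per (t, channel)."""
    mask = rng.random((n_samples, n_channels)) < rate
    t, ch = np.nonzero(mask)
    return EventStream(t, ch, fs=fs, n_channels=n_channels, duration=n_samples)


@pytest.fixture
def stream(rng):
    return random_stream(rng)
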