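import numpy as np
import pytest

from organoid_mea.io import Recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_tone_recording(freqs_amps, fs_hz=1000.0, duration_s=20.0,
                        n_channels=1, noise_sd=0.0, seed=0):
    """Recording whose channels are identical sums of tones (plus noise)."""
    rng = np.random.default_rng(seed)
    t = np.arange(int(round(duration_s * fs_hz))) / fs_hz
    x = np.zeros_like(t)
    for f, a in freqs_amps:
        x = x + a * np.cos(2 * np.pi * f * t)
    data = np.tile(x, (n_channels, 1))
    if noise_sd > 0:
        data = data + rng.normal(0, noise_sd, data.shape)
    return Recording(data, fs_hz)


@pytest.fixture
def tone_recording():
    return make_tone_recording
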