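import numpy as np
import pytest

from netdyn import MultichannelRecording

FS = 512.0


@pytest.fixture
def fs():
    return FS


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_recording(data, fs=FS, channels=None, meta=None):
    data = np.atleast_2d(np.asarray(data, float))
    if data.shape[0] < data.shape[1]:
        data = data.T
    if channels is None:
        channels = [f"ch{i}" for i in range(data.shape[1])]
    return MultichannelRecording(data, fs, channels, meta or {})


@pytest.fixture
def sine_recording():
    """1-channel 64-s recording: 3 µV·sin(2π·10t)."""
    t = np.arange(int(FS * 64)) / FS
    return make_recording(3.0 * np.sin(2 * np.pi * 10 * t))


@pytest.fixture
def white_recording(rng):
    """2-channel independent white-noise recording, 200 s."""
    return make_recording(rng.standard_normal((int(FS * 200), 2)))
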