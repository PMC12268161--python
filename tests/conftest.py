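import numpy as np
import pytest

from adbskit.signal_io import TimeSeries


@pytest.fixture
def sine_500hz():
    """Unit 15 Hz sinusoid, 20 s at 500 Hz."""
    fs = 500.0
    t = np.arange(int(20 * fs)) / fs
    return TimeSeries(values=np.sin(2 * np.pi * 15.0 * t), rate=fs)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
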