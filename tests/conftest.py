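import numpy as np
import pytest

from penpulse.preprocess import MagnitudeTrace


@pytest.fixture()
def rng():
    return np.random.default_rng(20240331)


def sinusoid_trace(freq_hz, duration, fs=100.0, amplitude=1.0, stage="filtered"):
    t = np.arange(int(round(duration * fs)) + 1) / fs
    return MagnitudeTrace(t=t, a=amplitude * np.sin(2 * np.pi * freq_hz * t), fs=fs, stage=stage)
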