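import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from plscan.record import TimeSeriesRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_tone_record(freq, fs=600.0, duration=10.0, amplitude=1.0, n_channels=1,
                     phase=0.0):
    t = np.arange(int(round(duration * fs))) / fs
    x = amplitude * np.cos(2 * np.pi * freq * t + phase)
    data = np.tile(x, (n_channels, 1))
    return TimeSeriesRecord(data=data, fs=fs,
                            labels=[f"ch{i}" for i in range(n_channels)])


def make_noise_record(rng, fs=600.0, duration=10.0, n_channels=1, sd=1.0):
    n = int(round(duration * fs))
    data = rng.normal(0.0, sd, size=(n_channels, n))
    return TimeSeriesRecord(data=data, fs=fs,
                            labels=[f"ch{i}" for i in range(n_channels)])


@pytest.fixture
def tone_record():
    return make_tone_record


@pytest.fixture
def noise_record():
    return make_noise_record
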