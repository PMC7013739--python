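import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from pulseaf import (
    BeatSeries,
    RhythmConfig,
    WaveformSignal,
    generate_rhythm,
    render_waveform,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def random_ibi_series(rng):
    """A plausible random IBI series (seconds) of moderate length."""
    return rng.normal(0.8, 0.08, size=60).clip(0.3, 1.5)


@pytest.fixture
def nsr_signal():
    """One clean NSR minute at 100 Hz with its ground truth."""
    config = RhythmConfig(
        "NSR", mean_hr=65, rr_cv=0.04, resp_mod_depth=0.05, resp_freq=0.25,
        duration=60, seed=42,
    )
    truth = generate_rhythm(config)
    return render_waveform(truth, 100.0), truth


@pytest.fixture
def af_signal():
    """One clean AF minute at 100 Hz with its ground truth."""
    config = RhythmConfig("AF", mean_hr=90, rr_cv=0.25, duration=60, seed=43)
    truth = generate_rhythm(config)
    return render_waveform(truth, 100.0), truth


def make_beat_series(times, fs=100.0):
    return BeatSeries.from_times(np.asarray(times, dtype=float), fs)


def make_signal(samples, fs=100.0):
    return WaveformSignal(np.asarray(samples, dtype=float), fs)
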