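"""Signal conditioning: Newton-interpolation resampling, Butterworth band-pass,
percentile amplitude normalization.

The pipeline order is fixed: resample -> band-pass -> normalize. Band-passing
precedes normalization so that the percentile is taken on a baseline-free
signal.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .containers import WaveformSignal
from .errors import ConfigurationError, SignalError


@dataclass(frozen=True)
class PreprocessConfig:
    """Conditioning parameters.

    Defaults are conventional pulse-waveform choices: 100 Hz target rate,
    0.5-8 Hz pass band (removes baseline wander, keeps pulse harmonics up to
    ~240 bpm's 2nd harmonic), 4th-order Butterworth applied forward-backward,
    and normalization by the 97th percentile of the filtered amplitudes.
    """

    target_fs: float = 100.0
    band_low: float = 0.5
    band_high: float = 8.0
    filter_order: int = 4
    norm_percentile: float = 97.0

    def __post_init__(self) -> None:
        if not (0 < self.band_low < self.band_high < self.target_fs / 2):
            raise ConfigurationError(
                f"need 0 < band_low < band_high < target_fs/2, got "
                f"({self.band_low}, {self.band_high}) at {self.target_fs} Hz"
            )
        if not (0 < self.norm_percentile <= 100):
            raise ConfigurationError("norm_percentile must be in (0, 100]")
        if self.filter_order < 1:
            raise ConfigurationError("filter_order must be >= 1")


def resample(signal: WaveformSignal, target_fs: float) -> WaveformSignal:
    """Resample to ``target_fs`` by local Newton divided-difference interpolation.

    Each output instant is evaluated with a degree-3 Newton polynomial over
    the 4 nearest input samples (stencil clamped at the edges). The record
    duration is preserved to within one output sample.
    """
    if not target_fs > 0:
        raise ConfigurationError(f"target_fs must be positive, got {target_fs}")
    x = signal.samples
    n = x.size
    if n < 4:
        raise SignalError("Newton resampling needs at least 4 input samples")
    if target_fs == signal.fs:
        return replace(signal, samples=x.copy())
    fs_in = signal.fs
    duration = (n - 1) / fs_in
    n_out = int(np.floor(duration * target_fs + 1e-9)) + 1
    t_out = np.arange(n_out) / target_fs
    # stencil start: interval index j with t in [t_j, t_{j+1}), then [j-1, j+2]
    j = np.clip(np.floor(t_out * fs_in).astype(int), 0, n - 2)
    i0 = np.clip(j - 1, 0, n - 4)
    idx = i0[:, None] + np.arange(4)
    xs = idx / fs_in                      # stencil abscissae
    ys = x[idx]                           # stencil ordinates
    # divided-difference table (vectorized over output points)
    d1 = (ys[:, 1:] - ys[:, :-1]) / (xs[:, 1:] - xs[:, :-1])
    d2 = (d1[:, 1:] - d1[:, :-1]) / (xs[:, 2:] - xs[:, :-2])
    d3 = (d2[:, 1:] - d2[:, :-1]) / (xs[:, 3:] - xs[:, :-3])
    dt0 = t_out - xs[:, 0]
    dt1 = t_out - xs[:, 1]
    dt2 = t_out - xs[:, 2]
    out = ys[:, 0] + d1[:, 0] * dt0 + d2[:, 0] * dt0 * dt1 + d3[:, 0] * dt0 * dt1 * dt2
    return WaveformSignal(out, target_fs, record_id=signal.record_id)


def bandpass(signal: WaveformSignal, low: float, high: float, order: int = 4) -> WaveformSignal:
    """Zero-phase Butterworth band-pass (forward-backward), length preserving."""
    nyq = signal.fs / 2
    if not (0 < low < high < nyq):
        raise ConfigurationError(
            f"band ({low}, {high}) Hz must satisfy 0 < low < high < Nyquist ({nyq} Hz)"
        )
    sos = sps.butter(order, [low, high], btype="bandpass", fs=signal.fs, output="sos")
    out = sps.sosfiltfilt(sos, signal.samples)
    return replace(signal, samples=out)


def normalize(signal: WaveformSignal, percentile: float = 97.0) -> WaveformSignal:
    """Divide the signal by the given percentile of its values.

    The percentile is the linear-interpolated order statistic of the raw
    (signed) sample values. Scale-invariant: ``normalize(c*x) == normalize(x)``
    for any c > 0, and idempotent.
    """
    if not (0 < percentile <= 100):
        raise ConfigurationError("percentile must be in (0, 100]")
    scale = float(np.percentile(signal.samples, percentile))
    if scale <= 0:
        raise SignalError(
            f"cannot normalize: {percentile}th percentile is {scale:.3g} (<= 0); "
            "signal may be unfiltered or degenerate"
        )
    return replace(signal, samples=signal.samples / scale)


def preprocess(signal: WaveformSignal, config: PreprocessConfig | None = None) -> WaveformSignal:
    """Full conditioning chain: resample -> band-pass -> normalize."""
    config = config or PreprocessConfig()
    out = resample(signal, config.target_fs)
    out = bandpass(out, config.band_low, config.band_high, config.filter_order)
    return normalize(out, config.norm_percentile)
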