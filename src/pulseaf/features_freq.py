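"""Frequency-domain HRV features from the evenly resampled IBI tachogram.

The IBI series is interpolated onto a uniform grid (default 4 Hz), mean
removed, and a one-sided FFT periodogram is integrated over the standard HRV
bands: VLF 0.0033-0.04 Hz, LF 0.04-0.15 Hz, HF 0.15-0.4 Hz (half-open
``[low, high)`` bins, so band sums are exact). ULF is unresolvable in a
one-minute window and is not extracted.

The 8 features: MaxPeak (power of the dominant in-band bin), TPW (total
power 0.0033-0.4 Hz), SpEn (normalized spectral entropy in [0, 1]), VLF, LF,
HF band powers, MeanFFT and STDFFT (mean / population std of the in-band
spectral magnitudes, i.e. square roots of the periodogram values).
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import interpolate, signal as sps

from .containers import BeatSeries, WaveformSignal
from .errors import InsufficientBeatsError, SignalError

logger = logging.getLogger(__name__)

FREQ_FEATURE_NAMES = ("MaxPeak", "TPW", "SpEn", "VLF", "LF", "HF", "MeanFFT", "STDFFT")

VLF_BAND = (0.0033, 0.04)
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.4)
TOTAL_BAND = (VLF_BAND[0], HF_BAND[1])


def ibi_tachogram(series: BeatSeries, fs_tach: float = 4.0) -> WaveformSignal:
    """Interpolate the IBI series onto a uniform grid and remove its mean.

    Each interval is placed at the time of its closing peak and cubically
    interpolated (order reduced when fewer than 4 intervals are available).
    Output length is ``round(fs_tach * span) + 1`` over the span of interval
    times.
    """
    if series.n_beats < 4:
        raise InsufficientBeatsError(f"tachogram needs >= 4 beats, got {series.n_beats}")
    t = series.peak_times[1:]
    v = series.ibis
    span = t[-1] - t[0]
    n = int(round(fs_tach * span)) + 1
    grid = np.minimum(t[0] + np.arange(n) / fs_tach, t[-1])
    kind = "cubic" if v.size >= 4 else "quadratic"
    y = interpolate.interp1d(t, v, kind=kind)(grid)
    return WaveformSignal(y - np.mean(y), fs_tach)


def power_spectrum(tachogram: WaveformSignal) -> tuple[np.ndarray, np.ndarray]:
    """One-sided FFT periodogram with density normalization.

    Satisfies Parseval: ``sum(power) * df`` equals the time-domain mean
    square (variance, for a mean-removed tachogram).
    """
    if len(tachogram) < 8:
        raise SignalError("power spectrum needs at least 8 tachogram samples")
    freqs, power = sps.periodogram(
        tachogram.samples, fs=tachogram.fs, window="boxcar", detrend=False
    )
    return freqs, power


def extract_frequency_features(series: BeatSeries, fs_tach: float = 4.0) -> dict[str, float]:
    """Compute all 8 frequency-domain features of a beat series."""
    tach = ibi_tachogram(series, fs_tach=fs_tach)
    freqs, power = power_spectrum(tach)
    df = freqs[1] - freqs[0]

    def band_power(lo: float, hi: float) -> float:
        mask = (freqs >= lo) & (freqs < hi)
        return float(np.sum(power[mask]) * df)

    in_band = (freqs >= TOTAL_BAND[0]) & (freqs < TOTAL_BAND[1])
    p_in = power[in_band]
    if p_in.size and np.sum(p_in) > 0:
        max_idx = int(np.argmax(p_in))
        max_peak = float(p_in[max_idx])
        logger.debug("dominant spectral peak at %.4f Hz", freqs[in_band][max_idx])
        p_norm = p_in[p_in > 0] / np.sum(p_in)
        spen = float(-np.sum(p_norm * np.log(p_norm)) / np.log(p_in.size)) if p_in.size > 1 else 0.0
        magnitudes = np.sqrt(p_in)
        mean_fft = float(np.mean(magnitudes))
        std_fft = float(np.std(magnitudes))
    else:  # zero-power spectrum: entropy and magnitudes carry no information
        max_peak = spen = mean_fft = std_fft = 0.0
    return {
        "MaxPeak": max_peak,
        "TPW": band_power(*TOTAL_BAND),
        "SpEn": spen,
        "VLF": band_power(*VLF_BAND),
        "LF": band_power(*LF_BAND),
        "HF": band_power(*HF_BAND),
        "MeanFFT": mean_fft,
        "STDFFT": std_fft,
    }
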