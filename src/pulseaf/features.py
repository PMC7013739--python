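"""Canonical 27-feature registry and whole-window extraction.

The feature vector of a one-minute window concatenates 13 time-domain,
8 frequency-domain and 6 time-frequency features, in that order.
"""

from __future__ import annotations

from .beats import detect_peaks
from .containers import BeatSeries, WaveformSignal
from .features_freq import FREQ_FEATURE_NAMES, extract_frequency_features
from .features_time import TIME_FEATURE_NAMES, extract_time_features
from .features_wavelet import WAVELET_FEATURE_NAMES, extract_wavelet_features

#: All 27 canonical feature names, in registry order.
FEATURE_NAMES: tuple[str, ...] = TIME_FEATURE_NAMES + FREQ_FEATURE_NAMES + WAVELET_FEATURE_NAMES

#: Name of the binary target column (1 = AF present, 0 = absent).
TARGET_NAME = "Vt"


def extract_features(
    signal: WaveformSignal,
    threshold_percentile: float = 88.0,
    min_distance: float = 0.25,
    sampen_m: int = 2,
    sampen_r_fraction: float = 0.2,
    she_bins: int = 16,
    fs_tach: float = 4.0,
    wavelet_name: str = "db4",
    beat_series: BeatSeries | None = None,
) -> dict[str, float]:
    """Extract all 27 features of one preprocessed window.

    Beats are detected on the window itself unless a precomputed
    ``beat_series`` is supplied. Raises the underlying detection/length
    errors for windows with too few beats.
    """
    series = beat_series if beat_series is not None else detect_peaks(
        signal, threshold_percentile=threshold_percentile, min_distance=min_distance
    )
    out = extract_time_features(
        series.ibis, m=sampen_m, r_fraction=sampen_r_fraction, n_bins=she_bins
    )
    out.update(extract_frequency_features(series, fs_tach=fs_tach))
    out.update(extract_wavelet_features(signal, wavelet_name))
    return out
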