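"""Pulse peak detection and interbeat-interval extraction.

Peaks are local maxima whose amplitude exceeds a window-local percentile
threshold (default 88th), with a refractory merge rule: of any two candidate
peaks closer than ``min_distance`` only the taller survives (ties: earlier).
"""

from __future__ import annotations

import numpy as np

from .containers import REFRACTORY_S, BeatSeries, WaveformSignal
from .errors import InsufficientBeatsError


def _local_maxima(x: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima; plateaus contribute their first sample.

    Edge samples are excluded (they lack two neighbours).
    """
    n = x.size
    out = []
    i = 1
    while i < n - 1:
        if x[i] > x[i - 1]:
            j = i
            while j < n - 1 and x[j + 1] == x[i]:
                j += 1
            if j < n - 1 and x[j + 1] < x[i]:
                out.append(i)
            i = j + 1
        else:
            i += 1
    return np.asarray(out, dtype=int)


def detect_peaks(
    signal: WaveformSignal,
    threshold_percentile: float = 88.0,
    min_distance: float = REFRACTORY_S,
) -> BeatSeries:
    """Detect pulse peaks above the window-local percentile threshold.

    Parameters
    ----------
    signal : WaveformSignal
        A (preferably preprocessed) pulse waveform.
    threshold_percentile : float
        Amplitude threshold as a percentile of this window's values; peaks
        must exceed it strictly. Being a percentile, detection is invariant
        to positive rescaling of the signal.
    min_distance : float
        Refractory spacing in seconds; of two closer candidates the taller
        (ties: earlier) is kept. Default 0.25 s (~240 bpm ceiling).

    Raises
    ------
    InsufficientBeatsError
        If fewer than 2 peaks survive.
    """
    x = signal.samples
    threshold = np.percentile(x, threshold_percentile)
    candidates = _local_maxima(x)
    candidates = candidates[x[candidates] > threshold]
    # greedy refractory suppression: tallest first, earlier wins ties
    order = np.lexsort((candidates, -x[candidates]))
    min_gap = min_distance * signal.fs
    kept: list[int] = []
    for c in candidates[order]:
        if all(abs(c - k) >= min_gap for k in kept):
            kept.append(int(c))
    if len(kept) < 2:
        raise InsufficientBeatsError(
            f"only {len(kept)} peak(s) above the {threshold_percentile}th percentile; "
            "need at least 2 beats"
        )
    idx = np.sort(np.asarray(kept))
    return BeatSeries(idx / signal.fs, idx, signal.fs)


def peaks_to_ibi(series: BeatSeries) -> np.ndarray:
    """Interbeat intervals in seconds: first differences of the peak times."""
    if series.n_beats < 2:
        raise InsufficientBeatsError("need at least 2 peaks to form intervals")
    return np.diff(series.peak_times)


def match_beats(
    detected: np.ndarray, truth: np.ndarray, tolerance: float = 0.05
) -> tuple[int, int, int]:
    """Match detected beat times to ground truth within ``tolerance`` seconds.

    Greedy one-to-one matching in time order. Returns ``(tp, fp, fn)`` from
    which beat-level sensitivity ``tp/(tp+fn)`` and positive predictivity
    ``tp/(tp+fp)`` follow.
    """
    detected = np.asarray(detected, dtype=float)
    truth = np.asarray(truth, dtype=float)
    i = j = tp = 0
    while i < detected.size and j < truth.size:
        dt = detected[i] - truth[j]
        if abs(dt) <= tolerance:
            tp += 1
            i += 1
            j += 1
        elif dt < 0:
            i += 1
        else:
            j += 1
    return tp, detected.size - tp, truth.size - tp


def beat_detection_scores(
    detected: np.ndarray,
    truth: np.ndarray,
    duration: float,
    tolerance: float = 0.05,
    edge_margin: float = 0.5,
) -> tuple[int, int, int]:
    """``(tp, fp, fn)`` restricted to the window interior.

    A pulse centred on the very first or last instant of a window is only
    half rendered and carries no detectable local maximum, so both lists are
    clipped to ``[edge_margin, duration - edge_margin]`` before matching;
    sensitivity and positive predictivity are then window-interior rates.
    """
    detected = np.asarray(detected, dtype=float)
    truth = np.asarray(truth, dtype=float)
    lo, hi = edge_margin, duration - edge_margin
    return match_beats(
        detected[(detected >= lo) & (detected <= hi)],
        truth[(truth >= lo) & (truth <= hi)],
        tolerance=tolerance,
    )
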