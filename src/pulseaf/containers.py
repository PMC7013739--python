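"""Core in-memory containers: uniformly sampled waveforms and detected beat series."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import SignalError

#: Physiological refractory floor between consecutive beats, seconds (~240 bpm).
REFRACTORY_S = 0.25


@dataclass(frozen=True)
class WaveformSignal:
    """A uniformly sampled amplitude series.

    Parameters
    ----------
    samples : array-like of float
        Amplitudes in arbitrary units, uniformly spaced in time.
    fs : float
        Sampling rate in Hz.
    record_id : str, optional
        Identifier carried through the pipeline for logging/manifests.
    """

    samples: np.ndarray
    fs: float
    record_id: str | None = None

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size < 2:
            raise SignalError("a waveform needs at least 2 samples in one channel")
        if not np.all(np.isfinite(samples)):
            raise SignalError("waveform contains NaN or infinite samples")
        if not self.fs > 0:
            raise SignalError(f"sampling rate must be positive, got {self.fs}")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Span of the record in seconds, ``(n - 1) / fs``."""
        return (self.samples.size - 1) / self.fs

    def times(self) -> np.ndarray:
        """Sample instants in seconds, starting at 0."""
        return np.arange(self.samples.size) / self.fs


@dataclass(frozen=True)
class BeatSeries:
    """Detected pulse peaks and the derived interbeat-interval (IBI) series.

    ``ibis[k] == peak_times[k+1] - peak_times[k]`` by construction.
    """

    peak_times: np.ndarray
    peak_indices: np.ndarray
    fs: float
    ibis: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        times = np.asarray(self.peak_times, dtype=float)
        idx = np.asarray(self.peak_indices, dtype=int)
        if times.size != idx.size:
            raise SignalError("peak_times and peak_indices must have equal length")
        if times.size >= 2 and not np.all(np.diff(times) > 0):
            raise SignalError("peak times must be strictly increasing")
        object.__setattr__(self, "peak_times", times)
        object.__setattr__(self, "peak_indices", idx)
        object.__setattr__(self, "ibis", np.diff(times))

    @classmethod
    def from_times(cls, peak_times, fs: float) -> "BeatSeries":
        """Build a series from peak times alone (indices snapped to the grid)."""
        times = np.asarray(peak_times, dtype=float)
        return cls(times, np.round(times * fs).astype(int), fs)

    @property
    def n_beats(self) -> int:
        return self.peak_times.size
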