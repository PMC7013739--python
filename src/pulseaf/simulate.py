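"""Synthetic NSR / AF pulse-rhythm simulator with ground-truth beat times.

Two rhythm models:

* **NSR** (normal sinus rhythm): RR intervals follow a base interval modulated
  by a respiratory sinusoid plus Gaussian jitter,
  ``RR(t) = RR0 * (1 + d * sin(2*pi*f_resp*t)) + N(0, (cv*RR0)^2)``.
* **AF** (atrial fibrillation): RR intervals are drawn i.i.d. from a Gamma
  distribution with the configured mean and coefficient of variation — the
  simplest serially uncorrelated ("irregularly irregular") process.

Waveforms are rendered as a train of asymmetric PPG-like pulses (a narrow
systolic lobe plus a delayed, wider diastolic lobe), one per beat, with
optional Gaussian noise and slow sinusoidal baseline wander.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .containers import REFRACTORY_S, WaveformSignal
from .errors import ConfigurationError

NSR = "NSR"
AF = "AF"

#: Config ranges the cohort generator draws from, per rhythm class.
NSR_HR_RANGE = (55.0, 90.0)
NSR_CV_RANGE = (0.02, 0.06)
NSR_RESP_DEPTH_RANGE = (0.02, 0.08)
NSR_RESP_FREQ_RANGE = (0.15, 0.35)
AF_HR_RANGE = (70.0, 130.0)
AF_CV_RANGE = (0.18, 0.35)


@dataclass(frozen=True)
class RhythmConfig:
    """Parameters of one simulated rhythm record."""

    rhythm_label: str
    mean_hr: float = 70.0
    rr_cv: float = 0.04
    resp_mod_depth: float = 0.0
    resp_freq: float = 0.25
    duration: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rhythm_label not in (NSR, AF):
            raise ConfigurationError(f"rhythm_label must be 'NSR' or 'AF', got {self.rhythm_label!r}")
        if not self.mean_hr > 0:
            raise ConfigurationError(f"mean_hr must be positive, got {self.mean_hr}")
        if self.rr_cv < 0:
            raise ConfigurationError(f"rr_cv must be >= 0, got {self.rr_cv}")
        if not self.duration > 0:
            raise ConfigurationError(f"duration must be positive, got {self.duration}")
        if self.rhythm_label == AF and self.rr_cv < 0.15:
            raise ConfigurationError("AF configs require rr_cv >= 0.15 (irregularly irregular)")
        if self.rhythm_label == NSR and self.rr_cv > 0.08:
            raise ConfigurationError("NSR configs require rr_cv <= 0.08")


@dataclass(frozen=True)
class GroundTruth:
    """True beat times of a simulated record, with its rhythm label."""

    beat_times: np.ndarray
    rhythm_label: str
    duration: float

    def __post_init__(self) -> None:
        times = np.asarray(self.beat_times, dtype=float)
        if times.size >= 2 and not np.all(np.diff(times) > 0):
            raise ConfigurationError("beat times must be strictly increasing")
        object.__setattr__(self, "beat_times", times)


def generate_rhythm(config: RhythmConfig) -> GroundTruth:
    """Generate ground-truth beat times for one record.

    Beats start at t=0 and cover ``[0, duration]``; every interval is clipped
    at the 0.25 s refractory floor. Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    base_rr = 60.0 / config.mean_hr
    times = [0.0]
    t = 0.0
    if config.rhythm_label == AF and config.rr_cv > 0:
        shape = 1.0 / config.rr_cv**2
        scale = base_rr * config.rr_cv**2

        def draw(_t: float) -> float:
            return rng.gamma(shape, scale)
    else:

        def draw(_t: float) -> float:
            rr = base_rr * (1.0 + config.resp_mod_depth * np.sin(2 * np.pi * config.resp_freq * _t))
            if config.rr_cv > 0:
                rr += rng.normal(0.0, config.rr_cv * base_rr)
            return rr

    while True:
        rr = max(draw(t), REFRACTORY_S)
        t = t + rr
        if t > config.duration + 1e-9:
            break
        times.append(t)
    return GroundTruth(np.asarray(times), config.rhythm_label, config.duration)


# PPG-like pulse template: narrow systolic lobe + delayed, wider diastolic lobe.
_SYS_WIDTH = 0.06   # s
_DIA_WIDTH = 0.18   # s
_DIA_DELAY = 0.15   # s
_DIA_AMP = 0.4


def _pulse_raw(t: np.ndarray) -> np.ndarray:
    return np.exp(-(t**2) / (2 * _SYS_WIDTH**2)) + _DIA_AMP * np.exp(
        -((t - _DIA_DELAY) ** 2) / (2 * _DIA_WIDTH**2)
    )


def _template_calibration() -> tuple[float, float]:
    # offset/scale such that the rendered pulse has its maximum exactly at the
    # beat time with unit amplitude
    tt = np.linspace(-0.1, 0.1, 4001)
    vals = _pulse_raw(tt)
    k = int(np.argmax(vals))
    return float(tt[k]), float(vals[k])


_PEAK_OFFSET, _PEAK_SCALE = _template_calibration()
_TEMPLATE_HALF_SPAN = 1.2  # s of template support kept on each side of a beat


def render_waveform(
    truth: GroundTruth,
    fs: float,
    noise_sd: float = 0.0,
    baseline_amp: float = 0.0,
    baseline_freq: float = 0.2,
    seed: int | None = None,
) -> WaveformSignal:
    """Render a pulse waveform from ground-truth beat times.

    One unit-peak pulse template is centered at each beat time; additive
    Gaussian noise (``noise_sd``) and slow sinusoidal baseline wander
    (``baseline_amp`` at ``baseline_freq`` <= 0.3 Hz) are superimposed.
    Sample count is ``round(fs * duration) + 1``.
    """
    if truth is None or not truth.duration > 0:
        raise ConfigurationError("render_waveform needs a ground truth with positive duration")
    if fs < 25:
        raise ConfigurationError(f"fs must be >= 25 Hz to resolve the pulse shape, got {fs}")
    if baseline_freq > 0.3:
        raise ConfigurationError("baseline wander must stay below 0.3 Hz")
    n = int(round(fs * truth.duration)) + 1
    t = np.arange(n) / fs
    y = np.zeros(n)
    half = int(np.ceil(_TEMPLATE_HALF_SPAN * fs))
    for bt in truth.beat_times:
        c = int(round(bt * fs))
        lo, hi = max(c - half, 0), min(c + half + 1, n)
        y[lo:hi] += _pulse_raw(t[lo:hi] - bt + _PEAK_OFFSET) / _PEAK_SCALE
    if baseline_amp:
        y += baseline_amp * np.sin(2 * np.pi * baseline_freq * t)
    if noise_sd:
        rng = np.random.default_rng(seed)
        y += rng.normal(0.0, noise_sd, n)
    return WaveformSignal(y, fs)


def generate_dataset(
    n_per_class: int,
    fs: float = 100.0,
    seed: int = 0,
    duration: float = 60.0,
    noise_sd: float = 0.02,
    baseline_amp: float = 0.1,
) -> list[tuple[WaveformSignal, GroundTruth]]:
    """Generate a balanced labeled cohort of one-minute NSR and AF records.

    Per-record configurations are drawn uniformly from the documented ranges
    (NSR: mean HR 55-90 bpm, RR CV 0.02-0.06, respiratory modulation depth
    0.02-0.08 at 0.15-0.35 Hz; AF: mean HR 70-130 bpm, RR CV 0.18-0.35).
    Record seeds are derived as ``seed + index``; fully reproducible.
    """
    if n_per_class < 1:
        raise ConfigurationError("n_per_class must be >= 1")
    records: list[tuple[WaveformSignal, GroundTruth]] = []
    for i in range(2 * n_per_class):
        label = NSR if i < n_per_class else AF
        record_seed = seed + i
        params_rng = np.random.default_rng([record_seed, 1])
        if label == NSR:
            config = RhythmConfig(
                rhythm_label=NSR,
                mean_hr=params_rng.uniform(*NSR_HR_RANGE),
                rr_cv=params_rng.uniform(*NSR_CV_RANGE),
                resp_mod_depth=params_rng.uniform(*NSR_RESP_DEPTH_RANGE),
                resp_freq=params_rng.uniform(*NSR_RESP_FREQ_RANGE),
                duration=duration,
                seed=record_seed,
            )
        else:
            config = RhythmConfig(
                rhythm_label=AF,
                mean_hr=params_rng.uniform(*AF_HR_RANGE),
                rr_cv=params_rng.uniform(*AF_CV_RANGE),
                duration=duration,
                seed=record_seed,
            )
        truth = generate_rhythm(config)
        wave = render_waveform(
            truth, fs, noise_sd=noise_sd, baseline_amp=baseline_amp,
            seed=int(np.random.default_rng([record_seed, 2]).integers(2**31)),
        )
        rid = f"{label.lower()}_{i if label == NSR else i - n_per_class:04d}"
        wave = replace(wave, record_id=rid)
        records.append((wave, truth))
    return records
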