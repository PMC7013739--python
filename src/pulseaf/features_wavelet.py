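"""Time-frequency features from a single-level discrete wavelet transform.

The preprocessed waveform is decomposed once with an orthogonal wavelet
(default Daubechies-4, periodization boundaries) into approximation (cA) and
detail (cD) coefficients; six statistics are taken: average energy (mean of
squared coefficients), mean absolute value and population standard deviation
of each coefficient vector.
"""

from __future__ import annotations

import numpy as np
import pywt

from .containers import WaveformSignal
from .errors import ConfigurationError, SignalError

WAVELET_FEATURE_NAMES = ("AEcA", "MAVcA", "STDcA", "AEcD", "MAVcD", "STDcD")


def dwt_single_level(
    signal: WaveformSignal | np.ndarray, wavelet_name: str = "db4"
) -> tuple[np.ndarray, np.ndarray]:
    """One-level DWT with periodic ('periodization') boundary handling.

    For orthogonal wavelets and even input length this conserves energy:
    ``sum(cA**2) + sum(cD**2) == sum(x**2)`` (odd lengths are padded by the
    boundary mode and conserve only approximately).
    """
    x = signal.samples if isinstance(signal, WaveformSignal) else np.asarray(signal, dtype=float)
    try:
        wavelet = pywt.Wavelet(wavelet_name)
    except ValueError as exc:
        raise ConfigurationError(f"unknown wavelet {wavelet_name!r}") from exc
    if x.size < wavelet.dec_len:
        raise SignalError(
            f"signal of {x.size} samples is shorter than the {wavelet_name} filter "
            f"({wavelet.dec_len} taps)"
        )
    ca, cd = pywt.dwt(x, wavelet, mode="periodization")
    return ca, cd


def extract_wavelet_features(
    signal: WaveformSignal, wavelet_name: str = "db4"
) -> dict[str, float]:
    """Compute the 6 time-frequency features (population-std convention)."""
    ca, cd = dwt_single_level(signal, wavelet_name)
    return {
        "AEcA": float(np.mean(ca**2)),
        "MAVcA": float(np.mean(np.abs(ca))),
        "STDcA": float(np.std(ca)),
        "AEcD": float(np.mean(cd**2)),
        "MAVcD": float(np.mean(np.abs(cd))),
        "STDcD": float(np.std(cd)),
    }
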