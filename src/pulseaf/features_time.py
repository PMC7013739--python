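"""Time-domain HRV features of an interbeat-interval series.

The 13 features: Mean, STD, SDRR, RMSSD, SampEn, CosEn, ShE, SD1, SD2,
SD1/SD2 ratio, Poincare ellipse area S, MeanAD, MAD. All standard deviations
use the population (divide-by-n) convention.

SDRR and STD both denote the standard deviation of the IBI series and are
reported as two (equal) columns; a hook (``std_source``) exists should a
different STD source ever be wanted.
"""

from __future__ import annotations

import warnings

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import SignalError

#: Canonical names of the 13 time-domain features.
TIME_FEATURE_NAMES = (
    "Mean", "STD", "SDRR", "RMSSD", "SampEn", "CosEn", "ShE",
    "SD1", "SD2", "SD1_SD2", "S", "MeanAD", "MAD",
)

#: Cap reported when sample entropy is undefined (no template matches).
SAMPEN_CAP = 10.0


def _pop_std(x: np.ndarray) -> float:
    return float(np.std(x))


def sample_entropy(x, m: int = 2, r: float | None = None, cap: float = SAMPEN_CAP) -> float:
    """Sample entropy: -ln(A/B) over Chebyshev template matches.

    ``B`` counts pairs of length-``m`` templates (drawn from the first
    ``n - m`` positions, self-matches excluded) within tolerance ``r``
    (inclusive); ``A`` does the same for length ``m + 1``. If either count is
    zero the entropy is undefined and the documented ``cap`` (default 10 nats)
    is returned with a warning, keeping downstream feature tables finite.

    ``r`` defaults to ``0.2 * std(x)`` (population std).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < m + 2:
        raise SignalError(f"sample entropy needs at least m+2={m + 2} points, got {n}")
    if r is None:
        r = 0.2 * _pop_std(x)
    if r < 0:
        raise SignalError("tolerance r must be >= 0")

    def n_matches(length: int) -> int:
        tpl = sliding_window_view(x, length)[: n - m]
        d = np.max(np.abs(tpl[:, None, :] - tpl[None, :, :]), axis=-1)
        iu = np.triu_indices(tpl.shape[0], k=1)
        return int(np.count_nonzero(d[iu] <= r))

    b = n_matches(m)
    a = n_matches(m + 1)
    if a == 0 or b == 0:
        warnings.warn(
            f"sample entropy undefined (A={a}, B={b}); reporting cap {cap}",
            RuntimeWarning,
            stacklevel=2,
        )
        return cap
    return float(-np.log(a / b) + 0.0)  # + 0.0 maps -0.0 to 0.0


def shannon_entropy(x, n_bins: int = 16) -> float:
    """Shannon entropy (nats) of an equal-width histogram over [min, max].

    A degenerate range (max == min) carries no information and returns 0.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise SignalError("Shannon entropy needs at least 2 points")
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        return 0.0
    counts, _ = np.histogram(x, bins=n_bins, range=(lo, hi))
    p = counts[counts > 0] / x.size
    return float(-np.sum(p * np.log(p)))


def poincare_descriptors(x) -> tuple[float, float, float, float]:
    """Poincare-plot dispersions ``(SD1, SD2, SD1/SD2, S)``.

    SD1 (perpendicular to the identity line) = std of successive differences
    / sqrt(2); SD2 (along it) = sqrt(2*SDRR^2 - SD1^2) floored at 0; S is the
    fitted ellipse area pi*SD1*SD2. Population std convention.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise SignalError("Poincare descriptors need at least 3 intervals")
    sd1 = _pop_std(np.diff(x)) / np.sqrt(2.0)
    sdrr = _pop_std(x)
    sd2 = float(np.sqrt(max(2.0 * sdrr**2 - sd1**2, 0.0)))
    ratio = sd1 / sd2 if sd2 > 0 else 0.0
    return sd1, sd2, ratio, float(np.pi * sd1 * sd2)


def extract_time_features(
    x,
    m: int = 2,
    r_fraction: float = 0.2,
    n_bins: int = 16,
    sampen_cap: float = SAMPEN_CAP,
) -> dict[str, float]:
    """Compute all 13 time-domain features of an IBI series (seconds).

    CosEn applies the short-record correction ``SampEn + ln(r) - ln(mean)``;
    for a constant series (r = 0) it is reported as ``-sampen_cap``.
    """
    x = np.asarray(x, dtype=float)
    if x.size < max(m + 2, 3):
        raise SignalError(f"need at least {max(m + 2, 3)} intervals, got {x.size}")
    mean = float(np.mean(x))
    std = _pop_std(x)
    diffs = np.diff(x)
    rmssd = float(np.sqrt(np.mean(diffs**2)))
    # a constant series has zero tolerance exactly (fp std of a constant
    # array can come out as ~1e-17, which would poison ln(r))
    r = r_fraction * std if np.ptp(x) > 0 else 0.0
    sampen = sample_entropy(x, m=m, r=r, cap=sampen_cap)
    if r > 0 and mean > 0:
        cosen = sampen + float(np.log(r)) - float(np.log(mean))
    else:
        warnings.warn(
            "CosEn undefined (zero tolerance or non-positive mean); reporting -cap",
            RuntimeWarning,
            stacklevel=2,
        )
        cosen = -sampen_cap
    sd1, sd2, ratio, area = poincare_descriptors(x)
    return {
        "Mean": mean,
        "STD": std,
        "SDRR": std,
        "RMSSD": rmssd,
        "SampEn": sampen,
        "CosEn": cosen,
        "ShE": shannon_entropy(x, n_bins=n_bins),
        "SD1": sd1,
        "SD2": sd2,
        "SD1_SD2": ratio,
        "S": area,
        "MeanAD": float(np.mean(np.abs(x - mean))),
        "MAD": float(np.median(np.abs(x - np.median(x)))),
    }
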