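"""Independent brute-force oracles used to verify the implementation.

Everything here is written as plain, direct arithmetic (explicit loops,
sorting, rotation) on purpose: these functions must not share code paths
with the package.
"""

from __future__ import annotations

import math

import numpy as np


def sampen_bruteforce(x, m: int, r: float) -> float | None:
    """Sample entropy by exhaustive O(n^2) template comparison.

    Returns None when undefined (no matches at either length).
    """
    x = list(map(float, x))
    n = len(x)

    def count(length: int) -> int:
        total = 0
        n_templates = n - m  # both lengths use the first n-m starting positions
        for i in range(n_templates):
            for j in range(i + 1, n_templates):
                if all(abs(x[i + k] - x[j + k]) <= r for k in range(length)):
                    total += 1
        return total

    b = count(m)
    a = count(m + 1)
    if a == 0 or b == 0:
        return None
    return -math.log(a / b)


def shannon_entropy_bruteforce(x, n_bins: int) -> float:
    """Histogram entropy via explicit bin assignment (right edge in last bin)."""
    x = list(map(float, x))
    lo, hi = min(x), max(x)
    if hi == lo:
        return 0.0
    width = (hi - lo) / n_bins
    counts = [0] * n_bins
    for v in x:
        k = min(int((v - lo) / width), n_bins - 1)
        counts[k] += 1
    total = len(x)
    return -sum(c / total * math.log(c / total) for c in counts if c)


def sd1_rotation_oracle(x) -> float:
    """SD1 via explicit 45-degree rotation of the (RR_n, RR_{n+1}) cloud."""
    x = np.asarray(x, dtype=float)
    pts = np.column_stack([x[:-1], x[1:]])
    c, s = math.cos(np.pi / 4), math.sin(np.pi / 4)
    perp = -s * pts[:, 0] + c * pts[:, 1]  # coordinate perpendicular to identity line
    return float(np.sqrt(np.mean((perp - perp.mean()) ** 2)))


def sorted_percentile_oracle(x, q: float) -> float:
    """Linear-interpolated order statistic computed from an explicit sort."""
    xs = sorted(map(float, x))
    pos = q / 100.0 * (len(xs) - 1)
    lo = int(math.floor(pos))
    hi = int(math.ceil(pos))
    frac = pos - lo
    return xs[lo] * (1 - frac) + xs[hi] * frac


def periodogram_bruteforce(x, fs: float):
    """One-sided density periodogram from the raw DFT definition."""
    x = np.asarray(x, dtype=float)
    n = x.size
    spectrum = np.fft.rfft(x)
    power = (np.abs(spectrum) ** 2) / (fs * n)
    power[1:] *= 2.0
    if n % 2 == 0:
        power[-1] /= 2.0
    freqs = np.arange(power.size) * fs / n
    return freqs, power


def band_power_bruteforce(freqs, power, lo: float, hi: float) -> float:
    """Rectangle-rule band integration over half-open [lo, hi)."""
    df = freqs[1] - freqs[0]
    return float(sum(p for f, p in zip(freqs, power) if lo <= f < hi) * df)


def haar_dwt_bruteforce(x):
    """Single-level Haar analysis filter bank, periodic boundaries."""
    x = np.asarray(x, dtype=float)
    n = x.size
    assert n % 2 == 0
    inv = 1 / math.sqrt(2)
    ca = np.array([(x[2 * k] + x[2 * k + 1]) * inv for k in range(n // 2)])
    cd = np.array([(x[2 * k] - x[2 * k + 1]) * inv for k in range(n // 2)])
    return ca, cd


def auc_pairwise_oracle(labels, scores) -> float:
    """AUC as P(score_pos > score_neg) + 0.5 P(tie) over all pos/neg pairs."""
    pos = [s for l, s in zip(labels, scores) if l == 1]
    neg = [s for l, s in zip(labels, scores) if l == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def time_moments_bruteforce(x) -> dict[str, float]:
    """Mean, population std, RMSSD, MeanAD, MAD by direct arithmetic."""
    x = list(map(float, x))
    n = len(x)
    mean = sum(x) / n
    std = math.sqrt(sum((v - mean) ** 2 for v in x) / n)
    diffs = [x[i + 1] - x[i] for i in range(n - 1)]
    rmssd = math.sqrt(sum(d * d for d in diffs) / len(diffs))
    mean_ad = sum(abs(v - mean) for v in x) / n

    def median(vals):
        vs = sorted(vals)
        mid = len(vs) // 2
        return vs[mid] if len(vs) % 2 else 0.5 * (vs[mid - 1] + vs[mid])

    med = median(x)
    mad = median([abs(v - med) for v in x])
    return {"Mean": mean, "STD": std, "RMSSD": rmssd, "MeanAD": mean_ad, "MAD": mad}
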