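"""Independent brute-force oracles used to validate the package.

These deliberately avoid the package's vectorized implementations: the
interval scanner is a plain Python loop, the samplers are inverse-CDF
one-liners, and the phasor mean is computed sample by sample.
"""

from __future__ import annotations

import cmath

import numpy as np


def scan_intervals(dphi, valid, fs, threshold, min_duration=1, include_censored=True):
    """Linear-scan reference for lock-interval extraction (no smoothing).

    Returns a list of ``(duration_seconds, censored)`` tuples in order.
    A run is censored when the sample before its start or after its end is
    absent or invalid.
    """
    n = len(dphi)
    locked = [abs(float(d)) < threshold and bool(v) for d, v in zip(dphi, valid)]
    out = []
    i = 0
    while i < n:
        if not locked[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and locked[j + 1]:
            j += 1
        left_open = (i == 0) or (not valid[i - 1])
        right_open = (j == n - 1) or (not valid[j + 1])
        censored = left_open or right_open
        length = j - i + 1
        if length >= min_duration and (include_censored or not censored):
            out.append((length / fs, censored))
        i = j + 1
    return out


def phasor_mean_smooth(dphi, window):
    """Per-sample circular moving mean, computed one sample at a time."""
    n = len(dphi)
    half = window // 2
    out = []
    for t in range(n):
        lo, hi = max(0, t - half), min(n, t + half + 1)
        mean = sum(cmath.exp(1j * float(d)) for d in dphi[lo:hi]) / (hi - lo)
        out.append(cmath.phase(mean) if mean != 0 else 0.0)
    return np.array(out)


def sample_power_law(rng, n, alpha, xmin):
    """Inverse-CDF draws from the continuous power law p(x) ~ x^-alpha, x >= xmin."""
    u = rng.uniform(size=n)
    return xmin * (1.0 - u) ** (-1.0 / (alpha - 1.0))


def sample_shifted_exponential(rng, n, rate, xmin):
    """Draws from xmin + Exponential(rate)."""
    return xmin + rng.exponential(scale=1.0 / rate, size=n)


def welch_slope(x, fs, f_lo=1.0, f_hi=100.0, nperseg=4096):
    """Least-squares log-log PSD slope over [f_lo, f_hi] via Welch."""
    from scipy import signal

    f, p = signal.welch(x, fs=fs, nperseg=nperseg)
    m = (f >= f_lo) & (f <= f_hi) & (p > 0)
    return float(np.polyfit(np.log(f[m]), np.log(p[m]), 1)[0])
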