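"""Independent brute-force oracles used by the test suite.

Deliberately dumb pure-Python re-statements of the detection rules:
strict-neighbor extrema, exhaustive enumeration over all extremum pairs,
per-sample scans.  They share nothing with the vectorized implementations
they check beyond the standard filtering primitives.
"""

from __future__ import annotations

import numpy as np


def strict_minima(v) -> list[int]:
    return [i for i in range(1, len(v) - 1) if v[i - 1] > v[i] < v[i + 1]]


def strict_maxima(v) -> list[int]:
    return [i for i in range(1, len(v) - 1) if v[i - 1] < v[i] > v[i + 1]]


def brute_pvv_pairs(v, deriv, descent_threshold: float) -> list[tuple[int, int]]:
    """All (contact, toe-off) index pairs passing the velocity-pattern
    conditions, by exhaustive enumeration on the filtered signal."""
    mins, maxs = strict_minima(v), strict_maxima(v)
    pairs = []
    for ic in mins:
        tos = [m for m in maxs if m > ic]
        for j, to in enumerate(tos):
            nxt = tos[j + 1] if j + 1 < len(tos) else len(v)
            onset = None
            for k in range(to + 1, nxt):
                if deriv[k] < descent_threshold:
                    onset = k
                    break
            if onset is None:
                continue
            pool = [m for m in maxs if ic < m <= onset]
            if all(v[to] >= v[m] for m in pool):
                pairs.append((ic, to))
                break
    return pairs


def brute_rfa_pairs(a, to_threshold: float, u_factor: float = 0.5) -> list[tuple[int, int]]:
    """All (contact, toe-off) peak pairs passing the acceleration-pattern
    conditions, by exhaustive enumeration on the filtered resultant."""
    maxs = strict_maxima(a)
    pairs = []
    for i, ic in enumerate(maxs):
        for to in maxs[i + 1 :]:
            if a[to] < to_threshold:
                continue
            if to - ic < 2:
                continue
            valley = min(a[ic + 1 : to])
            if valley < u_factor * min(a[ic], a[to]):
                pairs.append((ic, to))
                break
    return pairs


def scan_grf_windows(v, threshold: float, min_samples: int) -> tuple[list, bool]:
    """Per-sample scan for supra-threshold windows; returns (windows,
    truncated_flag) where each window is (first index > thr, first
    subsequent index < thr)."""
    windows, truncated = [], False
    i, n = 0, len(v)
    while i < n:
        if v[i] > threshold:
            ic = i
            j = i
            while j < n and not (v[j] < threshold):
                j += 1
            if j == n:
                truncated = True
                break
            if j - ic >= min_samples:
                windows.append((ic, j))
            i = j
        else:
            i += 1
    return windows, truncated


def sorted_quantile(values, q: float) -> float:
    """Linear-interpolation quantile computed from first principles."""
    xs = sorted(float(x) for x in values)
    pos = q * (len(xs) - 1)
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    frac = pos - lo
    return xs[lo] * (1 - frac) + xs[hi] * frac
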