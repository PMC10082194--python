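"""Penalized least-squares change-point detection for 1-D signals.

Cost of a segment is its within-segment sum of squared deviations from the
segment mean; each additional change point pays a constant penalty.  For
signals up to ``EXACT_LIMIT`` points the exact optimum is found with PELT
(pruned dynamic programming, exact for constant penalties); longer signals
fall back to greedy binary segmentation with the same cost/penalty rule.
"""

from __future__ import annotations

import numpy as np

EXACT_LIMIT = 5_000


def _cumsums(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    cs = np.concatenate([[0.0], np.cumsum(x)])
    cs2 = np.concatenate([[0.0], np.cumsum(x * x)])
    return cs, cs2


def _seg_cost(cs, cs2, s, t):
    """Sum of squared residuals of x[s:t] about its mean (vectorized over s)."""
    n = t - s
    total = cs[t] - cs[s]
    return cs2[t] - cs2[s] - total * total / n


def pelt_breakpoints(values: np.ndarray, penalty: float) -> list[int]:
    """Exact optimal partition; returns sorted end indices of segments.

    The last breakpoint is always ``len(values)``.
    """
    if penalty <= 0:
        raise ValueError("penalty must be positive")
    x = np.asarray(values, dtype=float)
    n = x.size
    if n == 0:
        return []
    cs, cs2 = _cumsums(x)
    F = np.empty(n + 1)
    F[0] = -penalty
    last = np.zeros(n + 1, dtype=np.int64)
    cand = np.array([0], dtype=np.int64)
    for t in range(1, n + 1):
        vals = F[cand] + _seg_cost(cs, cs2, cand, t) + penalty
        i = int(np.argmin(vals))
        F[t] = vals[i]
        last[t] = cand[i]
        cand = cand[vals - penalty <= F[t]]
        cand = np.append(cand, t)
    bkps: list[int] = []
    t = n
    while t > 0:
        bkps.append(t)
        t = int(last[t])
    return bkps[::-1]


def binseg_breakpoints(values: np.ndarray, penalty: float) -> list[int]:
    """Greedy binary segmentation with the same penalized-cost stopping rule."""
    if penalty <= 0:
        raise ValueError("penalty must be positive")
    x = np.asarray(values, dtype=float)
    n = x.size
    if n == 0:
        return []
    cs, cs2 = _cumsums(x)

    def best_split(s: int, t: int) -> tuple[float, int]:
        # gain of splitting x[s:t] at each interior point
        if t - s < 2:
            return 0.0, -1
        mids = np.arange(s + 1, t)
        whole = float(_seg_cost(cs, cs2, np.array([s]), t)[0])
        left = _seg_cost(cs, cs2, s, mids)
        right = _seg_cost(cs, cs2, mids, t)
        gains = whole - (left + right)
        i = int(np.argmax(gains))
        return float(gains[i]), int(mids[i])

    cuts: list[int] = []
    work = [(0, n)]
    while work:
        s, t = work.pop()
        gain, m = best_split(s, t)
        if m >= 0 and gain > penalty:
            cuts.append(m)
            work.append((s, m))
            work.append((m, t))
    return sorted(cuts) + [n]


def detect_breakpoints(values: np.ndarray, penalty: float) -> list[int]:
    """Dispatch: exact PELT up to EXACT_LIMIT points, binary segmentation beyond."""
    x = np.asarray(values, dtype=float)
    if x.size <= EXACT_LIMIT:
        return pelt_breakpoints(x, penalty)
    return binseg_breakpoints(x, penalty)


def estimate_noise_sd(values: np.ndarray) -> float:
    """Robust noise SD from first differences (MAD-based, step-insensitive)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        return 0.0
    d = np.diff(x)
    return float(1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2.0))
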