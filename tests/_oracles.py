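"""Independent brute-force oracles for the entropy and distance estimators.

These deliberately use naive pairwise loops and explicit comparison
chains, sharing no code with the package implementations.
"""

from __future__ import annotations

import math

import numpy as np


def sampen_oracle(x, m: int, r: float) -> float:
    """Definitional O(N^2) sample entropy: explicit pair counting."""
    x = np.asarray(x, dtype=float)
    n_templates = len(x) - m
    n_m = 0
    n_m1 = 0
    for i in range(n_templates):
        # vectorized over j > i, but with per-pair Chebyshev computed afresh
        for j in range(i + 1, n_templates):
            d_m = max(abs(x[i + k] - x[j + k]) for k in range(m))
            if d_m < r:
                n_m += 1
                d_m1 = max(d_m, abs(x[i + m] - x[j + m]))
                if d_m1 < r:
                    n_m1 += 1
    if n_m == 0 or n_m1 == 0:
        return float("nan")
    return -math.log(n_m1 / n_m)


def modified_symbol_oracle(a: float, b: float, c: float) -> int:
    """Exhaustive comparison chain for one triplet, modified table."""
    if a == b and b == c:
        return 11
    if a == b:
        return 7 if b < c else 8
    if b == c:
        return 9 if a > b else 10
    if a == c:  # outer tie resolved as a < c
        return 2 if a < b else 3
    if a < b < c:
        return 1
    if a < b and b > c and a < c:
        return 2
    if a > b and b < c and a < c:
        return 3
    if a < b and b > c and a > c:
        return 4
    if a > b > c:
        return 5
    if a > b and b < c and a > c:
        return 6
    raise AssertionError("unreachable")


def symbolize_oracle(x, lag: int = 1) -> list[int]:
    x = list(map(float, np.asarray(x, dtype=float)))
    return [
        modified_symbol_oracle(x[i], x[i + lag], x[i + 2 * lag])
        for i in range(len(x) - 2 * lag)
    ]


def shannon(probs) -> float:
    return -sum(p * math.log(p) for p in probs if p > 0)


def mpe_oracle(x, lag: int = 1) -> float:
    symbols = symbolize_oracle(x, lag)
    counts: dict[int, int] = {}
    for s in symbols:
        counts[s] = counts.get(s, 0) + 1
    total = len(symbols)
    return shannon([c / total for c in counts.values()])


def wmpe_oracle(x, lag: int = 1) -> float:
    """Variance-weighted modified PE via explicit per-motif loops."""
    x = np.asarray(x, dtype=float)
    symbols = symbolize_oracle(x, lag)
    weighted: dict[int, float] = {}
    total_w = 0.0
    for i, s in enumerate(symbols):
        vec = [x[i], x[i + lag], x[i + 2 * lag]]
        mu = sum(vec) / 3.0
        w = sum((v - mu) ** 2 for v in vec) / 3.0
        weighted[s] = weighted.get(s, 0.0) + w
        total_w += w
    if total_w == 0:
        counts: dict[int, int] = {}
        for s in symbols:
            counts[s] = counts.get(s, 0) + 1
        return shannon([c / len(symbols) for c in counts.values()])
    return shannon([w / total_w for w in weighted.values()])


def strict_motif_oracle(a: float, b: float, c: float) -> int:
    """One of the 6 strict motifs, ties treated as '<'."""
    ab = a <= b
    bc = b <= c
    ac = a <= c
    if ab and bc:
        return 1
    if ab and not bc and ac:
        return 2
    if not ab and bc and ac:
        return 3
    if ab and not bc and not ac:
        return 4
    if not ab and not bc:
        return 5
    return 6


def pattern_probs_oracle(x, lag: int = 1) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    counts = np.zeros(6)
    for i in range(len(x) - 2 * lag):
        counts[strict_motif_oracle(x[i], x[i + lag], x[i + 2 * lag]) - 1] += 1
    return counts / counts.sum()


def moving_average_oracle(x, s: int) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return np.array([np.mean(x[j : j + s]) for j in range(len(x) - s + 1)])


def isod_oracle(series, sx: int, sy: int, lag: int = 1) -> float:
    """End-to-end: moving-average scale both, count motifs, apply the
    squared-difference distance."""
    px = pattern_probs_oracle(moving_average_oracle(series, sx), lag)
    py = pattern_probs_oracle(moving_average_oracle(series, sy), lag)
    return 6.0 / 5.0 * float(np.sum((px - py) ** 2))
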