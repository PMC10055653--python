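"""Independent brute-force oracles used to cross-check the package."""

from __future__ import annotations

from itertools import combinations

import numpy as np

NEG = float("-inf")


def sw_affine_brute(a: str, b: str, matrix, gap_open: float, gap_extend: float) -> float:
    """Quadratic-space Smith-Waterman with affine gaps (a gap of length g
    costs gap_open + g * gap_extend), written as the classic three-state
    recurrence, independent of the package's aligner."""
    oe = gap_open + gap_extend
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)  # gap in a (consume b)
    F = np.full((n + 1, m + 1), NEG)  # gap in b (consume a)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - oe, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - oe, F[i - 1][j] - gap_extend)
            s = matrix[a[i - 1]][b[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def mann_whitney_exact_enumeration(a, b) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by enumerating every assignment of
    the pooled (tie-free) values to the two samples."""
    a = list(map(float, a))
    b = list(map(float, b))
    pooled = a + b
    assert len(set(pooled)) == len(pooled), "enumeration oracle requires no ties"
    na = len(a)

    def u_of(sample_a, sample_b):
        return sum(1 for x in sample_a for y in sample_b if x > y)

    u_obs = u_of(a, b)
    us = []
    for idx in combinations(range(len(pooled)), na):
        sa = [pooled[i] for i in idx]
        sb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        us.append(u_of(sa, sb))
    us = np.array(us)
    p_le = float((us <= u_obs).mean())
    p_ge = float((us >= u_obs).mean())
    return float(u_obs), min(1.0, 2.0 * min(p_le, p_ge))


def best_window_scan(values: np.ndarray, window: int, step: int):
    """All (start, sum) sliding windows, fully enumerated."""
    out = []
    for s in range(0, len(values) - window + 1, step):
        out.append((s, float(values[s : s + window].sum())))
    return out


def best_two_partition_ss(points: np.ndarray) -> float:
    """Minimal within-cluster sum of squares over every 2-partition."""
    n = len(points)
    best = float("inf")
    for r in range(1, n // 2 + 1):
        for idx in combinations(range(n), r):
            mask = np.zeros(n, dtype=bool)
            mask[list(idx)] = True
            ss = 0.0
            for m in (mask, ~mask):
                c = points[m].mean(axis=0)
                ss += float(((points[m] - c) ** 2).sum())
            best = min(best, ss)
    return best
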