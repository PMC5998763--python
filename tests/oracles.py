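"""Independent oracles used by the test suite.

Each oracle is written directly from a textbook definition (brute force,
enumeration, closed form) and never calls the implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np


def tanimoto_sets(bits_a: set[int], bits_b: set[int]) -> float:
    union = bits_a | bits_b
    if not union:
        return 0.0
    return len(bits_a & bits_b) / len(union)


def smith_waterman_affine(
    seq_a: str, seq_b: str, matrix, gap_open: float, gap_extend: float
) -> float:
    """Gotoh local alignment; a gap of length k costs open + (k-1)*extend."""
    n, m = len(seq_a), len(seq_b)
    NEG = -1e18
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)  # gap in seq_b (vertical)
    F = np.full((n + 1, m + 1), NEG)  # gap in seq_a (horizontal)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i - 1][j] - gap_open, E[i - 1][j] - gap_extend)
            F[i][j] = max(H[i][j - 1] - gap_open, F[i][j - 1] - gap_extend)
            s = matrix[seq_a[i - 1], seq_b[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def rwr_linear_solve(
    adjacency: np.ndarray, seeds: list[int], restart: float
) -> np.ndarray:
    """Closed form p = r (I - (1-r) A)^-1 p0 with out-edge row normalization.

    Dangling rows redistribute to the seed vector, matching the iterative
    dangling-node policy.
    """
    n = adjacency.shape[0]
    p0 = np.zeros(n)
    p0[seeds] = 1.0 / len(seeds)
    M = adjacency.astype(float).copy()
    out = M.sum(axis=1)
    for i in range(n):
        if out[i] > 0:
            M[i] /= out[i]
        else:
            M[i] = p0
    A = M.T
    return restart * np.linalg.solve(np.eye(n) - (1.0 - restart) * A, p0)


def auroc_pair_counting(scores, labels) -> float:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = scores[labels]
    neg = scores[~labels]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def fisher_two_sided_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Sum hypergeometric pmf over all same-margin tables at most as probable."""
    r1, c1, N = a + b, a + c, a + b + c + d
    lo, hi = max(0, r1 + c1 - N), min(r1, c1)
    denom = math.comb(N, c1)
    pmf = [math.comb(r1, k) * math.comb(N - r1, c1 - k) / denom for k in range(lo, hi + 1)]
    p_obs = pmf[a - lo]
    return min(1.0, sum(p for p in pmf if p <= p_obs * (1.0 + 1e-9)))


def pearson_abs(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc, yc = x - x.mean(), y - y.mean()
    return abs(float((xc * yc).sum() / math.sqrt((xc**2).sum() * (yc**2).sum())))


def quantile_linear(values, q: float) -> float:
    """Linear-interpolation quantile over sorted order statistics."""
    v = sorted(values)
    h = (len(v) - 1) * q
    lo = math.floor(h)
    hi = math.ceil(h)
    return v[lo] + (h - lo) * (v[hi] - v[lo])
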