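"""Independent brute-force reference implementations used as test oracles.

Each function recomputes a quantity by exhaustive enumeration or by the
literal textbook definition, sharing no code with the package's
dynamic-programming / vectorized implementations.
"""

from __future__ import annotations

import math

import numpy as np


def enumerate_warping_paths(n: int, m: int):
    """All monotone warping paths from (0,0) to (n-1,m-1) with steps
    {(1,0),(0,1),(1,1)}."""

    def rec(i, j, path):
        if (i, j) == (n - 1, m - 1):
            yield path
            return
        for di, dj in ((1, 0), (0, 1), (1, 1)):
            ni, nj = i + di, j + dj
            if ni < n and nj < m:
                yield from rec(ni, nj, path + [(ni, nj)])

    yield from rec(0, 0, [(0, 0)])


def dtw_brute(a, b) -> float:
    """Minimum cumulative Euclidean cost over all enumerated warping paths."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    if b.ndim == 1:
        b = b[:, None]

    def cost(i, j):
        return float(np.sqrt(((a[i] - b[j]) ** 2).sum()))

    best = math.inf
    for path in enumerate_warping_paths(len(a), len(b)):
        best = min(best, sum(cost(i, j) for i, j in path))
    return best


def pam_exhaustive(dist, k: int) -> float:
    """Globally optimal k-medoids objective by enumerating all medoid sets."""
    import itertools

    d = np.asarray(dist, dtype=float)
    n = d.shape[0]
    best = math.inf
    for meds in itertools.combinations(range(n), k):
        best = min(best, float(d[:, list(meds)].min(axis=1).sum()))
    return best


def bh_brute(p) -> np.ndarray:
    """Literal BH step-up: for sorted p(1)<=...<=p(m),
    padj(i) = min_{j >= i} min(1, m p(j) / j), mapped back to input order."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    for rank_i in range(m):
        best = 1.0
        for rank_j in range(rank_i, m):
            best = min(best, m * p[order[rank_j]] / (rank_j + 1))
        adj_sorted[rank_i] = best
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def hypergeom_tail(n_pop: int, n_success: int, n_draw: int, k: int) -> float:
    """Exact upper-tail P(X >= k) by direct summation of the pmf."""
    total = math.comb(n_pop, n_draw)
    acc = 0
    for i in range(k, min(n_success, n_draw) + 1):
        if n_draw - i > n_pop - n_success:
            continue
        acc += math.comb(n_success, i) * math.comb(n_pop - n_success, n_draw - i)
    return acc / total


def es_brute(stats, hit_mask, weight: float = 1.0):
    """Literal running-sum enrichment score: hits add |s|**w normalized by
    the set total, misses subtract 1/(N-K); ES is the extreme of larger
    magnitude (ties positive)."""
    stats = list(stats)
    hit_mask = list(hit_mask)
    n = len(stats)
    k = sum(hit_mask)
    total = sum(abs(s) ** weight for s, h in zip(stats, hit_mask) if h)
    running = []
    cur = 0.0
    for s, h in zip(stats, hit_mask):
        if h:
            cur += (abs(s) ** weight) / total if total > 0 else 1.0 / k
        else:
            cur -= 1.0 / (n - k)
        running.append(cur)
    max_dev = max(max(running), 0.0)
    min_dev = min(min(running), 0.0)
    # same tie rule as the implementation: positive extreme wins a tie
    es = max_dev if max_dev >= -min_dev - 1e-12 else min_dev
    return es, running
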