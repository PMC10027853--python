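"""Independent brute-force oracles used to validate the implementation.

These deliberately avoid the code paths they check: exact integer
arithmetic for the hypergeometric enumeration, naive loops for filters,
joins and rank statistics.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb
from itertools import combinations

import numpy as np


def fisher_twosided_exact(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided Fisher p-value by exact integer enumeration of the
    conditional hypergeometric distribution (ties compared exactly)."""
    m = k1 + k2
    lo, hi = max(0, m - n2), min(m, n1)
    nums = {k: comb(n1, k) * comb(n2, m - k) for k in range(lo, hi + 1)}
    obs = nums[k1]
    total = sum(v for v in nums.values() if v <= obs)
    return float(Fraction(total, comb(n1 + n2, m)))


def fisher_grid_exact(n1: int, n2: int) -> dict[tuple[int, int], float]:
    """p-values for every table with the given row margins, grouped by
    the first-column margin so each distribution is enumerated once."""
    out: dict[tuple[int, int], float] = {}
    for m in range(n1 + n2 + 1):
        lo, hi = max(0, m - n2), min(m, n1)
        ks = list(range(lo, hi + 1))
        nums = [comb(n1, k) * comb(n2, m - k) for k in ks]
        denom = comb(n1 + n2, m)
        for k, num in zip(ks, nums):
            total = sum(v for v in nums if v <= num)
            out[(k, m - k)] = total / denom
    return out


def wilcoxon_exact_pvalue(x: list[float], y: list[float]) -> float:
    """Exact two-sided rank-sum p-value by enumerating all assignments of
    ranks to the first group (ties not supported)."""
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "exact oracle requires no ties"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    w_obs = sum(ranks[v] for v in x)
    n, m = len(x), len(y)
    all_ranks = list(range(1, n + m + 1))
    ws = [sum(c) for c in combinations(all_ranks, n)]
    mean_w = n * (n + m + 1) / 2
    dev = abs(w_obs - mean_w)
    extreme = sum(1 for w in ws if abs(w - mean_w) >= dev - 1e-12)
    return extreme / len(ws)


def mannwhitney_normal_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    """Normal-approximation two-sided rank-sum p-value with tie
    correction, computed from first principles."""
    from scipy.special import ndtr

    pooled = np.concatenate([x, y])
    order = pooled.argsort(kind="mergesort")
    ranks = np.empty(len(pooled))
    sorted_vals = pooled[order]
    i = 0
    pos = np.empty(len(pooled))
    while i < len(sorted_vals):
        j = i
        while j < len(sorted_vals) and sorted_vals[j] == sorted_vals[i]:
            j += 1
        pos[i:j] = (i + j + 1) / 2  # average rank, 1-based
        i = j
    ranks[order] = pos
    n1, n2 = len(x), len(y)
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    mu = n1 * n2 / 2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts)
    n = n1 + n2
    var = n1 * n2 / 12 * ((n + 1) - tie_term / (n * (n - 1)))
    if var == 0:
        return 1.0
    z = (u - mu - np.sign(u - mu) * 0.5) / np.sqrt(var)  # continuity corrected
    return float(2 * (1 - ndtr(abs(z))))


def brute_force_qc(
    counts: np.ndarray,
    mito_rows: list[int],
    mito_max: float,
    features_min: int,
    features_max: int | None,
) -> list[int]:
    """Surviving cell indices by a naive per-cell scan of a dense matrix."""
    survivors = []
    for c in range(counts.shape[1]):
        col = counts[:, c]
        total = col.sum()
        mito = col[mito_rows].sum() if mito_rows else 0
        frac = mito / total if total > 0 else 0.0
        nfeat = int((col > 0).sum())
        ok = frac < mito_max and nfeat > features_min
        if features_max is not None:
            ok = ok and nfeat < features_max
        if ok:
            survivors.append(c)
    return survivors
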