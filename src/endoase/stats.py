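"""Shared statistical primitives: vectorised rank-sum tests and BH FDR."""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["ranksum_pvalues", "bh_adjust"]


def _tie_terms(X: np.ndarray) -> np.ndarray:
    """Per-column sum of t^3 - t over tied groups (for the rank-sum
    variance correction)."""
    N, g = X.shape
    S = np.sort(X, axis=0)
    change = np.vstack([np.ones((1, g), dtype=bool), S[1:] != S[:-1]])
    out = np.empty(g)
    for j in range(g):
        starts = np.flatnonzero(change[:, j])
        t = np.diff(np.append(starts, N))
        out[j] = float((t.astype(np.int64) ** 3 - t).sum())
    return out


def ranksum_pvalues(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum p-values, column by column.

    Normal approximation with tie correction (the convention of the
    single-cell marker-test tool family); columns where the variance
    degenerates (all values tied) get p = 1.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    n1, g = A.shape
    n2 = B.shape[0]
    N = n1 + n2
    X = np.vstack([A, B])
    ranks = stats.rankdata(X, axis=0)
    R1 = ranks[:n1].sum(axis=0)
    U = R1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    tie = _tie_terms(X)
    sigma2 = n1 * n2 / 12.0 * ((N + 1) - tie / (N * (N - 1.0)))
    p = np.ones(g)
    ok = sigma2 > 0
    z = np.zeros(g)
    z[ok] = (U[ok] - mu) / np.sqrt(sigma2[ok])
    p[ok] = np.clip(2.0 * stats.norm.sf(np.abs(z[ok])), 0.0, 1.0)
    return p


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, order
    preserving with the input)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
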