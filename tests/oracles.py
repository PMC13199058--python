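"""Independent brute-force oracles used to check the geometric and
statistical routines. These deliberately avoid the code paths of the
implementation: hull membership is decided by least-squares feasibility of a
convex combination (NNLS), distances by exhaustive pairwise enumeration, and
Mann-Whitney p-values by full enumeration of group allocations."""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
from scipy.optimize import nnls
from scipy.spatial.distance import cdist


def in_hull_nnls(points: np.ndarray, queries: np.ndarray, tol: float = 1e-7) -> np.ndarray:
    """Is each query a convex combination of ``points``?

    Solves min ||A w - b|| with w >= 0 where A stacks the points and a row of
    ones; the query is in the hull iff the residual vanishes. Independent of
    any facet construction.
    """
    scale = 1.0 + float(np.max(np.abs(points)))
    a = np.vstack([points.T / scale, np.ones(len(points))])
    out = np.zeros(len(queries), dtype=bool)
    for i, q in enumerate(queries):
        b = np.concatenate([q / scale, [1.0]])
        _, resid = nnls(a, b)
        out[i] = resid <= tol
    return out


def min_distance_mm(queries: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Exact nearest distance from each query point to the target set."""
    return cdist(queries, targets).min(axis=1)


def all_voxel_centers(shape, spacing) -> np.ndarray:
    idx = np.indices(shape).reshape(3, -1).T
    return idx * np.asarray(spacing)


def mann_whitney_exact_p(a, b) -> float:
    """Two-sided exact Mann-Whitney p by full enumeration of allocations.

    Enumerates every way of assigning the pooled values to the first group,
    computes the U statistic of each allocation from the pairwise
    greater-than matrix, and doubles the smaller tail of the observed U
    (capped at 1). Requires a tie-free pooled sample.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    n = len(pooled)
    n1 = len(a)
    assert len(np.unique(pooled)) == n, "oracle requires tie-free samples"

    greater = (pooled[:, None] > pooled[None, :]).astype(float)
    picks = np.array(list(combinations(range(n), n1)))
    masks = np.zeros((len(picks), n))
    masks[np.arange(len(picks))[:, None], picks] = 1.0
    # U(allocation) = number of (i in A, j in B) pairs with x_i > x_j
    us = np.einsum("ci,ij,cj->c", masks, greater, 1.0 - masks)
    u_obs = float(greater[:n1, n1:].sum())
    total = comb(n, n1)
    assert len(picks) == total
    p_le = np.count_nonzero(us <= u_obs + 1e-9) / total
    p_ge = np.count_nonzero(us >= u_obs - 1e-9) / total
    return min(1.0, 2.0 * min(p_le, p_ge))


def pearson_chi2(table: np.ndarray) -> float:
    """Textbook Pearson chi-squared: sum (O - E)^2 / E."""
    table = np.asarray(table, dtype=float)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / table.sum()
    return float(((table - expected) ** 2 / expected).sum())
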