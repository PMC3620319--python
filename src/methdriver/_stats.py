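"""Shared statistical primitives.

Every hypergeometric tail, BH adjustment and two-sample t-test in the
package goes through this module so that the corresponding tests (exact
enumeration for small universes, cross-checks against scipy/statsmodels)
cover all call sites at once.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "bh_qvalues",
    "bh_reject_columns",
    "hypergeom_sf",
    "welch_ttest_matrix",
    "ttest_groups",
]


def bh_qvalues(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (q-values) for a 1-D array."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def bh_reject_columns(pmat: np.ndarray, q_cut: float) -> np.ndarray:
    """BH step-up rejection applied independently to each column.

    Vectorized over columns so that the permutation stage can process all
    replicates at once; equivalent to running ``multipletests`` per column.

    Parameters
    ----------
    pmat : (m, B) array of p-values (m tests, B independent families).
    q_cut : FDR level.

    Returns
    -------
    (m, B) boolean array: True where the hypothesis is rejected.
    """
    P = np.asarray(pmat, dtype=float)
    if P.ndim != 2:
        raise ValueError("expected a 2-D p-value matrix")
    m, _ = P.shape
    order = np.argsort(P, axis=0)
    p_sorted = np.take_along_axis(P, order, axis=0)
    thresh = q_cut * np.arange(1, m + 1, dtype=float)[:, None] / m
    ok = p_sorted <= thresh
    any_ok = ok.any(axis=0)
    # index of the largest k with p_(k) <= q*k/m, per column
    kmax = m - 1 - np.argmax(ok[::-1, :], axis=0)
    idx = np.maximum(kmax, 0)[None, :]
    cut = np.take_along_axis(p_sorted, idx, axis=0)[0]
    cut = np.where(any_ok, cut, -np.inf)
    return P <= cut[None, :]


def hypergeom_sf(k: int, N: int, K: int, n: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    Drawing ``n`` items from a universe of ``N`` containing ``K`` marked
    items; probability of observing at least ``k`` marked in the draw.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent hypergeometric parameters N={N}, K={K}, n={n}")
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def welch_ttest_matrix(
    X: np.ndarray, groups_a: np.ndarray, groups_b: np.ndarray
) -> np.ndarray:
    """Two-sided Welch t-test p-values for many genes x many group pairs.

    Parameters
    ----------
    X : (m, s) value matrix (features x samples).
    groups_a, groups_b : (s, B) boolean membership matrices; column ``b``
        defines the two groups of replicate ``b``. Groups must be disjoint
        per column with at least two members each.

    Returns
    -------
    (m, B) array of p-values. Features with zero pooled standard error in a
    replicate get p = 1 (the zero-variance convention).
    """
    X = np.asarray(X, dtype=float)
    A = np.asarray(groups_a, dtype=float)
    B_ = np.asarray(groups_b, dtype=float)
    nA = A.sum(axis=0)
    nB = B_.sum(axis=0)
    if np.any(nA < 2) or np.any(nB < 2):
        raise ValueError("each group needs at least 2 samples")
    sA = X @ A
    sB = X @ B_
    mA = sA / nA
    mB = sB / nB
    X2 = X * X
    vA = np.maximum((X2 @ A - nA * mA**2) / (nA - 1), 0.0)
    vB = np.maximum((X2 @ B_ - nB * mB**2) / (nB - 1), 0.0)
    se2 = vA / nA + vB / nB
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mA - mB) / np.sqrt(se2)
        df_num = se2**2
        df_den = (vA / nA) ** 2 / (nA - 1) + (vB / nB) ** 2 / (nB - 1)
        df = df_num / df_den
    p = np.ones_like(t)
    valid = se2 > 0
    p[valid] = 2.0 * stats.t.sf(np.abs(t[valid]), df[valid])
    return p


def ttest_groups(
    values: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray, equal_var: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise two-sample t-test between two column index sets.

    Returns (p, mean_diff) with mean_diff = mean(A) - mean(B). Rows where
    the statistic is undefined (zero variance in both groups) get p = 1.
    """
    V = np.atleast_2d(np.asarray(values, dtype=float))
    a = V[:, idx_a]
    b = V[:, idx_b]
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    p = np.asarray(res.pvalue, dtype=float)
    p = np.where(np.isnan(p), 1.0, p)
    diff = a.mean(axis=1) - b.mean(axis=1)
    return p, diff
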