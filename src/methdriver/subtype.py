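"""Tumor clustering on driver-locus profiles and subtype-specific drivers.

Tumors are clustered on their ternary states over the driver loci with a
Jaccard-style distance and average (UPGMA) linkage; subtype specificity
of a driver alteration is tested with the hypergeometric upper tail of
its altered-tumor count inside each subtype.

The ternary Jaccard treats +1 and -1 as distinct categories: similarity
is |positions with equal nonzero state| / |positions nonzero in either
profile|; two all-zero profiles count as identical. A binarized variant
(any nonzero state collapses to 1) is available for sensitivity checks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from ._stats import bh_qvalues, hypergeom_sf
from .data_model import ValidationError

logger = logging.getLogger(__name__)


def jaccard_distance(a, b, binarize: bool = False) -> float:
    """Ternary Jaccard distance between two alteration profiles."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValidationError("profiles must have equal length")
    if binarize:
        a = (a != 0).astype(int)
        b = (b != 0).astype(int)
    union = int(((a != 0) | (b != 0)).sum())
    if union == 0:
        return 0.0
    equal_nonzero = int(((a == b) & (a != 0)).sum())
    return 1.0 - equal_nonzero / union


def pairwise_jaccard(ternary: pd.DataFrame, binarize: bool = False) -> np.ndarray:
    """Square matrix of ternary Jaccard distances between tumor columns."""
    X = ternary.to_numpy()
    if binarize:
        X = (X != 0).astype(np.int8)
    H = (X == 1).astype(float)
    L = (X == -1).astype(float)
    NZ = H + L
    both = NZ.T @ NZ
    n = NZ.sum(axis=0)
    union = n[:, None] + n[None, :] - both
    equal = H.T @ H + L.T @ L
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, equal / np.where(union > 0, union, 1), 1.0)
    D = 1.0 - sim
    np.fill_diagonal(D, 0.0)
    return D


@dataclass
class ClusterResult:
    labels: pd.Series  # tumor -> cluster id in 1..k
    linkage_matrix: np.ndarray
    sample_order: list[str]  # canonical (sorted) order used for the linkage
    newick: str


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick tree with branch lengths."""
    n = len(labels)
    height = {i: 0.0 for i in range(n)}
    rep = {i: labels[i] for i in range(n)}
    for step, (a, b, dist, _count) in enumerate(Z):
        a, b = int(a), int(b)
        node = n + step
        la = max(dist - height[a], 0.0)
        lb = max(dist - height[b], 0.0)
        rep[node] = f"({rep[a]}:{la:.6g},{rep[b]}:{lb:.6g})"
        height[node] = dist
    return rep[n + len(Z) - 1] + ";" if len(Z) else f"({','.join(labels)});"


def hierarchical_cluster(
    ternary: pd.DataFrame, k: int, binarize: bool = False
) -> ClusterResult:
    """UPGMA clustering of tumor columns on their driver-locus profiles.

    Tumor columns are put in canonical (sorted-id) order before the
    linkage is computed, so the result is invariant to the input column
    order; the merge heights are non-decreasing by the UPGMA property.
    Labels are renumbered 1..k by first appearance in canonical order.
    """
    n_tumors = ternary.shape[1]
    if k > n_tumors:
        raise ValidationError(f"k={k} exceeds the {n_tumors} tumors available")
    if ternary.shape[0] == 0:
        raise ValidationError("no driver loci to cluster on")
    order = sorted(ternary.columns)
    T = ternary[order]
    D = pairwise_jaccard(T, binarize=binarize)
    Z = linkage(squareform(D, checks=False), method="average")
    raw = fcluster(Z, t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    for lab in raw:
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
    labels = pd.Series([relabel[lab] for lab in raw], index=order, name="cluster")
    return ClusterResult(
        labels=labels,
        linkage_matrix=Z,
        sample_order=order,
        newick=linkage_to_newick(Z, order),
    )


def cluster_subtype_table(labels: pd.Series, subtypes: pd.Series) -> pd.DataFrame:
    """Plain cluster x subtype contingency table (labeled tumors only)."""
    sub = subtypes.dropna()
    common = labels.index.intersection(sub.index)
    return pd.crosstab(labels.loc[common], sub.loc[common])


@dataclass
class SubtypeCall:
    locus_id: str
    gene_id: str
    direction: str
    subtype: str
    n_subtype: int
    k_subtype: int
    n_total: int
    k_total: int
    p: float
    q: float = np.nan
    specific: bool = False

    @property
    def freq_subtype(self) -> float:
        return self.k_subtype / self.n_subtype

    @property
    def freq_rest(self) -> float:
        rest_n = self.n_total - self.n_subtype
        return (self.k_total - self.k_subtype) / rest_n if rest_n else np.nan


def subtype_specific_test(
    ternary: pd.DataFrame,
    locus_directions: dict[str, str],
    subtypes: pd.Series,
    annotation: pd.DataFrame,
    q_cut: float = 0.05,
) -> list[SubtypeCall]:
    """Hypergeometric subtype specificity of each driver locus.

    For each driver locus (taken in its driver direction) and each
    subtype: k altered tumors in the subtype out of n subtype members,
    against K altered overall among the N labeled tumors; p = P(X >= k).
    BH across all (locus, subtype) pairs; a call is specific when q <
    ``q_cut`` and the in-subtype frequency exceeds the rest frequency.
    Unlabeled tumors are excluded with a logged count.
    """
    sub = subtypes.dropna()
    labeled = [s for s in ternary.columns if s in sub.index]
    n_dropped = ternary.shape[1] - len(labeled)
    if n_dropped:
        logger.info("excluded %d tumor(s) without subtype label", n_dropped)
    levels = sorted(sub.loc[labeled].unique())
    if len(levels) < 2:
        raise ValidationError("at least 2 subtype labels are required")
    N = len(labeled)
    sign = {"hyper": 1, "hypo": -1}
    calls: list[SubtypeCall] = []
    for locus, direction in sorted(locus_directions.items()):
        states = ternary.loc[locus, labeled]
        altered = states == sign[direction]
        K = int(altered.sum())
        gene = str(annotation.loc[locus, "gene_id"])
        for subtype in levels:
            members = [s for s in labeled if sub.loc[s] == subtype]
            k = int(altered[members].sum())
            p = hypergeom_sf(k, N, K, len(members))
            calls.append(
                SubtypeCall(
                    locus_id=locus,
                    gene_id=gene,
                    direction=direction,
                    subtype=subtype,
                    n_subtype=len(members),
                    k_subtype=k,
                    n_total=N,
                    k_total=K,
                    p=p,
                )
            )
    if calls:
        qs = bh_qvalues(np.array([c.p for c in calls]))
        for c, q in zip(calls, qs):
            c.q = float(q)
            c.specific = bool(q < q_cut and c.freq_subtype > (c.freq_rest or 0.0))
    return calls


def subtype_specific_genes(calls: list[SubtypeCall]) -> dict[str, set[str]]:
    """Gene-level rollup: a gene is subtype-specific if any locus is."""
    out: dict[str, set[str]] = {}
    for c in calls:
        if c.specific:
            out.setdefault(c.subtype, set()).add(c.gene_id)
    return out


def subtype_calls_frame(calls: list[SubtypeCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "locus_id": c.locus_id,
                "gene_id": c.gene_id,
                "direction": c.direction,
                "subtype": c.subtype,
                "freq_subtype": c.freq_subtype,
                "freq_rest": c.freq_rest,
                "k_subtype": c.k_subtype,
                "n_subtype": c.n_subtype,
                "k_total": c.k_total,
                "n_total": c.n_total,
                "p": c.p,
                "q": c.q,
                "specific": c.specific,
            }
            for c in calls
        ]
    )
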