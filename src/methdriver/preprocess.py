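"""Beta-value computation, probe filters and differential expression.

The raw-intensity path converts methylated (M) and unmethylated (U)
fluorescence intensities to the bounded beta value
``max(M, 0) / (|U| + |M| + 100)``; the offset of 100 regularizes loci
with near-zero total signal. When beta matrices are supplied directly the
conversion is bypassed. Probe reliability is judged from detection
p-values: a locus is dropped when more than 10% of samples fail detection
at p > 0.05. Sex-chromosome loci are excluded to avoid gender-driven
methylation differences masquerading as tumor alterations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _stats
from .data_model import SEX_CHROMOSOMES, ValidationError

logger = logging.getLogger(__name__)


def compute_beta(M, U):
    """Beta value max(M, 0) / (|U| + |M| + 100); always in [0, 1).

    Accepts scalars or aligned arrays/DataFrames. Negative raw intensities
    are legal: the numerator is clamped at zero and the denominator uses
    absolute values.
    """
    M_arr = np.asarray(M, dtype=float)
    U_arr = np.asarray(U, dtype=float)
    if not (np.isfinite(M_arr).all() and np.isfinite(U_arr).all()):
        raise ValidationError("intensities must be finite")
    beta = np.maximum(M_arr, 0.0) / (np.abs(U_arr) + np.abs(M_arr) + 100.0)
    if isinstance(M, pd.DataFrame):
        return pd.DataFrame(beta, index=M.index, columns=M.columns)
    if np.isscalar(M) or M_arr.ndim == 0:
        return float(beta)
    return beta


def filter_unreliable_loci(
    detection_p: pd.DataFrame, p_cut: float = 0.05, max_fraction: float = 0.10
) -> pd.Index:
    """Locus ids passing the detection-p reliability filter.

    A locus is dropped iff the fraction of samples with detection p >
    ``p_cut`` is strictly greater than ``max_fraction`` — exactly at the
    boundary the locus is retained.
    """
    vals = detection_p.to_numpy(dtype=float)
    frac_failing = (vals > p_cut).mean(axis=1)
    keep = frac_failing <= max_fraction
    dropped = int((~keep).sum())
    if dropped:
        logger.info("detection-p filter dropped %d of %d loci", dropped, len(keep))
    return detection_p.index[keep]


def exclude_sex_chromosomes(loci: pd.Index, annotation: pd.DataFrame) -> pd.Index:
    """Drop loci annotated on chromosome X or Y.

    Every locus must be present in the annotation (indexed by locus_id).
    """
    missing = loci.difference(annotation.index)
    if len(missing):
        raise ValidationError(f"loci missing from annotation: {missing.tolist()[:10]}")
    chrom = annotation.loc[loci, "chromosome"]
    keep = ~chrom.isin(SEX_CHROMOSOMES)
    retained = loci[keep.to_numpy()]
    if len(retained) == 0:
        logger.warning("all loci were on sex chromosomes; nothing retained")
    return retained


@dataclass
class DEResult:
    """Per-gene differential expression between two sample groups."""

    table: pd.DataFrame  # columns: p, q, mean_diff, direction, de

    @property
    def de_genes(self) -> frozenset[str]:
        return frozenset(self.table.index[self.table["de"]])


def differential_expression(
    expr: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    q_cut: float = 0.05,
    equal_var: bool = False,
) -> DEResult:
    """Two-sided two-sample t-test per gene with BH adjustment.

    ``direction`` is the sign of mean(A) - mean(B); a gene is DE iff its
    BH q-value is below ``q_cut``. Genes with zero variance in both groups
    get p = 1 (the test is undefined; this keeps BH well-behaved and is
    conservative). Welch's unequal-variance flavor is the default.
    """
    set_a, set_b = set(group_a), set(group_b)
    if set_a & set_b:
        raise ValidationError("expression groups must be disjoint")
    if len(set_a) < 2 or len(set_b) < 2:
        raise ValidationError("each expression group needs at least 2 samples")
    missing = (set_a | set_b) - set(expr.columns)
    if missing:
        raise ValidationError(f"samples absent from expression matrix: {sorted(missing)[:5]}")
    col_pos = {s: i for i, s in enumerate(expr.columns)}
    ia = np.array([col_pos[s] for s in group_a])
    ib = np.array([col_pos[s] for s in group_b])
    p, diff = _stats.ttest_groups(expr.to_numpy(dtype=float), ia, ib, equal_var=equal_var)
    q = _stats.bh_qvalues(p)
    table = pd.DataFrame(
        {
            "p": p,
            "q": q,
            "mean_diff": diff,
            "direction": np.sign(diff).astype(int),
            "de": q < q_cut,
        },
        index=expr.index,
    )
    return DEResult(table)
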