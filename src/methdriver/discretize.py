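"""Per-sample ternary discretization of tumor methylation profiles.

Each tumor's beta value at each locus is converted to a Z-score against
the mean and standard deviation of that locus across the normal samples,
tested with a two-sided Z-test, and BH-adjusted. States: +1
(hypermethylated), -1 (hypomethylated), 0 (no differential methylation).

The adjustment family is each tumor sample's own locus profile by default
(each sample is discretized independently); a single global family over
all (locus, tumor) pairs is available via ``scope="global"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_qvalues
from .data_model import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class NormalReference:
    """Per-locus mean/sd of beta across the normal samples.

    Loci whose normal-sample standard deviation is zero have no defined
    Z-score and are dropped at construction, with their ids recorded.
    """

    mean: pd.Series
    sd: pd.Series
    n_normal: int
    dropped_zero_sd: list[str] = field(default_factory=list)

    @property
    def loci(self) -> pd.Index:
        return self.mean.index


def normal_reference(beta: pd.DataFrame, normals: list[str]) -> NormalReference:
    """Build the normal reference from >= 2 normal-sample columns."""
    normals = list(normals)
    if len(normals) < 2:
        raise ValidationError("at least 2 normal samples are required")
    missing = set(normals) - set(beta.columns)
    if missing:
        raise ValidationError(f"normal samples absent from beta matrix: {sorted(missing)[:5]}")
    sub = beta[normals]
    mean = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    degenerate = sd <= 0
    dropped = beta.index[degenerate].tolist()
    if dropped:
        logger.info("dropped %d locus/loci with zero normal-reference sd", len(dropped))
    return NormalReference(
        mean=mean[~degenerate],
        sd=sd[~degenerate],
        n_normal=len(normals),
        dropped_zero_sd=dropped,
    )


def zscore(beta, ref_mean, ref_sd):
    """(beta - mean) / sd; requires sd > 0."""
    sd = np.asarray(ref_sd, dtype=float)
    if np.any(sd <= 0):
        raise ValidationError("zero normal-reference sd: Z-score undefined")
    return (np.asarray(beta, dtype=float) - np.asarray(ref_mean, dtype=float)) / sd


def ztest_p(z):
    """Two-sided standard-normal p-value: 2 * (1 - Phi(|z|))."""
    return 2.0 * stats.norm.sf(np.abs(np.asarray(z, dtype=float)))


def discretize_matrix(
    tumor_beta: pd.DataFrame,
    ref: NormalReference,
    q_cut: float = 0.05,
    scope: str = "per_sample",
) -> pd.DataFrame:
    """Ternary alteration matrix for the tumor columns of ``tumor_beta``.

    State = sign(z) where the BH-adjusted Z-test p-value is below
    ``q_cut``, else 0. ``scope`` chooses the BH family: each tumor's locus
    profile independently (``"per_sample"``, default) or all (locus,
    tumor) pairs jointly (``"global"``).
    """
    if scope not in ("per_sample", "global"):
        raise ValueError(f"unknown adjustment scope {scope!r}")
    missing = tumor_beta.index.difference(ref.loci)
    if len(missing):
        raise ValidationError(
            f"loci absent from normal reference: {missing.tolist()[:10]}"
        )
    mean = ref.mean.loc[tumor_beta.index].to_numpy()
    sd = ref.sd.loc[tumor_beta.index].to_numpy()
    z = (tumor_beta.to_numpy(dtype=float) - mean[:, None]) / sd[:, None]
    p = ztest_p(z)
    if scope == "per_sample":
        q = np.column_stack([bh_qvalues(p[:, j]) for j in range(p.shape[1])])
    else:
        q = bh_qvalues(p.ravel()).reshape(p.shape)
    states = np.where(q < q_cut, np.sign(z), 0.0).astype(np.int8)
    return pd.DataFrame(states, index=tumor_beta.index, columns=tumor_beta.columns)


def write_ternary(ternary: pd.DataFrame, path) -> None:
    ternary.astype(int).to_csv(path, sep="\t")


def read_ternary(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    vals = df.to_numpy()
    if not np.isin(vals, (-1, 0, 1)).all():
        raise ValidationError("ternary matrix entries must be in {-1, 0, 1}")
    return df.astype(np.int8)
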