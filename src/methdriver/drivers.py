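"""The driver-calling cascade.

A candidate alteration (a locus carried in one direction by at least 10%
of tumors) must clear three conditions to be called a driver:

1. *cis effect* — the candidate gene's own expression differs between
   altered and unaltered tumors (t-test, BH FDR across candidates),
   in the direction promoter methylation predicts (hypermethylation →
   lower expression, hypomethylation → higher).
2. *downstream effect* — the number of genes differentially expressed
   between altered and unaltered tumors exceeds what random tumor
   groupings of the same sizes produce (B random draws; empirical
   p BH-adjusted across candidates).
3. *pathway disturbance* — those downstream genes are enriched in at
   least one cancer-associated pathway (hypergeometric upper tail, BH
   across the pathways tested for the candidate).

A gene with at least one driver alteration locus is a driver gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _stats
from .config import AnalysisConfig
from .data_model import ValidationError
from .preprocess import differential_expression

logger = logging.getLogger(__name__)

HYPER = "hyper"
HYPO = "hypo"
_DIRECTION_SIGN = {HYPER: 1, HYPO: -1}


@dataclass(frozen=True)
class CandidateLocus:
    """A frequency-passing (locus, direction) pair and its tumor groups."""

    locus_id: str
    gene_id: str
    direction: str  # "hyper" | "hypo"
    altered_samples: tuple[str, ...]
    zero_samples: tuple[str, ...]

    @property
    def sign(self) -> int:
        return _DIRECTION_SIGN[self.direction]


@dataclass
class PermutationNull:
    """Replicate downstream-DE counts for one candidate's group sizes."""

    n_altered: int
    n_zero: int
    counts: np.ndarray  # length B
    p: float  # empirical p of the observed count

    @property
    def B(self) -> int:
        return len(self.counts)


@dataclass
class DriverCall:
    """Full per-candidate provenance through the three conditions."""

    locus_id: str
    gene_id: str
    direction: str
    altered_sample_count: int
    unaltered_sample_count: int
    tested: bool = False
    skip_reason: str | None = None
    cis_p: float = np.nan
    cis_q: float = np.nan
    cis_direction_ok: bool = False
    cis_pass: bool = False
    downstream_gene_ids: frozenset[str] = field(default_factory=frozenset)
    observed_downstream_count: int = 0
    permutation_p: float = np.nan
    permutation_q: float = np.nan
    permutation_pass: bool = False
    enriched_pathways: dict[str, tuple[int, float, float]] = field(default_factory=dict)
    best_pathway_q: float = np.nan
    pathway_pass: bool = False
    is_driver: bool = False


@dataclass
class DriverResult:
    calls: list[DriverCall]
    driver_loci: list[str]
    driver_genes: list[str]
    cascade: dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.calls:
            rows.append(
                {
                    "locus_id": c.locus_id,
                    "gene_id": c.gene_id,
                    "direction": c.direction,
                    "n_altered": c.altered_sample_count,
                    "n_unaltered": c.unaltered_sample_count,
                    "tested": c.tested,
                    "skip_reason": c.skip_reason or "",
                    "cis_p": c.cis_p,
                    "cis_q": c.cis_q,
                    "cis_direction_ok": c.cis_direction_ok,
                    "cis_pass": c.cis_pass,
                    "n_downstream": c.observed_downstream_count,
                    "permutation_p": c.permutation_p,
                    "permutation_q": c.permutation_q,
                    "permutation_pass": c.permutation_pass,
                    "best_pathway_q": c.best_pathway_q,
                    "pathway_pass": c.pathway_pass,
                    "is_driver": c.is_driver,
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# stage 0: frequency filter


def frequency_filter(
    ternary: pd.DataFrame, annotation: pd.DataFrame, min_fraction: float = 0.10
) -> list[CandidateLocus]:
    """Candidates altered in >= ``min_fraction`` of tumors, one per direction.

    The boundary is inclusive ("at least 10%"). A gene with both a hyper
    and a hypo candidate among its loci is excluded outright — both of
    its candidates are dropped.
    """
    if ternary.size == 0:
        return []
    missing = ternary.index.difference(annotation.index)
    if len(missing):
        raise ValidationError(f"loci missing from annotation: {missing.tolist()[:10]}")
    n_tumors = ternary.shape[1]
    genes = annotation.loc[ternary.index, "gene_id"]
    vals = ternary.to_numpy()
    candidates: list[CandidateLocus] = []
    for direction, sgn in _DIRECTION_SIGN.items():
        counts = (vals == sgn).sum(axis=1)
        for i in np.flatnonzero(counts / n_tumors >= min_fraction):
            row = vals[i]
            altered = tuple(ternary.columns[row == sgn])
            zero = tuple(ternary.columns[row == 0])
            candidates.append(
                CandidateLocus(
                    locus_id=str(ternary.index[i]),
                    gene_id=str(genes.iloc[i]),
                    direction=direction,
                    altered_samples=altered,
                    zero_samples=zero,
                )
            )
    per_gene_dirs: dict[str, set[str]] = {}
    for c in candidates:
        per_gene_dirs.setdefault(c.gene_id, set()).add(c.direction)
    both = {g for g, dirs in per_gene_dirs.items() if len(dirs) == 2}
    if both:
        logger.info("excluded %d gene(s) altered in both directions", len(both))
    kept = [c for c in candidates if c.gene_id not in both]
    kept.sort(key=lambda c: (c.locus_id, c.direction))
    return kept


# ---------------------------------------------------------------------------
# condition 1: cis effect


def cis_statistic(
    candidate: CandidateLocus, expr: pd.DataFrame, equal_var: bool = False
) -> tuple[float, float]:
    """(p, mean_diff) of the candidate's own gene, altered vs zero-state."""
    row = expr.loc[[candidate.gene_id]].to_numpy(dtype=float)
    col_pos = {s: i for i, s in enumerate(expr.columns)}
    ia = np.array([col_pos[s] for s in candidate.altered_samples if s in col_pos])
    ib = np.array([col_pos[s] for s in candidate.zero_samples if s in col_pos])
    p, diff = _stats.ttest_groups(row, ia, ib, equal_var=equal_var)
    return float(p[0]), float(diff[0])


def run_cis_stage(
    candidates: list[CandidateLocus],
    expr: pd.DataFrame,
    calls: dict[tuple[str, str], DriverCall],
    config: AnalysisConfig,
) -> list[CandidateLocus]:
    """Condition 1 over all candidates; BH across the candidates tested.

    Concordance rule: a hyper candidate must have lower own-gene
    expression in the altered group, a hypo candidate higher.
    """
    testable: list[CandidateLocus] = []
    stats_rows: list[tuple[float, float]] = []
    for c in candidates:
        call = calls[(c.locus_id, c.direction)]
        n_alt = sum(s in expr.columns for s in c.altered_samples)
        n_zero = sum(s in expr.columns for s in c.zero_samples)
        if c.gene_id not in expr.index:
            call.skip_reason = "gene absent from expression matrix"
            logger.info("skipping %s (%s): %s", c.locus_id, c.gene_id, call.skip_reason)
            continue
        if min(n_alt, n_zero) < config.min_group_size:
            call.skip_reason = f"group below minimum size {config.min_group_size}"
            logger.info("skipping %s (%s): %s", c.locus_id, c.gene_id, call.skip_reason)
            continue
        call.tested = True
        testable.append(c)
        stats_rows.append(cis_statistic(c, expr, equal_var=config.equal_var))
    if not testable:
        return []
    p = np.array([r[0] for r in stats_rows])
    diffs = np.array([r[1] for r in stats_rows])
    q = _stats.bh_qvalues(p)
    survivors: list[CandidateLocus] = []
    for c, pi, qi, di in zip(testable, p, q, diffs):
        call = calls[(c.locus_id, c.direction)]
        call.cis_p = float(pi)
        call.cis_q = float(qi)
        # expected sign of (altered - zero) mean difference is -direction
        call.cis_direction_ok = bool(di * c.sign < 0)
        call.cis_pass = bool(qi < config.cis_q and call.cis_direction_ok)
        if call.cis_pass:
            survivors.append(c)
    return survivors


# ---------------------------------------------------------------------------
# condition 2: downstream genes and permutation null


def downstream_genes(
    candidate: CandidateLocus,
    expr: pd.DataFrame,
    q_cut: float = 0.05,
    equal_var: bool = False,
) -> frozenset[str]:
    """DE genes between altered and zero-state tumors, minus the gene itself.

    Tumors carrying the opposite state at the locus belong to neither
    group and are excluded from the comparison.
    """
    group_a = [s for s in candidate.altered_samples if s in expr.columns]
    group_b = [s for s in candidate.zero_samples if s in expr.columns]
    de = differential_expression(expr, group_a, group_b, q_cut=q_cut, equal_var=equal_var)
    return frozenset(de.de_genes - {candidate.gene_id})


class PermutationNullCache:
    """Replicate downstream-DE counts, shared across equal group sizes.

    The null distribution of the DE count depends only on the two group
    sizes, so replicate draws are generated once per (n_altered, n_zero)
    pair under a seed derived from the base seed and the sizes, and
    reused for every candidate with those sizes. Per-candidate exclusion
    of the candidate's own gene is applied by subtracting, per replicate,
    the indicator of that gene being DE.
    """

    def __init__(
        self,
        expr: pd.DataFrame,
        tumor_samples: list[str],
        B: int,
        de_q: float,
        base_seed: int,
        shared: bool = True,
    ) -> None:
        self.values = expr.to_numpy(dtype=float)
        self.gene_pos = {g: i for i, g in enumerate(expr.index)}
        col_pos = {s: i for i, s in enumerate(expr.columns)}
        self.tumor_idx = np.array([col_pos[s] for s in tumor_samples if s in col_pos])
        self.B = B
        self.de_q = de_q
        self.base_seed = base_seed
        self.shared = shared
        self._cache: dict[tuple[int, int], tuple[np.ndarray, dict[int, np.ndarray]]] = {}
        self._serial = 0

    def _simulate(self, n_alt: int, n_zero: int) -> tuple[np.ndarray, dict[int, np.ndarray]]:
        n = len(self.tumor_idx)
        if n_alt + n_zero > n:
            raise ValidationError(
                f"group sizes {n_alt}+{n_zero} exceed {n} available tumors"
            )
        seed_key = [self.base_seed, n_alt, n_zero]
        if not self.shared:
            self._serial += 1
            seed_key.append(self._serial)
        rng = np.random.default_rng(seed_key)
        # disjoint groups per replicate: first n_alt and next n_zero of a permutation
        keys = rng.random((self.B, n))
        order = np.argsort(keys, axis=1)
        pick = self.tumor_idx[order[:, : n_alt + n_zero]]
        A = np.zeros((self.values.shape[1], self.B), dtype=float)
        Z = np.zeros_like(A)
        rows = np.arange(self.B)
        for j in range(n_alt):
            A[pick[:, j], rows] = 1.0
        for j in range(n_alt, n_alt + n_zero):
            Z[pick[:, j], rows] = 1.0
        P = _stats.welch_ttest_matrix(self.values, A, Z)
        de_mask = _stats.bh_reject_columns(P, self.de_q)
        counts = de_mask.sum(axis=0).astype(np.int64)
        gene_rows, reps = np.nonzero(de_mask)
        per_gene: dict[int, np.ndarray] = {}
        for g in np.unique(gene_rows):
            per_gene[int(g)] = reps[gene_rows == g]
        return counts, per_gene

    def counts_excluding(self, n_alt: int, n_zero: int, gene_id: str) -> np.ndarray:
        key = (n_alt, n_zero)
        if key not in self._cache or not self.shared:
            self._cache[key] = self._simulate(n_alt, n_zero)
        counts, per_gene = self._cache[key]
        out = counts.copy()
        gi = self.gene_pos.get(gene_id)
        if gi is not None and gi in per_gene:
            out[per_gene[gi]] -= 1
        return out


def empirical_p(observed: int, replicate_counts: np.ndarray, estimator: str = "literal") -> float:
    """Empirical p of the observed count against replicate counts.

    ``"literal"`` returns r/B where r is the number of replicates whose
    count is at least the observed one (>= — counts at least as extreme
    are counted). ``"add_one"`` returns (r+1)/(B+1), which is bounded
    away from zero at finite B.
    """
    r = int((replicate_counts >= observed).sum())
    B = len(replicate_counts)
    if estimator == "literal":
        return r / B
    if estimator == "add_one":
        return (r + 1) / (B + 1)
    raise ValueError(f"unknown estimator {estimator!r}")


def permutation_test(
    candidate: CandidateLocus,
    observed_count: int,
    cache: PermutationNullCache,
    estimator: str = "literal",
    expr_columns=None,
) -> PermutationNull:
    """Condition-2 permutation null for one candidate."""
    cols = set(expr_columns) if expr_columns is not None else None
    alt = [s for s in candidate.altered_samples if cols is None or s in cols]
    zero = [s for s in candidate.zero_samples if cols is None or s in cols]
    counts = cache.counts_excluding(len(alt), len(zero), candidate.gene_id)
    p = empirical_p(observed_count, counts, estimator=estimator)
    return PermutationNull(n_altered=len(alt), n_zero=len(zero), counts=counts, p=p)


# ---------------------------------------------------------------------------
# condition 3: pathway enrichment


def pathway_enrichment(
    downstream: frozenset[str],
    pathways: dict[str, frozenset[str]],
    background: frozenset[str],
    q_cut: float = 1.00e-4,
) -> tuple[dict[str, tuple[int, float, float]], float, bool]:
    """Hypergeometric enrichment of the downstream set in each pathway.

    Pathways are intersected with the background (the genes measured in
    the expression matrix) before testing; empty intersections are not
    tested. Returns ({pathway: (overlap, p, q)}, best q, pass flag).
    """
    if not background:
        raise ValidationError("enrichment background is empty")
    down = frozenset(downstream) & background
    names, ps, ks = [], [], []
    for name, members in pathways.items():
        K = len(members & background)
        if K == 0:
            continue
        k = len(down & members)
        p = _stats.hypergeom_sf(k, len(background), K, len(down))
        names.append(name)
        ps.append(p)
        ks.append(k)
    if not names:
        return {}, float("nan"), False
    qs = _stats.bh_qvalues(np.array(ps))
    table = {n: (k, float(p), float(q)) for n, k, p, q in zip(names, ks, ps, qs)}
    best_q = float(min(qs))
    return table, best_q, bool(best_q < q_cut)


# ---------------------------------------------------------------------------
# the full cascade


def call_drivers(
    ternary: pd.DataFrame,
    expr: pd.DataFrame,
    annotation: pd.DataFrame,
    pathways: dict[str, frozenset[str]],
    config: AnalysisConfig,
) -> DriverResult:
    """Run frequency filter and the three conditions; emit full provenance.

    Every candidate appears in the result with the statistics of each
    stage it reached, not only the survivors. Stage nesting holds by
    construction: drivers ⊆ condition-2 survivors ⊆ condition-1
    survivors ⊆ candidates.
    """
    candidates = frequency_filter(ternary, annotation, config.min_frequency)
    calls = {
        (c.locus_id, c.direction): DriverCall(
            locus_id=c.locus_id,
            gene_id=c.gene_id,
            direction=c.direction,
            altered_sample_count=len(c.altered_samples),
            unaltered_sample_count=len(c.zero_samples),
        )
        for c in candidates
    }

    cis_survivors = run_cis_stage(candidates, expr, calls, config)

    # condition 2
    tumor_cols = [s for s in ternary.columns if s in expr.columns]
    cache = PermutationNullCache(
        expr,
        tumor_cols,
        B=config.n_permutations,
        de_q=config.de_q,
        base_seed=config.seed,
        shared=config.share_permutation_null,
    )
    perm_ps = []
    for c in cis_survivors:
        call = calls[(c.locus_id, c.direction)]
        down = downstream_genes(c, expr, q_cut=config.de_q, equal_var=config.equal_var)
        call.downstream_gene_ids = down
        call.observed_downstream_count = len(down)
        null = permutation_test(
            c,
            len(down),
            cache,
            estimator=config.permutation_estimator,
            expr_columns=expr.columns,
        )
        call.permutation_p = null.p
        perm_ps.append(null.p)
    if cis_survivors:
        perm_qs = _stats.bh_qvalues(np.array(perm_ps))
        perm_survivors = []
        for c, q in zip(cis_survivors, perm_qs):
            call = calls[(c.locus_id, c.direction)]
            call.permutation_q = float(q)
            call.permutation_pass = bool(q < config.permutation_q)
            if call.permutation_pass:
                perm_survivors.append(c)
    else:
        perm_survivors = []

    # condition 3
    background = frozenset(expr.index)
    if config.pathway_fdr_scope == "within_candidate":
        for c in perm_survivors:
            call = calls[(c.locus_id, c.direction)]
            table, best_q, ok = pathway_enrichment(
                call.downstream_gene_ids, pathways, background, config.pathway_q
            )
            call.enriched_pathways = table
            call.best_pathway_q = best_q
            call.pathway_pass = ok
    else:  # one BH family across all (candidate, pathway) tests
        flat: list[tuple[CandidateLocus, str, int, float]] = []
        for c in perm_survivors:
            call = calls[(c.locus_id, c.direction)]
            down = call.downstream_gene_ids & background
            for name, members in pathways.items():
                K = len(members & background)
                if K == 0:
                    continue
                k = len(down & members)
                p = _stats.hypergeom_sf(k, len(background), K, len(down))
                flat.append((c, name, k, p))
        if flat:
            qs = _stats.bh_qvalues(np.array([f[3] for f in flat]))
            for (c, name, k, p), q in zip(flat, qs):
                call = calls[(c.locus_id, c.direction)]
                call.enriched_pathways[name] = (k, float(p), float(q))
            for c in perm_survivors:
                call = calls[(c.locus_id, c.direction)]
                if call.enriched_pathways:
                    call.best_pathway_q = min(q for _, _, q in call.enriched_pathways.values())
                    call.pathway_pass = bool(call.best_pathway_q < config.pathway_q)

    driver_loci: list[str] = []
    driver_genes: set[str] = set()
    for c in perm_survivors:
        call = calls[(c.locus_id, c.direction)]
        call.is_driver = call.cis_pass and call.permutation_pass and call.pathway_pass
        if call.is_driver:
            driver_loci.append(c.locus_id)
            driver_genes.add(c.gene_id)

    cascade = {
        "candidates": len(candidates),
        "candidate_genes": len({c.gene_id for c in candidates}),
        "cis_pass": len(cis_survivors),
        "cis_pass_genes": len({c.gene_id for c in cis_survivors}),
        "permutation_pass": len(perm_survivors),
        "permutation_pass_genes": len({c.gene_id for c in perm_survivors}),
        "drivers": len(driver_loci),
        "driver_genes": len(driver_genes),
    }
    logger.info(
        "cascade: %(candidates)d candidates -> %(cis_pass)d cis -> "
        "%(permutation_pass)d permutation -> %(drivers)d drivers",
        cascade,
    )
    return DriverResult(
        calls=[calls[(c.locus_id, c.direction)] for c in candidates],
        driver_loci=sorted(driver_loci),
        driver_genes=sorted(driver_genes),
        cascade=cascade,
    )
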