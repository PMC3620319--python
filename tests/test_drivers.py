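import itertools
import math

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from methdriver._stats import bh_reject_columns, hypergeom_sf, welch_ttest_matrix
from methdriver.config import AnalysisConfig
from methdriver.drivers import (
    CandidateLocus,
    PermutationNullCache,
    cis_statistic,
    downstream_genes,
    empirical_p,
    frequency_filter,
    pathway_enrichment,
    run_cis_stage,
)
from methdriver.drivers import DriverCall


def make_candidate(gene="g0", direction="hyper", altered=None, zero=None):
    return CandidateLocus(
        locus_id="L0",
        gene_id=gene,
        direction=direction,
        altered_samples=tuple(altered or []),
        zero_samples=tuple(zero or []),
    )


def exact_hypergeom_tail(k, N, K, n):
    """Closed-form upper tail from exact integer combinatorics."""
    total = math.comb(N, n)
    return sum(math.comb(K, j) * math.comb(N - K, n - j) for j in range(k, min(K, n) + 1)) / total


class TestFrequencyFilter:
    @pytest.fixture
    def annotation(self):
        return pd.DataFrame(
            {"gene_id": ["gA", "gA", "gB", "gC"], "chromosome": ["1"] * 4},
            index=pd.Index(["L0", "L1", "L2", "L3"], name="locus_id"),
        )

    def _ternary(self, rows, n_tumors=100):
        return pd.DataFrame(
            rows, index=[f"L{i}" for i in range(len(rows))],
            columns=[f"t{j}" for j in range(n_tumors)], dtype=np.int8,
        )

    def test_inclusive_boundary_at_10_percent(self, annotation):
        row_10 = [1] * 10 + [0] * 90
        row_9 = [1] * 9 + [0] * 91
        tern = self._ternary([row_10, row_9, [0] * 100, [0] * 100])
        cands = frequency_filter(tern, annotation, 0.10)
        assert [c.locus_id for c in cands] == ["L0"]
        assert len(cands[0].altered_samples) == 10
        assert len(cands[0].zero_samples) == 90

    def test_both_direction_gene_excluded(self, annotation):
        hyper = [1] * 15 + [0] * 85
        hypo = [-1] * 12 + [0] * 88
        other = [1] * 20 + [0] * 80
        tern = self._ternary([hyper, hypo, other, [0] * 100])
        cands = frequency_filter(tern, annotation, 0.10)
        # gA had a hyper locus and a hypo locus -> both dropped; gB survives
        assert {c.gene_id for c in cands} == {"gB"}

    def test_opposite_state_samples_in_neither_group(self, annotation):
        row = [1] * 15 + [-1] * 5 + [0] * 80
        tern = self._ternary([row, [0] * 100, [0] * 100, [0] * 100])
        (cand,) = frequency_filter(tern, annotation, 0.10)
        assert len(cand.altered_samples) == 15
        assert len(cand.zero_samples) == 80
        assert set(cand.altered_samples).isdisjoint(cand.zero_samples)

    def test_empty_matrix_yields_no_candidates(self, annotation):
        tern = pd.DataFrame(index=pd.Index([], name="locus"), columns=[], dtype=np.int8)
        assert frequency_filter(tern, annotation, 0.10) == []


class TestCisStage:
    def _expr_with_shift(self, shift, seed=0, n=20):
        rng = np.random.default_rng(seed)
        cols = [f"t{j}" for j in range(n)]
        x = rng.normal(10, 0.05, (1, n))
        x[0, : n // 2] += shift
        return pd.DataFrame(x, index=["g0"], columns=cols), cols[: n // 2], cols[n // 2 :]

    def test_concordant_hyper_candidate_passes(self):
        expr, alt, zero = self._expr_with_shift(-2.0)
        cand = make_candidate(direction="hyper", altered=alt, zero=zero)
        calls = {("L0", "hyper"): DriverCall("L0", "g0", "hyper", len(alt), len(zero))}
        survivors = run_cis_stage([cand], expr, calls, AnalysisConfig(n_permutations=1000))
        assert survivors == [cand]
        assert calls[("L0", "hyper")].cis_q < 0.05

    def test_discordant_direction_fails_despite_small_q(self):
        expr, alt, zero = self._expr_with_shift(+2.0)  # hyper but expression UP
        cand = make_candidate(direction="hyper", altered=alt, zero=zero)
        calls = {("L0", "hyper"): DriverCall("L0", "g0", "hyper", len(alt), len(zero))}
        survivors = run_cis_stage([cand], expr, calls, AnalysisConfig(n_permutations=1000))
        assert survivors == []
        call = calls[("L0", "hyper")]
        assert call.cis_q < 0.05 and not call.cis_direction_ok

    def test_small_group_skipped_with_reason(self):
        expr, alt, zero = self._expr_with_shift(-2.0)
        cand = make_candidate(direction="hyper", altered=alt[:2], zero=zero)
        calls = {("L0", "hyper"): DriverCall("L0", "g0", "hyper", 2, len(zero))}
        survivors = run_cis_stage([cand], expr, calls, AnalysisConfig(n_permutations=1000))
        assert survivors == [] and "minimum size" in calls[("L0", "hyper")].skip_reason

    def test_null_pass_fraction_controlled(self):
        """Expression independent of state: <5% of 200 null candidates pass."""
        rng = np.random.default_rng(77)
        n_genes, n_samp = 200, 60
        cols = [f"t{j}" for j in range(n_samp)]
        expr = pd.DataFrame(
            rng.normal(0, 1, (n_genes, n_samp)), index=[f"g{i}" for i in range(n_genes)],
            columns=cols,
        )
        candidates, calls = [], {}
        for i in range(n_genes):
            picks = rng.permutation(cols)
            c = CandidateLocus(
                locus_id=f"L{i}", gene_id=f"g{i}",
                direction="hyper" if rng.random() < 0.5 else "hypo",
                altered_samples=tuple(picks[:18]), zero_samples=tuple(picks[18:]),
            )
            candidates.append(c)
            calls[(c.locus_id, c.direction)] = DriverCall(c.locus_id, c.gene_id, c.direction, 18, 42)
        survivors = run_cis_stage(candidates, expr, calls, AnalysisConfig(n_permutations=1000))
        assert len(survivors) / len(candidates) < 0.05


class TestDownstreamGenes:
    def test_planted_signal_recovered_and_self_excluded(self):
        rng = np.random.default_rng(21)
        n_genes, per_group = 500, 15
        cols = [f"t{j}" for j in range(2 * per_group)]
        expr = pd.DataFrame(
            rng.normal(0, 1, (n_genes, 2 * per_group)),
            index=[f"g{i}" for i in range(n_genes)], columns=cols,
        )
        planted = [f"g{i}" for i in range(40)]
        expr.loc[planted, cols[:per_group]] += 2.0  # 2 pooled-sd shift
        expr.loc["g400", cols[:per_group]] += 5.0  # candidate's own gene, strongly DE
        cand = make_candidate(gene="g400", altered=cols[:per_group], zero=cols[per_group:])
        down = downstream_genes(cand, expr, q_cut=0.05)
        assert "g400" not in down
        recall = len(down & set(planted)) / len(planted)
        assert recall >= 0.9

    def test_fully_null_expression_yields_almost_nothing(self):
        rng = np.random.default_rng(8)
        cols = [f"t{j}" for j in range(30)]
        expr = pd.DataFrame(
            rng.normal(0, 1, (1000, 30)), index=[f"g{i}" for i in range(1000)], columns=cols
        )
        cand = make_candidate(gene="g0", altered=cols[:15], zero=cols[15:])
        assert len(downstream_genes(cand, expr, q_cut=0.05)) == 0


class TestEmpiricalP:
    def test_add_one_hand_computation(self):
        counts = np.array([10, 55, 60] + [0] * 7)  # r = 2 of B = 10 at >= 50
        assert empirical_p(50, counts, "add_one") == pytest.approx(3 / 11)
        assert empirical_p(50, counts, "literal") == pytest.approx(2 / 10)

    def test_observed_zero_gives_p_one(self):
        counts = np.zeros(100, dtype=int)
        assert empirical_p(0, counts, "add_one") == 1.0
        assert empirical_p(0, counts, "literal") == 1.0

    def test_exceeding_means_at_least(self):
        counts = np.array([5, 5, 5, 4])
        assert empirical_p(5, counts, "literal") == pytest.approx(3 / 4)


class TestPermutationCache:
    @pytest.fixture
    def expr(self):
        rng = np.random.default_rng(4)
        cols = [f"t{j}" for j in range(30)]
        return pd.DataFrame(
            rng.normal(0, 1, (300, 30)), index=[f"g{i}" for i in range(300)], columns=cols
        )

    def test_counts_shared_across_candidates_with_same_sizes(self, expr):
        cache = PermutationNullCache(expr, list(expr.columns), B=200, de_q=0.05, base_seed=3)
        c1 = cache.counts_excluding(10, 15, "gene_not_in_matrix_a")
        c2 = cache.counts_excluding(10, 15, "gene_not_in_matrix_b")
        assert np.array_equal(c1, c2)

    def test_seed_reproducibility(self, expr):
        a = PermutationNullCache(expr, list(expr.columns), B=200, de_q=0.05, base_seed=3)
        b = PermutationNullCache(expr, list(expr.columns), B=200, de_q=0.05, base_seed=3)
        assert np.array_equal(a.counts_excluding(10, 15, "g0"), b.counts_excluding(10, 15, "g0"))

    def test_own_gene_exclusion_subtracts_its_de_replicates(self, expr):
        expr2 = expr.copy()
        cache = PermutationNullCache(expr2, list(expr2.columns), B=100, de_q=0.3, base_seed=1)
        base = cache.counts_excluding(12, 12, "no_such_gene")
        excl = cache.counts_excluding(12, 12, "g0")
        assert ((base - excl) >= 0).all() and ((base - excl) <= 1).all()

    def test_oversized_groups_rejected(self, expr):
        cache = PermutationNullCache(expr, list(expr.columns), B=100, de_q=0.05, base_seed=1)
        with pytest.raises(Exception, match="exceed"):
            cache.counts_excluding(20, 20, "g0")


class TestSharedStats:
    def test_hypergeom_matches_full_enumeration(self):
        """P(X >= k) agrees with enumerating all C(20,5) draws exactly."""
        N, K, n = 20, 5, 5
        marked = set(range(K))
        for k in range(n + 1):
            count = sum(
                1 for draw in itertools.combinations(range(N), n)
                if len(marked.intersection(draw)) >= k
            )
            assert hypergeom_sf(k, N, K, n) == pytest.approx(count / math.comb(N, n), rel=1e-12)

    @pytest.mark.parametrize(
        "k, N, K, n",
        [(3, 25, 8, 6), (1, 10, 2, 5), (6, 22, 10, 9), (0, 15, 5, 5)],
    )
    def test_hypergeom_matches_exact_combinatorics(self, k, N, K, n):
        assert hypergeom_sf(k, N, K, n) == pytest.approx(exact_hypergeom_tail(k, N, K, n), rel=1e-12)

    def test_bh_reject_columns_matches_statsmodels(self):
        rng = np.random.default_rng(17)
        P = rng.random((50, 8)) ** 2
        mine = bh_reject_columns(P, 0.1)
        for j in range(8):
            ref = multipletests(P[:, j], alpha=0.1, method="fdr_bh")[0]
            assert np.array_equal(mine[:, j], ref)

    def test_welch_matrix_matches_scipy(self):
        from scipy import stats

        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (20, 16))
        A = np.zeros((16, 3))
        B = np.zeros((16, 3))
        for b in range(3):
            perm = rng.permutation(16)
            A[perm[:6], b] = 1
            B[perm[6:13], b] = 1
        P = welch_ttest_matrix(X, A, B)
        for b in range(3):
            ia = np.flatnonzero(A[:, b])
            ib = np.flatnonzero(B[:, b])
            ref = stats.ttest_ind(X[:, ia], X[:, ib], axis=1, equal_var=False).pvalue
            assert np.allclose(P[:, b], ref, rtol=1e-10)


class TestPathwayEnrichment:
    def test_perfect_overlap_equals_one_over_choose(self):
        background = frozenset(f"g{i}" for i in range(20))
        pathway = frozenset(f"g{i}" for i in range(5))
        down = frozenset(f"g{i}" for i in range(5))
        table, best_q, ok = pathway_enrichment(down, {"p1": pathway}, background, q_cut=1e-4)
        k, p, q = table["p1"]
        assert k == 5
        assert p == pytest.approx(1 / math.comb(20, 5), rel=1e-9)
        assert ok  # 1/15504 ~ 6.45e-5 < 1e-4

    def test_no_overlap_gives_p_one(self):
        background = frozenset(f"g{i}" for i in range(20)) | {"x1", "x2"}
        table, _, ok = pathway_enrichment(
            frozenset({"x1", "x2"}), {"p1": frozenset(f"g{i}" for i in range(5))},
            background, q_cut=1e-4,
        )
        assert table["p1"][1] == 1.0 and not ok

    def test_downstream_equals_background_degenerate(self):
        background = frozenset(f"g{i}" for i in range(30))
        pathways = {
            "p1": frozenset(f"g{i}" for i in range(10)),
            "p2": frozenset(f"g{i}" for i in range(10, 18)),
        }
        table, _, ok = pathway_enrichment(background, pathways, background, q_cut=1e-4)
        assert all(p == 1.0 for _, p, _ in table.values()) and not ok
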