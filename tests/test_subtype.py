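import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methdriver.data_model import ValidationError
from methdriver.simulate import block_ternary
from methdriver.subtype import (
    cluster_subtype_table,
    hierarchical_cluster,
    jaccard_distance,
    pairwise_jaccard,
    subtype_specific_test,
)


class TestJaccardDistance:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ((1, 0, -1, 1), (1, 1, -1, 0), 0.5),  # equal nonzero {1,3} of union {1,2,3,4}
            ((1, 1), (-1, -1), 1.0),  # opposite states never match
            ((0, 0, 0), (0, 0, 0), 0.0),  # two silent profiles are identical
            ((1, 0, -1), (1, 0, -1), 0.0),
        ],
    )
    def test_examples(self, a, b, expected):
        assert jaccard_distance(a, b) == pytest.approx(expected)

    def test_binarized_variant_ignores_direction(self):
        assert jaccard_distance((1, 1), (-1, -1), binarize=True) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            jaccard_distance((1, 0), (1, 0, 1))

    @given(
        st.lists(st.sampled_from([-1, 0, 1]), min_size=1, max_size=20),
        st.lists(st.sampled_from([-1, 0, 1]), min_size=1, max_size=20),
    )
    @settings(max_examples=150, derandomize=True)
    def test_metric_like_properties(self, a, b):
        n = min(len(a), len(b))
        a, b = a[:n], b[:n]
        d = jaccard_distance(a, b)
        assert 0.0 <= d <= 1.0
        assert d == jaccard_distance(b, a)
        assert jaccard_distance(a, a) == 0.0

    def test_pairwise_matches_scalar(self):
        rng = np.random.default_rng(5)
        T = pd.DataFrame(
            rng.choice([-1, 0, 1], size=(40, 8), p=[0.2, 0.6, 0.2]),
            columns=[f"t{j}" for j in range(8)],
        )
        D = pairwise_jaccard(T)
        for i in range(8):
            for j in range(8):
                assert D[i, j] == pytest.approx(
                    jaccard_distance(T.iloc[:, i], T.iloc[:, j]), abs=1e-12
                )


class TestHierarchicalCluster:
    def test_planted_blocks_recovered_exactly(self):
        tern, truth = block_ternary(seed=0)
        res = hierarchical_cluster(tern, k=3)
        # exact recovery up to relabeling: each true block maps to one cluster
        mapping = {}
        for t in res.labels.index:
            mapping.setdefault(truth.loc[t], set()).add(res.labels.loc[t])
        assert all(len(v) == 1 for v in mapping.values())
        assert len(set.union(*mapping.values())) == 3

    def test_k_equals_n_gives_singletons(self):
        tern, _ = block_ternary(n_blocks=2, loci_per_block=5, tumors_per_block=3, seed=1)
        res = hierarchical_cluster(tern, k=tern.shape[1])
        assert res.labels.nunique() == tern.shape[1]

    def test_duplicate_columns_co_cluster(self):
        tern, _ = block_ternary(n_blocks=2, loci_per_block=10, tumors_per_block=4, seed=2)
        tern["T900"] = tern["T000"]
        res = hierarchical_cluster(tern, k=4)
        assert res.labels.loc["T900"] == res.labels.loc["T000"]

    def test_invariant_to_column_order(self):
        tern, _ = block_ternary(seed=3)
        shuffled = tern[list(np.random.default_rng(0).permutation(tern.columns))]
        r1 = hierarchical_cluster(tern, k=3)
        r2 = hierarchical_cluster(shuffled, k=3)
        pd.testing.assert_series_equal(r1.labels, r2.labels)
        assert r1.newick == r2.newick

    def test_merge_heights_non_decreasing(self):
        tern, _ = block_ternary(seed=4)
        res = hierarchical_cluster(tern, k=3)
        heights = res.linkage_matrix[:, 2]
        assert (np.diff(heights) >= -1e-12).all()

    def test_k_larger_than_n_rejected(self):
        tern, _ = block_ternary(n_blocks=2, loci_per_block=5, tumors_per_block=2, seed=0)
        with pytest.raises(ValidationError):
            hierarchical_cluster(tern, k=10)

    def test_newick_leaf_set(self):
        tern, _ = block_ternary(n_blocks=2, loci_per_block=5, tumors_per_block=3, seed=0)
        res = hierarchical_cluster(tern, k=2)
        for t in tern.columns:
            assert t in res.newick
        assert res.newick.endswith(";")


class TestSubtypeSpecificTest:
    def _setup(self, k_in, n_in, k_total, n_total):
        tumors = [f"t{j}" for j in range(n_total)]
        states = np.zeros(n_total, dtype=np.int8)
        states[:k_in] = -1  # altered inside the subtype
        states[n_in : n_in + (k_total - k_in)] = -1  # altered outside
        tern = pd.DataFrame([states], index=["L0"], columns=tumors)
        subtypes = pd.Series(
            ["basal"] * n_in + ["other"] * (n_total - n_in), index=tumors
        )
        ann = pd.DataFrame(
            {"gene_id": ["geneA"], "chromosome": ["1"]},
            index=pd.Index(["L0"], name="locus_id"),
        )
        return tern, subtypes, ann

    def test_exact_tail_for_inferred_counts(self):
        """22-tumor subtype with 14 of 31 altered among 88 tumors overall.

        The exact combinatorial tail is 1.747e-3 (oracle below); the
        commonly quoted rounded figure for this configuration, 1.70e-3,
        agrees with it to within 3%.
        """
        import math

        tern, subtypes, ann = self._setup(k_in=14, n_in=22, k_total=31, n_total=88)
        calls = subtype_specific_test(tern, {"L0": "hypo"}, subtypes, ann)
        basal = next(c for c in calls if c.subtype == "basal")
        assert basal.freq_subtype == pytest.approx(14 / 22)
        assert basal.freq_rest == pytest.approx(17 / 66)
        exact = sum(
            math.comb(31, j) * math.comb(57, 22 - j) for j in range(14, 23)
        ) / math.comb(88, 22)
        assert basal.p == pytest.approx(exact, rel=1e-9)
        assert basal.p == pytest.approx(1.70e-3, rel=0.05)
        assert basal.specific

    def test_identical_frequency_never_specific(self):
        # k/n = K/N exactly: 5/20 inside, 20/80 overall
        tern, subtypes, ann = self._setup(k_in=5, n_in=20, k_total=20, n_total=80)
        calls = subtype_specific_test(tern, {"L0": "hypo"}, subtypes, ann)
        basal = next(c for c in calls if c.subtype == "basal")
        assert basal.p >= 0.5 and not basal.specific

    def test_fully_concentrated_alteration_is_specific(self):
        tern, subtypes, ann = self._setup(k_in=15, n_in=20, k_total=15, n_total=80)
        calls = subtype_specific_test(tern, {"L0": "hypo"}, subtypes, ann)
        basal = next(c for c in calls if c.subtype == "basal")
        assert basal.q < 1e-6 and basal.specific

    def test_unlabeled_tumors_excluded(self):
        tern, subtypes, ann = self._setup(k_in=10, n_in=20, k_total=15, n_total=80)
        subtypes.iloc[-5:] = pd.NA
        calls = subtype_specific_test(tern, {"L0": "hypo"}, subtypes, ann)
        assert all(c.n_total == 75 for c in calls)


def test_cluster_subtype_table_counts():
    labels = pd.Series([1, 1, 2], index=["a", "b", "c"])
    subs = pd.Series(["x", "y", "y"], index=["a", "b", "c"])
    tab = cluster_subtype_table(labels, subs)
    assert tab.loc[1, "x"] == 1 and tab.loc[1, "y"] == 1 and tab.loc[2, "y"] == 1
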