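import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_matrix
from oracles import bh_reference, naive_ssgsea
from tmmscope import (
    ExpressionMatrix,
    NullDistribution,
    bh_adjust,
    classify,
    cluster_samples,
    empirical_p,
    enrichment_matrix,
    generate_cohort,
    linkage_to_newick,
    permutation_null,
)
from tmmscope.enrichment import EnrichmentScoreMatrix


class TestPermutationNull:
    def test_same_seed_reproduces_exactly(self):
        rng = np.random.default_rng(0)
        m = random_matrix(rng, 40, 5)
        a = permutation_null(m, set_size=5, n_perm=120, seed=9)
        b = permutation_null(m, set_size=5, n_perm=120, seed=9)
        assert np.array_equal(a.scores, b.scores)
        assert not np.array_equal(
            a.scores, permutation_null(m, set_size=5, n_perm=120, seed=10).scores
        )

    def test_singleton_null_support_is_the_singleton_scores(self):
        df = pd.DataFrame({"s": [3.0, 1.0, 2.0]}, index=list("abc"))
        m = ExpressionMatrix(df)
        possible = {round(naive_ssgsea(df["s"], [g], 0.25), 12) for g in "abc"}
        null = permutation_null(m, set_size=1, n_perm=150, seed=1)
        observed = {round(v, 12) for v in null.scores[:, 0]}
        assert observed == possible

    def test_flat_column_gives_flat_null(self):
        df = pd.DataFrame({"flat": [2.0] * 6, "var": [1, 2, 3, 4, 5, 6.0]},
                          index=list("abcdef"))
        null = permutation_null(ExpressionMatrix(df), set_size=2, n_perm=100, seed=3)
        flat_scores = null.scores[:, 0]
        assert np.allclose(flat_scores, flat_scores[0])

    def test_set_size_out_of_range(self):
        m = random_matrix(np.random.default_rng(1), 10, 2)
        with pytest.raises(ValueError, match="set_size"):
            permutation_null(m, set_size=10, n_perm=100, seed=0)


class TestEmpiricalP:
    def test_extreme_observed_add_one_rule(self):
        null = np.arange(99, dtype=float)
        p, status = empirical_p(1000.0, null, side="upper")
        assert p == pytest.approx(1 / 100)
        assert status == "upregulated"

    def test_median_tie_counts_as_upregulated(self):
        null = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        _, status = empirical_p(3.0, null)
        assert status == "upregulated"

    def test_hand_counted_tail(self):
        null = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        p, status = empirical_p(4.5, null, side="upper")
        assert p == pytest.approx(2 / 6)  # one null value >= 4.5, add-one
        assert status == "upregulated"
        p_low, status_low = empirical_p(1.5, null, side="lower")
        assert p_low == pytest.approx(2 / 6)
        assert status_low == "downregulated"


class TestBH:
    @given(st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=1, max_size=6))
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_matches_bruteforce_reference(self, pvals):
        assert bh_adjust(np.array(pvals)) == pytest.approx(bh_reference(pvals))

    def test_monotone_in_sorted_p_and_bounded(self):
        p = np.array([0.9, 0.001, 0.04, 0.3, 0.04, 1.0])
        q = bh_adjust(p)
        assert (q <= 1).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


def _scores_from_row(values, samples, set_name="ALT_CHR") -> EnrichmentScoreMatrix:
    raw = pd.DataFrame([values], index=[set_name], columns=samples)
    return EnrichmentScoreMatrix(raw=raw, normalized=raw.copy(),
                                 weight_exponent=0.25, normalization="none")


def _null_from_scores(scores, samples, set_name="ALT_CHR", seed=0) -> NullDistribution:
    scores = np.asarray(scores, dtype=float)
    return NullDistribution(set_name=set_name, set_size=2, n_perm=scores.shape[0],
                            seed=seed, samples=list(samples), scores=scores)


class TestClassify:
    def test_q_exactly_at_threshold_is_non_alt(self):
        # single sample: 49 of 99 null scores >= observed -> p = q = 0.5
        null_scores = np.linspace(0, 98, 99).reshape(-1, 1)
        scores = _scores_from_row([49.5], ["s0"])
        calls = classify(scores, {"ALT_CHR": _null_from_scores(null_scores, ["s0"])},
                         fdr_threshold=0.5)
        assert calls.loc[0, "q"] == pytest.approx(0.5)
        assert calls.loc[0, "status"] == "upregulated"
        assert calls.loc[0, "label"] == "non_ALT"

    def test_missing_alt_chr_raises(self):
        scores = _scores_from_row([1.0], ["s0"], set_name="Tel_TERT")
        with pytest.raises(ValueError, match="ALT_CHR"):
            classify(scores, {})

    def test_label_invariant_to_sample_order(self):
        cohort = generate_cohort(n_samples=40, n_genes=300, seed=5)
        m = cohort.expression
        scores = enrichment_matrix(m, cohort.gene_sets)
        null = permutation_null(m, set_size=15, n_perm=200, seed=1, set_name="ALT_CHR")
        calls = classify(scores, {"ALT_CHR": null}).set_index("sample_id")

        perm = list(reversed(m.samples))
        m2 = m.subset_samples(perm)
        scores2 = enrichment_matrix(m2, cohort.gene_sets)
        null2 = permutation_null(m2, set_size=15, n_perm=200, seed=1, set_name="ALT_CHR")
        calls2 = classify(scores2, {"ALT_CHR": null2}).set_index("sample_id")
        assert calls2.loc[m.samples, "label"].tolist() == calls["label"].tolist()

    def test_planted_signal_recovered(self):
        cohort = generate_cohort(n_samples=60, n_genes=400, chr_effect_sd=3.0, seed=2)
        scores = enrichment_matrix(cohort.expression, cohort.gene_sets)
        null = permutation_null(cohort.expression, set_size=15, n_perm=300, seed=3,
                                set_name="ALT_CHR")
        calls = classify(scores, {"ALT_CHR": null})
        truth = cohort.truth["is_alt"].astype(bool).to_numpy()
        called = calls["label"].eq("ALT_like").to_numpy()
        assert (called == truth).mean() >= 0.95

    def test_tel_axis_follows_planted_telomerase_shift(self):
        cohort = generate_cohort(n_samples=50, n_genes=400, chr_effect_sd=3.0,
                                 tel_effect_sd=3.0, seed=8)
        m = cohort.expression
        scores = enrichment_matrix(m, cohort.gene_sets)
        from tmmscope import SsgseaEngine

        engine = SsgseaEngine(m)
        nulls = {}
        for name, k in (("ALT_CHR", 15), ("Tel_TERT", 19), ("Tel_TERC_DKC1", 19)):
            nulls[name] = permutation_null(m, set_size=k, n_perm=200, seed=4,
                                           set_name=name, engine=engine)
        calls = classify(scores, nulls)
        truth = cohort.truth["is_alt"].astype(bool).to_numpy()
        tel_high = calls["tel_axis"].eq("TEL_high").to_numpy()
        # telomerase axis should be high predominantly in latent non-ALT samples
        assert (tel_high == ~truth).mean() >= 0.9


class TestClusterSamples:
    @staticmethod
    def _matrix_with_log_profiles(profiles: dict) -> ExpressionMatrix:
        # build expression whose log10(x+1) equals the designed profiles exactly
        df = pd.DataFrame(profiles, index=[f"g{i}" for i in range(3)], dtype=float)
        return ExpressionMatrix(10.0 ** df - 1.0)

    def test_identical_samples_merge_first_at_zero(self):
        m = self._matrix_with_log_profiles(
            {"a": [1, 2, 3], "b": [1, 2, 3], "c": [3, 2, 1]}
        )
        linkage, _ = cluster_samples(m)
        assert linkage[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert {int(linkage[0, 0]), int(linkage[0, 1])} == {0, 1}

    def test_anticorrelated_samples_at_distance_two(self):
        m = self._matrix_with_log_profiles({"a": [1, 2, 3], "c": [3, 2, 1]})
        linkage, _ = cluster_samples(m)
        assert linkage[0, 2] == pytest.approx(2.0)

    def test_manual_average_linkage_trace(self):
        # pairwise 1-r distances: d(a,b)=0, d(a,d)=d(b,d)=0.5, d(a,c)=d(b,c)=2, d(c,d)=1.5
        m = self._matrix_with_log_profiles(
            {"a": [1, 2, 3], "b": [2, 4, 6], "c": [3, 2, 1], "d": [1, 3, 2]}
        )
        linkage, leaves = cluster_samples(m)
        heights = linkage[:, 2]
        assert heights == pytest.approx([0.0, 0.5, 11 / 6], abs=1e-9)
        # first merge a-b, then the (ab) cluster with d, then c joins last
        assert {int(linkage[0, 0]), int(linkage[0, 1])} == {0, 1}
        assert leaves.index("c") in (0, 3)

    def test_single_sample_rejected(self):
        m = self._matrix_with_log_profiles({"a": [1, 2, 3]})
        with pytest.raises(ValueError, match="2 samples"):
            cluster_samples(m)

    def test_newick_export_contains_all_leaves(self):
        m = self._matrix_with_log_profiles(
            {"a": [1, 2, 3], "b": [2, 4, 6], "c": [3, 2, 1], "d": [1, 3, 2]}
        )
        linkage, _ = cluster_samples(m)
        newick = linkage_to_newick(linkage, m.samples)
        assert newick.endswith(";")
        for s in m.samples:
            assert s in newick
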