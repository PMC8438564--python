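import numpy as np
import pandas as pd
import pytest
import scipy.stats as ss

from conftest import random_matrix
from oracles import mannwhitney_exact_p, welch_t
from tmmscope import (
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    correlate_with_anchor,
    correlation_heatmap_table,
    differential_expression,
    enrichment_matrix,
)
from tmmscope.stats import compare_scores, format_p


def _matrix(values: dict, genes=None) -> ExpressionMatrix:
    df = pd.DataFrame(values)
    df.index = genes or [f"g{i}" for i in range(len(df))]
    return ExpressionMatrix(df)


class TestDifferentialExpression:
    def test_identical_groups_give_unit_p(self):
        vals = np.tile([1.0, 5.0, 3.0, 2.0], (3, 1))
        m = ExpressionMatrix(pd.DataFrame(
            np.hstack([vals, vals]), index=list("abc"),
            columns=[f"s{i}" for i in range(8)],
        ))
        res = differential_expression(m, [True] * 4 + [False] * 4)
        assert res["stat"].to_numpy() == pytest.approx(0.0)
        assert res["p"].to_numpy() == pytest.approx(1.0)

    def test_label_swap_negates_stat_keeps_p(self):
        rng = np.random.default_rng(0)
        m = random_matrix(rng, 10, 8)
        labels = np.array([True] * 4 + [False] * 4)
        a = differential_expression(m, labels)
        b = differential_expression(m, ~labels)
        assert b["stat"].to_numpy() == pytest.approx(-a["stat"].to_numpy())
        assert b["p"].to_numpy() == pytest.approx(a["p"].to_numpy())

    def test_welch_matches_closed_form(self):
        x = [4.1, 5.2, 6.3, 5.5, 4.9]
        y = [3.0, 2.8, 3.5, 3.1, 2.9]
        m = _matrix({f"s{i}": [v] for i, v in enumerate(x + y)}, genes=["g"])
        res = differential_expression(m, [True] * 5 + [False] * 5)
        t_ref, df_ref = welch_t(x, y)
        p_ref = 2 * ss.t.sf(abs(t_ref), df_ref)
        assert res.loc[0, "stat"] == pytest.approx(t_ref)
        assert res.loc[0, "p"] == pytest.approx(p_ref)
        assert res.loc[0, "direction"] == "up_in_A"

    def test_small_group_rejected_and_constants_skipped(self):
        m = _matrix({"s0": [1, 2.0], "s1": [2, 2.0], "s2": [3, 2.0], "s3": [4, 2.0]})
        with pytest.raises(ValueError, match=">= 2 samples"):
            differential_expression(m, [True, False, False, False])
        res = differential_expression(m, [True, True, False, False])
        assert res["feature"].tolist() == ["g0"]  # constant g1 skipped


class TestCompareScores:
    @staticmethod
    def _scores(values_by_set, samples):
        m = random_matrix(np.random.default_rng(1), 20, len(samples))
        scores = enrichment_matrix(
            m, GeneSetCollection([GeneSet(name="dummy", genes=tuple(m.genes[:3]))])
        )
        raw = pd.DataFrame(values_by_set, index=samples).T
        scores.raw = raw
        scores.normalized = raw.copy()
        return scores

    def test_dominant_group_flagged_with_direction(self):
        samples = [f"s{i}" for i in range(12)]
        vals = {"S": np.r_[np.arange(6) + 10.0, np.arange(6)]}
        scores = self._scores(vals, samples)
        res = compare_scores(scores, [True] * 6 + [False] * 6)
        assert res.loc[0, "direction"] == "up_in_A"
        assert res.loc[0, "p"] < 0.01

    def test_exact_p_matches_enumeration(self):
        samples = [f"s{i}" for i in range(6)]
        x, y = [1.3, 0.2, 2.1], [0.9, 1.8, 0.1]
        scores = self._scores({"S": x + y}, samples)
        res = compare_scores(scores, [True] * 3 + [False] * 3)
        assert res.loc[0, "p"] == pytest.approx(mannwhitney_exact_p(x, y))

    def test_type_one_error_near_nominal(self):
        rng = np.random.default_rng(42)
        reps, n = 1000, 25
        x = rng.normal(size=(reps, n))
        y = rng.normal(size=(reps, n))
        rate_w = (ss.mannwhitneyu(x, y, axis=1, alternative="two-sided").pvalue < 0.05).mean()
        rate_t = (ss.ttest_ind(x, y, axis=1, equal_var=False).pvalue < 0.05).mean()
        assert 0.03 <= rate_w <= 0.07
        assert 0.03 <= rate_t <= 0.07


class TestCorrelations:
    def test_self_and_negated_panel(self):
        rng = np.random.default_rng(2)
        base = rng.lognormal(1, 0.5, 50)
        m = _matrix(
            {f"s{i}": [base[i], base[i], base.max() - base[i]] for i in range(50)},
            genes=["anchor", "same", "flipped"],
        )
        res = correlate_with_anchor(m, "anchor", ["same", "flipped"]).set_index("gene_b")
        assert res.loc["same", "r"] == pytest.approx(1.0)
        assert res.loc["flipped", "r"] == pytest.approx(-1.0)

    def test_absent_anchor_raises_absent_panel_warns(self, caplog):
        m = _matrix({"s0": [1, 2.0], "s1": [2, 1.0], "s2": [3, 4.0]})
        with pytest.raises(ValueError, match="anchor"):
            correlate_with_anchor(m, "nope", ["g1"])
        with caplog.at_level("WARNING"):
            res = correlate_with_anchor(m, "g0", ["g1", "ghost"])
        assert res["gene_b"].tolist() == ["g1"]
        assert "ghost" in caplog.text

    def test_heatmap_single_gene_unit_cell(self):
        m = _matrix({"s0": [1.0], "s1": [2.0], "s2": [3.0]}, genes=["g"])
        res = correlation_heatmap_table(m, ["g"], ["g"])
        assert len(res) == 1
        assert res.loc[0, "r"] == pytest.approx(1.0)

    def test_neg_log10_of_q_005_is_about_1p3(self):
        # -log10(0.05) = 1.301, the conventional significance line
        assert -np.log10(0.05) == pytest.approx(1.301, abs=1e-3)
        rng = np.random.default_rng(3)
        m = random_matrix(rng, 6, 40)
        res = correlation_heatmap_table(m, m.genes[:3], m.genes[3:])
        assert res["neg_log10_q"].to_numpy() == pytest.approx(
            -np.log10(res["q"].to_numpy())
        )

    def test_grid_matches_pairwise_oracle(self):
        rng = np.random.default_rng(4)
        m = random_matrix(rng, 6, 30)
        res = correlation_heatmap_table(m, m.genes[:3], m.genes[3:])
        n = len(m.samples)
        for _, row in res.iterrows():
            x = m.df.loc[row["gene_a"]].to_numpy()
            y = m.df.loc[row["gene_b"]].to_numpy()
            xc, yc = x - x.mean(), y - y.mean()
            r_ref = (xc * yc).sum() / np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
            t_ref = r_ref * np.sqrt((n - 2) / (1 - r_ref ** 2))
            p_ref = 2 * ss.t.sf(abs(t_ref), n - 2)
            assert row["r"] == pytest.approx(r_ref)
            assert row["p"] == pytest.approx(p_ref, rel=1e-6)

    def test_affine_invariance_of_r(self):
        rng = np.random.default_rng(5)
        m = random_matrix(rng, 4, 25)
        res1 = correlation_heatmap_table(m, m.genes[:2], m.genes[2:])
        m2 = ExpressionMatrix(m.df * 3.7 + 11.0)
        res2 = correlation_heatmap_table(m2, m.genes[:2], m.genes[2:])
        assert res2["r"].to_numpy() == pytest.approx(res1["r"].to_numpy())


def test_p_floor_formatting():
    assert format_p(1e-300) == "< 2.22e-16"
    assert format_p(0.0123) == "0.0123"
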