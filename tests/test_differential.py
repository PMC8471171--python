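import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from _oracles import bh_stepup, pooled_t
from conftest import make_beta
from mepact import differential as dm
from mepact.differential import (BetaMatrix, ExpressionMatrix, GeneAnnotation,
                                 bh_adjust, diff_expression, diff_methylation,
                                 moderated_t_test, promoter_mean_beta,
                                 promoter_windows)
from mepact.simulate import SimConfig, gen_methylome_transcriptome


class TestPromoterWindows:
    def test_strand_orientation(self, small_annotation):
        w = promoter_windows(small_annotation)
        assert (w.loc["gA", "start"], w.loc["gA", "end"]) == (8_500, 10_500)
        assert (w.loc["gB", "start"], w.loc["gB", "end"]) == (49_500, 51_500)
        assert ((w["end"] - w["start"]) == 2000).all()


class TestPromoterMeanBeta:
    def groups(self):
        return pd.Series(["control", "control", "case", "case"],
                         index=["s1", "s2", "s3", "s4"])

    def test_arithmetic_mean_of_in_window_probes(self, small_annotation):
        beta = make_beta(
            {"p1": 9_000, "p2": 9_500, "p3": 10_000},
            np.array([[0.2] * 4, [0.4] * 4, [0.6] * 4]), self.groups())
        means, dropped = promoter_mean_beta(beta, small_annotation)
        assert np.allclose(means.loc["gA"], 0.4)
        assert dropped == ["gB"]

    def test_constant_probes_give_that_constant(self, small_annotation):
        beta = make_beta({"p1": 9_000}, np.full((1, 4), 0.5), self.groups())
        means, _ = promoter_mean_beta(beta, small_annotation)
        assert np.allclose(means.loc["gA"], 0.5)

    def test_half_open_window_boundary(self, small_annotation):
        """Probe exactly at tss+500 on the plus strand is excluded; one base
        earlier is included — matches brute-force membership."""
        for pos, included in [(10_500, False), (10_499, True), (8_500, True),
                              (8_499, False)]:
            beta = make_beta({"p1": pos, "anchor": 9_000},
                             np.array([[0.9] * 4, [0.1] * 4]), self.groups())
            means, _ = promoter_mean_beta(beta, small_annotation)
            brute = 8_500 <= pos < 10_500
            assert included == brute
            expected = (0.9 + 0.1) / 2 if included else 0.1
            assert np.allclose(means.loc["gA"], expected)

    def test_output_bounded_by_probe_extremes(self, small_annotation):
        rng = np.random.default_rng(5)
        vals = rng.uniform(0, 1, size=(4, 4))
        beta = make_beta({f"p{i}": 9_000 + 100 * i for i in range(4)},
                         vals, self.groups())
        means, _ = promoter_mean_beta(beta, small_annotation)
        assert (means.loc["gA"] >= vals.min(axis=0)).all()
        assert (means.loc["gA"] <= vals.max(axis=0)).all()

    def test_no_probe_anywhere_errors(self, small_annotation):
        beta = make_beta({"p1": 999_999}, np.full((1, 4), 0.5), self.groups())
        with pytest.raises(ValueError):
            promoter_mean_beta(beta, small_annotation)


class TestModeratedT:
    def test_identical_groups_give_zero_effect_p_one(self):
        vals = pd.DataFrame(np.tile([[1.0, 2.0, 3.0]], (4, 2)),
                            index=list("abcd"),
                            columns=["c1", "c2", "c3", "t1", "t2", "t3"])
        groups = pd.Series(["control"] * 3 + ["case"] * 3, index=vals.columns)
        res = moderated_t_test(vals, groups)
        assert np.allclose(res["effect"], 0)
        assert np.allclose(res["p"], 1)

    def test_prior_df_zero_recovers_ordinary_pooled_t(self):
        rng = np.random.default_rng(11)
        vals = pd.DataFrame(rng.normal(size=(6, 6)),
                            columns=["c1", "c2", "c3", "t1", "t2", "t3"])
        groups = pd.Series(["control"] * 3 + ["case"] * 3, index=vals.columns)
        res = moderated_t_test(vals, groups, prior_df=0)
        for i in range(6):
            x = vals.iloc[i, 3:].to_numpy()
            y = vals.iloc[i, :3].to_numpy()
            assert res["t_mod"].iloc[i] == pytest.approx(pooled_t(x, y))
            t_sp, p_sp = stats.ttest_ind(x, y, equal_var=True)
            assert res["p"].iloc[i] == pytest.approx(p_sp)

    def test_posterior_variance_between_sample_and_prior_variance(self):
        """s2_post is a convex combination of the per-feature variance and
        the fitted prior variance, so it always lies between the two."""
        rng = np.random.default_rng(3)
        scales = rng.uniform(0.5, 3, size=(40, 1))
        vals = pd.DataFrame(rng.normal(size=(40, 10)) * scales)
        vals.columns = [f"c{i}" for i in range(5)] + [f"t{i}" for i in range(5)]
        groups = pd.Series(["control"] * 5 + ["case"] * 5, index=vals.columns)
        res = moderated_t_test(vals, groups)
        case = vals.iloc[:, 5:].to_numpy()
        ctrl = vals.iloc[:, :5].to_numpy()
        s2 = (case.var(axis=1, ddof=1) * 4 + ctrl.var(axis=1, ddof=1) * 4) / 8
        d0, s02 = dm._fit_variance_prior(s2, 8)
        assert d0 > 0
        s2_post = (res["effect"] / res["t_mod"]) ** 2 / (1 / 5 + 1 / 5)
        lo = np.minimum(s2, s02)
        hi = np.maximum(s2, s02)
        assert ((s2_post >= lo - 1e-9) & (s2_post <= hi + 1e-9)).all()

    def test_large_prior_df_approaches_z_test(self):
        rng = np.random.default_rng(4)
        vals = pd.DataFrame(rng.normal(size=(30, 8)))
        vals.columns = [f"c{i}" for i in range(4)] + [f"t{i}" for i in range(4)]
        groups = pd.Series(["control"] * 4 + ["case"] * 4, index=vals.columns)
        res = moderated_t_test(vals, groups, prior_df=np.inf)
        # one shared denominator for all features => t proportional to effect
        ratio = res["t_mod"] / res["effect"]
        assert np.allclose(ratio, ratio.iloc[0])

    def test_null_type_i_error_near_nominal(self):
        rng = np.random.default_rng(123)
        vals = pd.DataFrame(rng.normal(size=(500, 12)))
        vals.columns = [f"c{i}" for i in range(6)] + [f"t{i}" for i in range(6)]
        groups = pd.Series(["control"] * 6 + ["case"] * 6, index=vals.columns)
        res = moderated_t_test(vals, groups)
        rate = (res["p"] <= 0.05).mean()
        # 3 binomial SDs around 0.05 at n=500
        assert abs(rate - 0.05) <= 3 * np.sqrt(0.05 * 0.95 / 500)

    def test_all_zero_variance_falls_back_with_warning(self):
        vals = pd.DataFrame(np.ones((3, 6)),
                            columns=["c1", "c2", "c3", "t1", "t2", "t3"])
        groups = pd.Series(["control"] * 3 + ["case"] * 3, index=vals.columns)
        with pytest.warns(UserWarning, match="zero variance"):
            res = moderated_t_test(vals, groups)
        assert np.allclose(res["p"], 1.0)

    def test_requires_two_samples_per_group(self):
        vals = pd.DataFrame(np.ones((3, 3)), columns=["c1", "t1", "t2"])
        groups = pd.Series(["control", "case", "case"], index=vals.columns)
        with pytest.raises(ValueError):
            moderated_t_test(vals, groups)


class TestBHAdjust:
    def test_worked_examples(self):
        assert bh_adjust([0.05]) == pytest.approx([0.05])
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=50))
    def test_matches_bruteforce_stepup_and_dominates_input(self, pvals):
        adj = bh_adjust(pvals)
        assert np.allclose(adj, bh_stepup(pvals))
        assert (np.asarray(adj) >= np.asarray(pvals) - 1e-12).all()


class TestDifferentialCalls:
    def test_methylation_effect_below_point_one_never_significant(self):
        """A delta-beta of ~0.09 stays non-significant no matter how small
        the p-value (the effect-size threshold is 0.1)."""
        rng = np.random.default_rng(0)
        n = 50
        samples = [f"c{i}" for i in range(n)] + [f"t{i}" for i in range(n)]
        groups = pd.Series(["control"] * n + ["case"] * n, index=samples)
        base = np.full((20, 2 * n), 0.40)
        base[:, n:] += 0.09
        vals = np.clip(base + rng.normal(0, 0.002, size=base.shape), 0, 1)
        annot = GeneAnnotation(pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(20)], "chrom": "chr1",
            "strand": "+", "tss": 10_000 + 5_000 * np.arange(20)}))
        probes = pd.DataFrame({"chrom": "chr1",
                               "pos": 10_000 + 5_000 * np.arange(20)},
                              index=pd.Index([f"p{i}" for i in range(20)],
                                             name="probe_id"))
        beta = BetaMatrix(values=pd.DataFrame(vals, index=probes.index,
                                              columns=samples),
                          probes=probes, groups=groups)
        table, _ = diff_methylation(beta, annot)
        assert (table["p_adj"] < 1e-6).all()
        assert not table["significant"].any()

    def test_expression_lfc_below_half_never_significant(self):
        rng = np.random.default_rng(1)
        n = 30
        samples = [f"c{i}" for i in range(n)] + [f"t{i}" for i in range(n)]
        groups = pd.Series(["control"] * n + ["case"] * n, index=samples)
        vals = rng.normal(0, 0.05, size=(10, 2 * n)) + 5.0
        vals[:, n:] += 0.4
        expr = ExpressionMatrix(
            values=pd.DataFrame(vals, columns=samples), groups=groups)
        table = diff_expression(expr)
        assert (table["p_adj"] < 1e-6).all()
        assert not table["significant"].any()

    def test_planted_signals_recovered(self):
        cfg = SimConfig(seed=7)
        beta, expr, annot, truth = gen_methylome_transcriptome(cfg)
        meth, _ = diff_methylation(beta, annot)
        expr_table = diff_expression(expr)
        hyper = truth.index[truth["planted_delta_beta"] > 0]
        up = truth.index[truth["planted_log2fc"] > 0]
        assert meth.loc[hyper, "significant"].mean() >= 0.9
        assert expr_table.loc[up, "significant"].mean() >= 0.9

    def test_identical_groups_yield_no_calls(self, toy_expression):
        vals = toy_expression.values
        mirrored = pd.concat([vals.iloc[:, :3], vals.iloc[:, :3]], axis=1)
        mirrored.columns = vals.columns
        table = diff_expression(
            ExpressionMatrix(values=mirrored, groups=toy_expression.groups))
        assert not table["significant"].any()

    def test_constant_gene_gets_p_one(self, toy_expression):
        table = diff_expression(toy_expression)
        assert table.loc["constant", "p"] == pytest.approx(1.0)
        assert not table.loc["constant", "significant"]

    def test_significance_reproducible_from_effect_and_padj(self, toy_expression):
        table = diff_expression(toy_expression)
        rebuilt = (table["p_adj"] <= 0.01) & (table["effect"].abs() >= 0.5)
        assert (rebuilt == table["significant"]).all()
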