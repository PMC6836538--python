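import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from dese import selexp
from dese.selexp import (
    DEFAULT_LAMBDA,
    collapse_to_gene,
    conventional_z,
    declare_selective_genes,
    fit_huber_line,
    mad_z,
    rez_scores,
    rvp,
)

from conftest import make_summary


# ---------------------------------------------------------------------------
# Independent IRLS oracle: straightforward loop, statsmodels WLS for the fit
# ---------------------------------------------------------------------------

def oracle_rez(y, s, lam=DEFAULT_LAMBDA, tol=1e-6, max_iter=100):
    """Brute-force robust z-scores written independently of the package.

    Sort means ascending; iterate: WLS fit of sorted means on ranks with the
    current weights, residuals e, standardized residuals u = e/s, cutoff
    k = 1.345 * SD of w*e, weights 1/s where |u| <= k else k/|e|; stop on
    weight stability or k = 0. Then normalized weights give the robust
    mean/SD and z = (y - mu) / (sd * lam).
    """
    import statsmodels.api as sm

    y = np.asarray(y, float)
    s = np.asarray(s, float)
    order = np.argsort(y, kind="stable")
    ys, ss = y[order], s[order]
    N = len(y)
    X = sm.add_constant(np.arange(1, N + 1, dtype=float))
    w = 1.0 / ss
    for _ in range(max_iter):
        fit = sm.WLS(ys, X, weights=w).fit()
        e = ys - fit.fittedvalues
        k = 1.345 * np.std(w * e)
        if k == 0:
            break
        u = e / ss
        with np.errstate(divide="ignore"):
            new_w = np.where(np.abs(u) <= k, 1.0 / ss, k / np.abs(e))
        if np.abs(new_w - w).max() / w.max() < tol:
            w = new_w
            break
        w = new_w
    w_orig = np.empty(N)
    w_orig[order] = w
    wn = w_orig / w_orig.sum()
    mu = float(wn @ y)
    var = float(wn @ (y - mu) ** 2) / (1.0 - float(wn @ wn))
    z = (y - mu) / (math.sqrt(var) * lam)
    return z, mu, math.sqrt(var)


class TestFitHuberLine:
    def test_perfect_linear(self):
        f = fit_huber_line(np.arange(1.0, 6.0), np.full(5, 2.0))
        assert f.beta1 == pytest.approx(1.0)
        np.testing.assert_allclose(f.residuals, 0.0, atol=1e-12)
        np.testing.assert_allclose(f.weights, 0.5)  # 1/s

    def test_constant_input(self):
        f = fit_huber_line(np.full(5, 3.0), np.ones(5))
        assert f.beta1 == pytest.approx(0.0)
        np.testing.assert_allclose(f.residuals, 0.0, atol=1e-12)
        np.testing.assert_allclose(f.weights, 1.0)

    def test_outlier_downweighted(self):
        f = fit_huber_line(np.array([1.0, 2.0, 3.0, 4.0, 50.0]), np.ones(5))
        assert f.weights[-1] < min(f.weights[:4])

    @given(st.lists(st.floats(-50, 50), min_size=4, max_size=12))
    @settings(max_examples=60, deadline=None)
    def test_weight_monotone_in_residual(self, values):
        y = np.sort(np.asarray(values, float))
        f = fit_huber_line(y, np.ones(len(y)))
        r = np.abs(f.residuals)
        # equal ses: a larger |residual| never gets a larger weight
        order = np.argsort(r)
        w_sorted = f.weights[order]
        assert all(w_sorted[i] >= w_sorted[i + 1] - 1e-12 for i in range(len(y) - 1))

    def test_input_validation(self):
        with pytest.raises(ValueError, match="3 tissues"):
            fit_huber_line(np.array([1.0, 2.0]), np.ones(2))
        with pytest.raises(ValueError, match="non-finite"):
            fit_huber_line(np.array([1.0, np.nan, 3.0]), np.ones(3))
        with pytest.raises(ValueError, match="> 0"):
            fit_huber_line(np.array([1.0, 2.0, 3.0]), np.array([1.0, 0.0, 1.0]))


class TestRezScores:
    def test_matches_independent_oracle(self, rng):
        n_feat, N = 100, 20
        mean = rng.normal(10, 4, (n_feat, N))
        se = rng.uniform(0.5, 3.0, (n_feat, N))
        prof = rez_scores(make_summary(mean, se))
        for i in range(n_feat):
            z, mu, sd = oracle_rez(mean[i], se[i])
            np.testing.assert_allclose(prof.score.iloc[i].values, z, atol=1e-8)
            assert prof.robust_mean.iloc[i] == pytest.approx(mu, abs=1e-8)
            assert prof.robust_sd.iloc[i] == pytest.approx(sd, abs=1e-8)

    def test_equal_weight_ramp_example(self):
        # linear ramp fits exactly: weights equal; closed-form robust SD
        prof = rez_scores(make_summary([[1.0, 2.0, 3.0, 4.0, 5.0]]))
        sd = math.sqrt((2 * (4 + 1)) / 5 / (1 - 1 / 5))  # = sqrt(2/0.8)
        assert prof.robust_mean.iloc[0] == pytest.approx(3.0)
        assert prof.robust_sd.iloc[0] == pytest.approx(sd)
        z5 = 2.0 / (sd * DEFAULT_LAMBDA)
        assert prof.score.iloc[0, 4] == pytest.approx(z5)
        assert z5 == pytest.approx(1.0328, abs=2e-4)

    def test_pvalue_from_normal_cdf(self):
        prof = rez_scores(make_summary([[1.0, 2.0, 3.0, 4.0, 5.0]]))
        z = prof.score.values[0]
        expected = 2 * stats.norm.sf(np.abs(z))
        np.testing.assert_allclose(prof.pvalue.values[0], expected, atol=1e-12)

    def test_degenerate_constant_feature(self):
        prof = rez_scores(make_summary([[4.0, 4.0, 4.0, 4.0]]))
        assert (prof.score.values == 0).all()
        assert (prof.pvalue.values == 1).all()
        assert "g1" in prof.flags["degenerate"]

    def test_null_p_values_approximately_uniform(self, rng):
        # exchangeable normal tissue means: pooled p close to uniform
        mean = rng.normal(0, 1, (600, 50))
        prof = rez_scores(make_summary(mean))
        p = prof.pvalue.values.ravel()
        assert abs((p < 0.05).mean() - 0.05) < 0.015
        assert stats.kstest(p, "uniform").statistic < 0.06

    def test_scale_invariance(self, rng):
        mean = rng.normal(20, 5, (5, 12))
        se = rng.uniform(0.5, 2.0, (5, 12))
        a = rez_scores(make_summary(mean, se)).score
        b = rez_scores(make_summary(mean * 100, se * 100)).score
        np.testing.assert_allclose(a.values, b.values, atol=1e-9)

    def test_sensitivity_exceeds_conventional_z(self, rng):
        # 5 of 50 tissues shifted: REZ should detect more at matched type-I
        n_null, n_sig, N, shift = 400, 200, 50, 4.0
        null_mean = rng.normal(0, 1, (n_null, N))
        sig_mean = rng.normal(0, 1, (n_sig, N))
        sig_mean[:, :5] += shift
        null_prof_r = rez_scores(make_summary(null_mean)).score.values
        null_prof_c = conventional_z(make_summary(null_mean)).score.values
        thr_r = np.quantile(np.abs(null_prof_r).ravel(), 0.99)
        thr_c = np.quantile(np.abs(null_prof_c).ravel(), 0.99)
        sig_r = np.abs(rez_scores(make_summary(sig_mean)).score.values[:, :5])
        sig_c = np.abs(conventional_z(make_summary(sig_mean)).score.values[:, :5])
        assert (sig_r > thr_r).mean() > (sig_c > thr_c).mean()


class TestConventionalZ:
    def test_unit_sd_case(self):
        prof = conventional_z(make_summary([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(prof.score.values[0], [-1, 0, 1], atol=1e-12)

    def test_location_invariance(self, rng):
        y = rng.normal(0, 1, (4, 8))
        a = conventional_z(make_summary(y)).score.values
        b = conventional_z(make_summary(y + 17.3)).score.values
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_single_spike(self):
        prof = conventional_z(make_summary([[0.0, 0.0, 0.0, 0.0, 10.0]]))
        assert prof.score.iloc[0, 4] == pytest.approx(8 / math.sqrt(20), abs=1e-4)
        assert prof.score.iloc[0, 4] == pytest.approx(1.7889, abs=1e-4)

    def test_degenerate(self):
        prof = conventional_z(make_summary([[2.0, 2.0, 2.0]]))
        assert (prof.score.values == 0).all() and (prof.pvalue.values == 1).all()


class TestMadZ:
    def test_worked_example(self):
        # M=3; nonzero deviations (2,1,1,97); MAD = 1.4826*1.5
        prof = mad_z(make_summary([[1.0, 2.0, 3.0, 4.0, 100.0]]))
        mad = 1.4826 * 1.5
        np.testing.assert_allclose(
            prof.score.values[0], np.array([2, 1, 0, 1, 97]) / mad, atol=1e-10
        )
        assert prof.score.iloc[0, 4] == pytest.approx(43.62, abs=0.01)
        assert prof.pvalue is None

    def test_sign_recorded(self):
        prof = mad_z(make_summary([[1.0, 2.0, 3.0, 4.0, 100.0]]))
        assert prof.sign.iloc[0, 0] == -1
        assert prof.sign.iloc[0, 4] == 1

    def test_symmetric_bound(self, rng):
        y = np.sort(rng.normal(0, 1, 11))
        prof = mad_z(make_summary([y]))
        M = np.median(y)
        dev = np.abs(y - M)
        nz = dev[dev > 0]
        bound = dev.max() / (1.4826 * np.median(nz))
        assert prof.score.values[0].max() <= bound + 1e-12

    def test_all_equal_degenerate(self):
        prof = mad_z(make_summary([[3.0, 3.0, 3.0, 3.0]]))
        assert (prof.score.values == 0).all()
        assert "g1" in prof.flags["degenerate"]

    def test_matches_direct_formula(self, rng):
        y = rng.gamma(2, 5, (20, 9))
        prof = mad_z(make_summary(y))
        for i in range(20):
            M = np.median(y[i])
            dev = np.abs(y[i] - M)
            mad = 1.4826 * np.median(dev[dev > 0])
            np.testing.assert_array_equal(prof.score.values[i], dev / mad)


class TestRvp:
    def test_single_contributor(self):
        prof = rvp(make_summary([[0.0, 0.0, 5.0]]))
        np.testing.assert_allclose(prof.score.values[0], [0, 0, 1], atol=1e-15)

    def test_three_four(self):
        prof = rvp(make_summary([[3.0, 4.0]]))
        np.testing.assert_allclose(prof.score.values[0], [0.36, 0.64], atol=1e-15)

    def test_scale_invariance_and_conservation(self, rng):
        y = rng.gamma(1.5, 8, (25, 7))
        a = rvp(make_summary(y)).score.values
        b = rvp(make_summary(y * 3.7)).score.values
        np.testing.assert_allclose(a, b, atol=1e-12)
        np.testing.assert_allclose(a.sum(axis=1), 1.0, atol=1e-12)
        assert (a >= 0).all() and (a <= 1).all()

    def test_all_zero_flagged(self):
        prof = rvp(make_summary([[0.0, 0.0, 0.0]]))
        assert np.isnan(prof.score.values[0]).all()
        assert "g1" in prof.flags["degenerate"]


class TestCollapseToGene:
    def _profile(self, scores, features, tissues=("T1", "T2")):
        score = pd.DataFrame(scores, index=features, columns=list(tissues), dtype=float)
        pval = 1.0 / (1.0 + score.abs())
        return selexp.SelectiveExpressionProfile(
            score=score, pvalue=pval, measure="rez", level="transcript"
        )

    def test_max_transcript_represents_gene(self):
        prof = self._profile([[2.0, 1.0], [210.3, 0.5]], ["tx1", "tx2"])
        out = collapse_to_gene(prof, {"tx1": "CACNA1C", "tx2": "CACNA1C"})
        assert out.score.loc["CACNA1C", "T1"] == 210.3
        assert out.representing.loc["CACNA1C", "T1"] == "tx2"
        # p carried from the representing transcript
        assert out.pvalue.loc["CACNA1C", "T1"] == prof.pvalue.loc["tx2", "T1"]
        assert out.score.loc["CACNA1C", "T2"] == 1.0
        assert out.representing.loc["CACNA1C", "T2"] == "tx1"

    def test_single_transcript_identity(self):
        prof = self._profile([[1.5, -0.5]], ["tx1"])
        out = collapse_to_gene(prof, {"tx1": "G"})
        np.testing.assert_allclose(out.score.loc["G"].values, [1.5, -0.5])

    def test_permutation_invariance(self):
        p1 = self._profile([[1.0, 5.0], [3.0, 2.0]], ["a", "b"])
        p2 = self._profile([[3.0, 2.0], [1.0, 5.0]], ["b", "a"])
        m = {"a": "G", "b": "G"}
        pd.testing.assert_frame_equal(
            collapse_to_gene(p1, m).score, collapse_to_gene(p2, m).score
        )

    def test_unmapped_excluded(self):
        prof = self._profile([[1.0, 2.0], [3.0, 4.0]], ["a", "zz"])
        out = collapse_to_gene(prof, {"a": "G"})
        assert list(out.score.index) == ["G"]


class TestDeclareSelectiveGenes:
    def test_transcript_count_bonferroni(self):
        # 26 transcripts of one gene: threshold alpha/26
        alpha = 0.05
        n_tx = 26
        ps = np.ones((n_tx, 1))
        ps[0, 0] = alpha / n_tx * 0.99  # just under
        score = pd.DataFrame(np.ones((n_tx, 1)), columns=["T1"],
                             index=[f"tx{i}" for i in range(n_tx)])
        prof = selexp.SelectiveExpressionProfile(
            score=score, pvalue=pd.DataFrame(ps, index=score.index, columns=["T1"]),
            measure="rez", level="transcript",
        )
        tmap = {f"tx{i}": "G" for i in range(n_tx)}
        assert declare_selective_genes(prof, alpha, transcript_gene_map=tmap)["T1"] == {"G"}
        prof.pvalue.iloc[0, 0] = alpha / n_tx * 1.01  # just over
        assert declare_selective_genes(prof, alpha, transcript_gene_map=tmap)["T1"] == set()

    def test_alpha_one_accepts_every_finite_p(self, rng):
        # single-transcript genes: per-gene threshold is alpha/1 = 1
        prof = rez_scores(make_summary(rng.normal(0, 1, (6, 5))))
        prof.level = "transcript"
        tmap = {f: f.upper() for f in prof.feature_ids}
        sets = declare_selective_genes(prof, alpha=1.0, transcript_gene_map=tmap)
        assert all(len(s) == 6 for s in sets.values())

    def test_all_p_one_empty(self):
        prof = rez_scores(make_summary([[2.0, 2.0, 2.0]]))  # degenerate: p = 1
        sets = declare_selective_genes(prof, alpha=0.05)
        assert all(len(s) == 0 for s in sets.values())

    def test_no_pvalue_measure_rejected(self):
        prof = rvp(make_summary([[1.0, 2.0, 3.0]]))
        with pytest.raises(ValueError, match="no p-values"):
            declare_selective_genes(prof)
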