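"""Unit tests of the cohort statistics toolbox against closed-form oracles."""

import numpy as np
import pytest
import scipy.stats as sps

from dmfit import ancova, cohens_d, levene, regress, ttests_fdr, w_scores


class TestWScores:
    def test_matches_hand_computation_on_toy_table(self):
        # 4 control subjects x 2 regions; hand-computed mean and sample SD
        hc = np.array([[1.0, 10.0], [2.0, 12.0], [3.0, 14.0], [4.0, 16.0]])
        # means (2.5, 13), SDs (1.2909944, 2.5819889)
        w = w_scores(np.array([2.5 + 1.2909944487358056, 13.0]), hc)
        assert w == pytest.approx([1.0, 0.0], abs=1e-10)

    def test_controls_standardise_to_mean_zero_sd_one(self, rng):
        hc = rng.normal(5.0, 2.0, size=(20, 6))
        w = w_scores(hc, hc)
        assert np.allclose(w.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(w.std(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_zero_control_sd_raises_naming_region(self):
        hc = np.array([[1.0, 3.0], [1.0, 4.0]])
        with pytest.raises(ValueError, match="region 0"):
            w_scores(np.array([1.0, 3.5]), hc)


class TestRegress:
    def test_exact_line_gives_unit_correlation(self):
        x = np.arange(6.0)
        res = regress(-2.0 * x + 3.0, x)
        assert res.R == pytest.approx(-1.0)
        assert res.R2 == pytest.approx(1.0)
        assert res.slope == pytest.approx(-2.0)
        assert res.intercept == pytest.approx(3.0)

    def test_fixed_dataset_matches_closed_form_ols(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([2.1, 2.9, 4.2, 4.8, 6.1, 6.9])
        res = regress(y, x)
        sxx = np.sum((x - x.mean()) ** 2)
        sxy = np.sum((x - x.mean()) * (y - y.mean()))
        slope = sxy / sxx
        assert res.slope == pytest.approx(slope, rel=1e-12)
        assert res.R == pytest.approx(sxy / np.sqrt(sxx * np.sum((y - y.mean()) ** 2)), rel=1e-12)
        # for simple OLS eta_p2 equals R^2
        assert res.eta_p2 == pytest.approx(res.R2, rel=1e-12)

    def test_null_association_rarely_large(self, rng):
        hits = 0
        for _ in range(40):
            x = rng.normal(size=1000)
            y = rng.normal(size=1000)
            if abs(regress(y, x).R) < 0.1:
                hits += 1
        assert hits >= 38  # |R| < 0.1 in ~95% of null draws at n=1000

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            regress([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])


class TestAncova:
    def test_null_factor_p_uniform(self, rng):
        ps = []
        for _ in range(300):
            n = 40
            factor = np.repeat(["a", "b"], n // 2)
            y = rng.normal(size=n)
            cov = rng.normal(size=n)
            tab = ancova(y, factor, cov)
            ps.append(float(tab.loc[tab["term"] == "factor", "p"].iloc[0]))
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_planted_gender_offset_detected(self, rng):
        detected = 0
        for _ in range(20):
            n = 60
            factor = np.repeat(["F", "M"], n // 2)
            cov = rng.uniform(0, 10, size=n)
            y = 0.05 * cov + (factor == "F") * 1.0 + rng.normal(0, 0.1, size=n)
            tab = ancova(y, factor, cov)
            if float(tab.loc[tab["term"] == "factor", "p"].iloc[0]) < 0.001:
                detected += 1
        assert detected >= 19

    def test_zero_slope_orthogonal_covariate_has_tiny_eta(self, rng):
        n = 200
        factor = np.tile(["a", "b"], n // 2)
        cov = rng.normal(size=n)
        y = (factor == "a") * 1.0 + rng.normal(0, 0.05, size=n)
        tab = ancova(y, factor, cov)
        assert float(tab.loc[tab["term"] == "covariate", "eta_p2"].iloc[0]) < 0.05

    def test_matches_simple_regression_when_factor_degenerate(self, rng):
        # with a single factor level ANCOVA is rank deficient -> compare the
        # covariate F/p against plain OLS on a 2-level factor with no effect
        n = 50
        x = rng.uniform(0, 5, n)
        y = 2.0 - 0.5 * x + rng.normal(0, 0.3, n)
        factor = np.array(["a", "b"] * (n // 2))
        tab = ancova(y, factor, x)
        reg = regress(y, x)
        # F of covariate ~ t^2 of the slope; p-values agree to a few percent
        p_cov = float(tab.loc[tab["term"] == "covariate", "p"].iloc[0])
        assert np.isclose(p_cov, reg.p, rtol=0.25, atol=1e-12) or (p_cov < 1e-10 and reg.p < 1e-10)


class TestLevene:
    def test_identical_samples_give_zero_statistic(self):
        res = levene([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0
        assert res.p_raw == 1.0

    def test_fixed_toy_matches_direct_formula(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([1.0, 5.0, 9.0])
        res = levene(a, b)
        # classical Levene: one-way ANOVA F on Z_ij = |y_ij - mean_i|
        za = np.abs(a - a.mean())
        zb = np.abs(b - b.mean())
        stat, p = sps.f_oneway(za, zb)
        assert res.statistic == pytest.approx(stat, rel=1e-12)
        assert res.p_raw == pytest.approx(p, rel=1e-12)

    def test_detects_threefold_spread(self, rng):
        hits = 0
        for _ in range(30):
            a = rng.normal(0, 1, 50)
            b = a.mean() + 3.0 * (rng.normal(0, 1, 50))
            if levene(a, b).p_raw < 0.05:
                hits += 1
        assert hits >= 27


class TestTTestsFDR:
    def test_bh_stepup_on_fixed_raw_ps(self):
        # raw p {0.01..0.05} with m=5 all adjust to 0.05 under BH
        from statsmodels.stats.multitest import multipletests

        raw = np.array([0.01, 0.02, 0.03, 0.04, 0.05])
        _, adj, _, _ = multipletests(raw, method="fdr_bh")
        assert np.allclose(adj, 0.05)

    def test_identical_samples_p_near_one_and_single_pair_unadjusted(self, rng):
        x = rng.normal(size=30)
        out = ttests_fdr({"a": x, "b": x.copy()}, [("a", "b")])
        assert out["p_raw"].iloc[0] == pytest.approx(1.0)
        assert out["p_adjusted"].iloc[0] == out["p_raw"].iloc[0]

    def test_adjusted_monotone_in_raw_rank(self, rng):
        samples = {f"g{i}": rng.normal(0.1 * i, 1.0, 25) for i in range(6)}
        pairs = [(f"g{i}", f"g{j}") for i in range(6) for j in range(i + 1, 6)]
        out = ttests_fdr(samples, pairs).sort_values("p_raw")
        assert (np.diff(out["p_adjusted"].to_numpy()) >= -1e-12).all()
        assert (out["p_adjusted"] >= out["p_raw"] - 1e-12).all()
        assert (out["p_adjusted"] <= 1.0 + 1e-12).all()


class TestCohensD:
    def test_equal_samples_zero(self, rng):
        x = rng.normal(size=20)
        assert cohens_d(x, x.copy()) == pytest.approx(0.0)

    def test_one_pooled_sd_shift_gives_unit_effect(self, rng):
        a = rng.normal(0, 1, 200)
        b = a.copy()
        na, nb = len(a), len(b)
        pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2))
        assert cohens_d(a + pooled, b) == pytest.approx(1.0, rel=1e-12)

    def test_invariant_under_common_affine_map(self, rng):
        a = rng.normal(1, 2, 30)
        b = rng.normal(0, 2, 40)
        d0 = cohens_d(a, b)
        assert cohens_d(3.0 * a + 7.0, 3.0 * b + 7.0) == pytest.approx(d0, rel=1e-10)

    def test_fixed_toy_matches_hand_computation(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([2.0, 4.0, 6.0])
        # means 2, 4; vars 1, 4; pooled sd = sqrt((2*1+2*4)/4) = sqrt(2.5)
        assert cohens_d(a, b) == pytest.approx(-2.0 / np.sqrt(2.5), rel=1e-12)
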