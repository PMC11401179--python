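import numpy as np
import pandas as pd
import pytest
from scipy import stats

from edgentropy import synth
from edgentropy.templates import similarity_matrix
from edgentropy.varcomp import (VarianceComponentModel, bootstrap_contrast,
                                edgewise_variance, fit_moment_matching,
                                impute, jackknife_contrast, permutation_p,
                                project_out_covariates, quantile_normalize,
                                univariate_fit)


class TestQuantileNormalize:
    def test_three_point_column(self):
        out = quantile_normalize(np.array([[1.0], [2.0], [3.0]]))
        expected = stats.norm.ppf([1 / 6, 3 / 6, 5 / 6])
        np.testing.assert_allclose(out.ravel(), expected, atol=1e-3)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.random((40, 1))
        np.testing.assert_allclose(quantile_normalize(x),
                                   quantile_normalize(np.exp(5 * x)),
                                   atol=1e-12)

    def test_output_moments(self):
        rng = np.random.default_rng(1)
        out = quantile_normalize(rng.random((97, 3)))
        np.testing.assert_allclose(out.mean(0), 0, atol=1e-12)
        np.testing.assert_allclose(out.var(0), 1, atol=0.05)

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError):
            quantile_normalize(np.ones((10, 1)))

    def test_dataframe_roundtrip_keeps_labels(self):
        df = pd.DataFrame(np.random.default_rng(2).random((10, 2)),
                          columns=["a", "b"])
        out = quantile_normalize(df)
        assert list(out.columns) == ["a", "b"]


class TestImpute:
    def test_behavior_median_and_dose_zero(self):
        beh = pd.DataFrame({"mem": [1.0, np.nan, 3.0, 5.0, 2.0, 2.0,
                                    4.0, 1.0, 2.0, 3.0, 3.0]})
        cov = pd.DataFrame({"dose": [np.nan, 10.0] + [5.0] * 9})
        b2, c2 = impute(beh, cov)
        assert b2.loc[1, "mem"] == beh.mem.median()
        assert c2.loc[0, "dose"] == 0.0

    def test_no_missing_is_identity(self):
        beh = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        cov = pd.DataFrame({"dose": [1.0, 2.0, 3.0]})
        b2, c2 = impute(beh, cov)
        pd.testing.assert_frame_equal(b2, beh)
        pd.testing.assert_frame_equal(c2, cov)

    def test_excess_missingness_rejected(self):
        beh = pd.DataFrame({"x": [np.nan, np.nan, 3.0, 4.0]})
        with pytest.raises(ValueError):
            impute(beh, pd.DataFrame({"dose": [1.0] * 4}))


class TestProjection:
    def test_dimension_is_n_minus_rank(self, structured_R, covariates_100):
        Y = np.random.default_rng(3).standard_normal((100, 7))
        Y_t, R_t = project_out_covariates(Y, covariates_100, structured_R)
        assert Y_t.shape == (100 - 6, 7)  # intercept + 5 covariates
        assert R_t.shape == (94, 94)

    def test_intercept_only_equals_centering(self, structured_R):
        Y = np.random.default_rng(4).standard_normal((100, 3))
        fit_proj = VarianceComponentModel(n_perm=0).fit(Y, structured_R, None)
        Yc = Y - Y.mean(0)
        # centered fit in the complement basis must give the same fractions
        fit2 = VarianceComponentModel(n_perm=0).fit(Yc, structured_R, None)
        assert fit_proj.m_raw_ == pytest.approx(fit2.m_raw_, abs=1e-10)

    def test_fixed_effects_annihilated(self, structured_R, covariates_100):
        rng = np.random.default_rng(5)
        Y = rng.standard_normal((100, 7))
        B = 10 * rng.standard_normal((5, 7))
        f1 = VarianceComponentModel(n_perm=0).fit(Y, structured_R,
                                                  covariates_100)
        f2 = VarianceComponentModel(n_perm=0).fit(
            Y + covariates_100 @ B, structured_R, covariates_100)
        assert abs(f1.m_raw_ - f2.m_raw_) < 1e-10

    def test_collinear_columns_listed(self, structured_R):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((50, 3))
        X = np.column_stack([X, X[:, 0] + X[:, 1]])
        with pytest.raises(ValueError, match="collinear.*3"):
            project_out_covariates(rng.standard_normal((50, 2)), X,
                                   structured_R[:50, :50])


class TestMomentMatching:
    def test_hand_computed_formulas_small_case(self):
        # N = 4, P = 1: evaluate the two closed-form expressions manually
        Y = np.array([[1.0], [-2.0], [0.5], [3.0]])
        R = np.array([[1.0, 0.5, 0.2, 0.1],
                      [0.5, 1.0, 0.3, 0.2],
                      [0.2, 0.3, 1.0, 0.4],
                      [0.1, 0.2, 0.4, 1.0]])
        N = 4
        tau = np.trace(R) / N
        kappa = np.trace(R @ R) / N
        nu = N * (kappa - tau ** 2)
        sigma_c_manual = (Y.T @ (R - tau * np.eye(N)) @ Y) / nu
        sigma_e_manual = (Y.T @ (kappa * np.eye(N) - tau * R) @ Y) / nu
        res = fit_moment_matching(Y, R)
        np.testing.assert_allclose(res.sigma_c, sigma_c_manual, atol=1e-12)
        np.testing.assert_allclose(res.sigma_e, sigma_e_manual, atol=1e-12)
        assert res.tau == pytest.approx(tau)
        assert res.nu == pytest.approx(nu)

    def test_null_mean_near_zero(self, structured_R, covariates_100):
        ms = []
        for rep in range(300):
            Y = np.random.default_rng(100 + rep).standard_normal((100, 7))
            fit = VarianceComponentModel(n_perm=0).fit(Y, structured_R,
                                                       covariates_100)
            ms.append(fit.m_overall_)  # clipped, as reported
        assert np.mean(ms) < 0.05

    def test_planted_fraction_recovered(self, structured_R, covariates_100):
        spec = synth.spec_for_fraction(0.40, 7, structured_R)
        ms = []
        for rep in range(300):
            Y = synth.generate_behavior(spec, covariates_100,
                                        seed=rep).to_numpy()
            fit = VarianceComponentModel(n_perm=0).fit(Y, structured_R,
                                                       covariates_100)
            ms.append(fit.m_raw_)
        assert 0.35 < np.mean(ms) < 0.45

    def test_scale_equivariance(self, structured_R):
        Y = np.random.default_rng(7).standard_normal((100, 4))
        f1 = VarianceComponentModel(n_perm=0).fit(Y, structured_R)
        f2 = VarianceComponentModel(n_perm=0).fit(7.3 * Y, structured_R)
        assert f1.m_raw_ == pytest.approx(f2.m_raw_, abs=1e-12)
        np.testing.assert_allclose(f1.m_per_measure_, f2.m_per_measure_,
                                   atol=1e-12)

    def test_tau_equals_one_for_unit_diagonal(self):
        stack = np.random.default_rng(8).random((30, 100))
        R = similarity_matrix(stack)
        assert np.trace(R) / len(R) == pytest.approx(1.0)

    def test_identity_kernel_unidentifiable(self):
        Y = np.random.default_rng(9).standard_normal((30, 2))
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_moment_matching(Y, np.eye(30))

    def test_recovery_monotone_in_planted_fraction(self, structured_R,
                                                   covariates_100):
        means = []
        for f in (0.0, 0.2, 0.4, 0.6, 0.8):
            spec = synth.spec_for_fraction(f, 7, structured_R)
            ms = [VarianceComponentModel(n_perm=0).fit(
                synth.generate_behavior(spec, covariates_100,
                                        seed=rep).to_numpy(),
                structured_R, covariates_100).m_raw_ for rep in range(60)]
            means.append(np.mean(ms))
        assert np.all(np.diff(means) > 0)


class TestInference:
    def test_wald_p_half_at_zero_estimate(self):
        from edgentropy.varcomp import _wald_pvalue
        assert _wald_pvalue(0.0, 0.1) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            _wald_pvalue(0.1, 0.0)

    def test_permutation_relabeling_invariance(self, structured_R):
        rng = np.random.default_rng(10)
        Y = rng.standard_normal((100, 3))
        perm = rng.permutation(100)
        f1 = VarianceComponentModel(n_perm=0).fit(Y, structured_R)
        f2 = VarianceComponentModel(n_perm=0).fit(
            Y[perm], structured_R[np.ix_(perm, perm)])
        assert f1.m_raw_ == pytest.approx(f2.m_raw_, abs=1e-10)

    def test_permutation_power_on_planted_signal(self, structured_R,
                                                 covariates_100):
        spec = synth.spec_for_fraction(0.40, 7, structured_R)
        rejections = 0
        n_runs = 60
        for rep in range(n_runs):
            Y = synth.generate_behavior(spec, covariates_100,
                                        seed=rep).to_numpy()
            Y_t, R_t = project_out_covariates(Y, covariates_100, structured_R)
            p = permutation_p(Y_t, R_t, n_perm=99, seed=rep)
            rejections += p <= 0.05
        assert rejections / n_runs > 0.80

    def test_permuted_outcome_mostly_nonsignificant(self, structured_R):
        rng = np.random.default_rng(11)
        nonsig = 0
        for rep in range(100):
            y = rng.standard_normal(100)
            fit = univariate_fit(y, None, structured_R)
            nonsig += fit.p_wald_ > 0.05
        assert nonsig / 100 >= 0.90


class TestUnivariate:
    def test_reduces_to_multivariate_single_column(self, structured_R,
                                                   covariates_100):
        y = np.random.default_rng(12).standard_normal(100)
        uni = univariate_fit(y, covariates_100, structured_R)
        multi = VarianceComponentModel(n_perm=0).fit(
            y[:, None], structured_R, covariates_100)
        assert uni.m_raw_ == pytest.approx(multi.m_raw_, abs=1e-12)
        assert uni.se_overall_ == pytest.approx(multi.se_overall_, abs=1e-12)

    def test_high_signal_recovery_within_two_se(self, structured_R,
                                                covariates_100):
        spec = synth.spec_for_fraction(0.60, 1, structured_R)
        hits = 0
        for rep in range(40):
            y = synth.generate_behavior(spec, covariates_100,
                                        seed=rep).to_numpy()
            fit = univariate_fit(y, covariates_100, structured_R)
            hits += abs(fit.m_raw_ - 0.60) <= 2 * fit.se_overall_
        assert hits / 40 > 0.80


class TestContrasts:
    @pytest.fixture(scope="class")
    def contrast_data(self):
        rng = np.random.default_rng(13)
        N, E = 97, 600
        mask_a = np.arange(0, 250)
        mask_b = np.arange(250, 500)
        stack = synth.generate_entropy_features(
            N, E, informative=[mask_a, mask_b], n_latent=20, signal=5.0,
            seed=14)
        X = rng.standard_normal((N, 3))
        return stack, mask_a, mask_b, X

    def test_identical_kernels_contain_zero(self, contrast_data):
        stack, mask_a, _, X = contrast_data
        R = similarity_matrix(stack[:, mask_a])
        Y = synth.generate_behavior(
            synth.spec_for_fraction(0.4, 5, R, n_covariates=3), X,
            seed=15).to_numpy()
        res = bootstrap_contrast(Y, X, stack, mask_a, mask_a, n_boot=200,
                                 seed=0)
        assert not res.loc["overall", "excludes_zero"]
        assert res.loc["overall", "difference"] == pytest.approx(0.0)

    def test_ci_nested_in_alpha(self, contrast_data):
        stack, mask_a, mask_b, X = contrast_data
        Y = np.random.default_rng(16).standard_normal((97, 5))
        wide = bootstrap_contrast(Y, X, stack, mask_a, mask_b, n_boot=300,
                                  alpha=0.01, seed=1)
        narrow = bootstrap_contrast(Y, X, stack, mask_a, mask_b, n_boot=300,
                                    alpha=0.10, seed=1)
        assert (wide.ci_hi - wide.ci_lo >= narrow.ci_hi - narrow.ci_lo
                - 1e-12).all()

    def test_planted_contrast_detected_and_methods_agree(self, contrast_data):
        stack, mask_a, mask_b, X = contrast_data
        R_a = similarity_matrix(stack[:, mask_a])
        R_b = similarity_matrix(stack[:, mask_b])
        agree = detected = 0
        n_runs = 10
        for rep in range(n_runs):
            Y = synth.generate_behavior_mixture(
                [(R_a, 0.2), (R_b, 0.5)], 5, X, seed=20 + rep).to_numpy()
            bs = bootstrap_contrast(Y, X, stack, mask_a, mask_b, n_boot=300,
                                    seed=rep)
            jk = jackknife_contrast(Y, X, stack, mask_a, mask_b)
            detected += bool(bs.loc["overall", "excludes_zero"]
                             and bs.loc["overall", "difference"] < 0)
            agree += np.sign(bs.loc["overall", "difference"]) == np.sign(
                jk.loc["overall", "difference"])
        assert detected / n_runs >= 0.8
        assert agree == n_runs  # same point estimate, so signs always agree

    def test_jackknife_zero_width_for_constant_loo(self):
        # a contrast of a mask with itself: every leave-one-out difference
        # is exactly zero, so the jackknife interval collapses to the point
        rng = np.random.default_rng(17)
        stack = synth.generate_entropy_features(20, 100,
                                                informative=np.arange(30),
                                                seed=18)
        Y = rng.standard_normal((20, 3))
        mask = np.arange(30)
        res = jackknife_contrast(Y, None, stack, mask, mask)
        assert res.se.eq(0).all()
        np.testing.assert_allclose(res.ci_lo, res.difference, atol=1e-12)

    def test_jackknife_se_comparable_to_bootstrap(self, contrast_data):
        stack, mask_a, mask_b, X = contrast_data
        Y = np.random.default_rng(19).standard_normal((97, 5))
        bs = bootstrap_contrast(Y, X, stack, mask_a, mask_b, n_boot=400,
                                seed=2)
        jk = jackknife_contrast(Y, X, stack, mask_a, mask_b)
        bs_se = (bs.loc["overall", "ci_hi"] - bs.loc["overall", "ci_lo"]) / (
            2 * stats.norm.ppf(0.975))
        ratio = jk.loc["overall", "se"] / bs_se
        assert 1 / 1.5 < ratio < 1.5


class TestEdgewise:
    def test_output_length_matches_mask(self):
        stack = synth.generate_entropy_features(40, 200, seed=20)
        Y = np.random.default_rng(21).standard_normal((40, 3))
        mask = np.arange(25)
        vals = edgewise_variance(Y, None, stack, mask)
        assert vals.shape == (25,)

    def test_null_edges_near_zero(self):
        stack = synth.generate_entropy_features(60, 50, seed=22)
        vals = []
        for rep in range(40):
            Y = np.random.default_rng(rep).standard_normal((60, 3))
            vals.append(np.nanmean(
                edgewise_variance(Y, None, stack, np.arange(5))))
        assert np.mean(vals) < 0.05

    def test_generating_edge_diluted_by_measure_count(self):
        # one edge drives one of P measures at fraction ~0.5: the edgewise
        # average should be near 0.5/P plus the null floor
        rng = np.random.default_rng(23)
        N, P = 120, 7
        stack = synth.generate_entropy_features(N, 30, seed=24)
        z = stats.zscore(stack[:, 3], ddof=0)
        Y = rng.standard_normal((N, P))
        Y[:, 0] = np.sqrt(0.5) * z + np.sqrt(0.5) * rng.standard_normal(N)
        val = edgewise_variance(Y, None, stack, np.array([3]))[0]
        assert 0.3 / P < val < 1.5 / P

    def test_zero_variance_edge_flagged(self):
        stack = synth.generate_entropy_features(30, 20, seed=25)
        stack[:, 4] = 0.2
        Y = np.random.default_rng(26).standard_normal((30, 2))
        vals = edgewise_variance(Y, None, stack, np.array([3, 4]))
        assert np.isfinite(vals[0]) and np.isnan(vals[1])
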