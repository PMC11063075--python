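"""Effect standardization: shrinkage, REML heritability, SD-unit conversion."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import invgamma, kstest

from exertrait.standardize import (
    HeritabilityEstimate,
    VariancePrior,
    estimate_h2_reml,
    fit_variance_prior,
    grm_eigen,
    h2_significance_filter,
    posterior_variance,
    pseudolog,
    residualize,
    standardize_effects,
    standardize_study,
    _profile_loglik,
)
from exertrait.simulate import _simulate_grm


class TestPseudolog:
    @pytest.mark.parametrize("x, expected", [(0, 0.0), (1, 1.0), (3, 2.0)])
    def test_values(self, x, expected):
        assert pseudolog(x) == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            pseudolog(-0.5)

    def test_inverts_counts_mapping(self, rng):
        y = rng.uniform(0, 12, size=100)
        assert np.allclose(pseudolog(np.exp2(y) - 1), y)


class TestResidualize:
    def test_matches_normal_equations_oracle(self, rng):
        n, q = 6, 2
        cov = rng.normal(size=(n, q))
        y = rng.normal(size=(n, 3))
        res = residualize(y, cov)
        design = np.column_stack([np.ones(n), cov])
        beta = np.linalg.inv(design.T @ design) @ design.T @ y
        assert np.allclose(res, y - design @ beta, atol=1e-10)

    def test_residuals_orthogonal_to_design(self, rng):
        cov = rng.normal(size=(40, 3))
        res = residualize(rng.normal(size=(40, 5)), cov)
        assert np.abs(cov.T @ res).max() < 1e-8
        assert np.abs(res.sum(axis=0)).max() < 1e-8

    def test_expression_equal_to_covariate_residual_zero(self, rng):
        cov = rng.normal(size=(20, 2))
        res = residualize(cov[:, [0]], cov)
        assert np.abs(res).max() < 1e-10

    def test_collinear_design_named(self, rng):
        c = rng.normal(size=(20, 1))
        cov = np.column_stack([c, 2 * c])
        with pytest.raises(ValueError, match="collinear"):
            residualize(rng.normal(size=(20, 2)), cov)


class TestVariancePrior:
    def test_recovers_inverse_gamma_parameters(self):
        s2 = invgamma.rvs(3.0, scale=2.0, size=5000,
                          random_state=np.random.default_rng(1))
        prior = fit_variance_prior(s2)
        assert prior.converged and not prior.fallback
        assert prior.shape == pytest.approx(3.0, rel=0.15)
        assert prior.rate == pytest.approx(2.0, rel=0.15)

    def test_fitted_cdf_near_half_at_median(self):
        s2 = invgamma.rvs(4.0, scale=1.5, size=2000,
                          random_state=np.random.default_rng(2))
        prior = fit_variance_prior(s2)
        at_median = invgamma.cdf(np.median(s2), prior.shape, scale=prior.rate)
        assert abs(at_median - 0.5) < 0.15

    def test_constant_input_falls_back_to_moment_matching(self):
        prior = fit_variance_prior(np.full(100, 2.5))
        assert prior.fallback
        assert prior.shape > 1e4  # degenerate: concentrates at the point mass

    def test_deterministic_objective(self):
        s2 = invgamma.rvs(3.0, scale=2.0, size=500,
                          random_state=np.random.default_rng(3))
        a = fit_variance_prior(s2)
        b = fit_variance_prior(s2)
        assert (a.shape, a.rate) == (b.shape, b.rate)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fit_variance_prior(np.ones(10))  # too few
        with pytest.raises(ValueError):
            fit_variance_prior(np.linspace(-1, 1, 100))  # non-positive


class TestPosteriorVariance:
    def test_no_data_returns_prior(self):
        prior = VariancePrior(shape=3.0, rate=4.0)
        post = posterior_variance(2.0, 0, prior)
        assert post.post_mean_var == pytest.approx(prior.prior_mean)

    def test_conjugate_update_formula(self):
        post = posterior_variance(2.0, 4, VariancePrior(shape=3.0, rate=4.0))
        assert (post.a_post, post.b_post) == (5.0, 8.0)
        assert post.post_mean_var == pytest.approx(2.0)

    def test_data_dominance_limit(self):
        post = posterior_variance(1.7, 10**6, VariancePrior(shape=3.0, rate=4.0))
        assert post.post_mean_var == pytest.approx(1.7, abs=1e-3)

    def test_shrinkage_between_prior_mean_and_s2(self):
        prior = VariancePrior(shape=5.0, rate=8.0)  # prior mean 2
        post = posterior_variance(6.0, 20, prior)
        assert 2.0 < post.post_mean_var < 6.0

    def test_monotone_in_s2(self):
        prior = VariancePrior(shape=3.0, rate=4.0)
        means = [posterior_variance(s2, 10, prior).post_mean_var
                 for s2 in (0.5, 1.0, 2.0, 4.0)]
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_undefined_posterior_mean_rejected(self):
        with pytest.raises(ValueError):
            posterior_variance(1.0, 0, VariancePrior(shape=0.5, rate=1.0))


def _structured_grm(n, seed=0):
    grm, _ = _simulate_grm(n, 2 * n, np.random.default_rng(seed))
    return grm


class TestReml:
    def test_pure_noise_estimates_near_zero(self):
        grm = _structured_grm(120, seed=4)
        eig = grm_eigen(grm)
        rng = np.random.default_rng(5)
        ests, pvals = [], []
        for _ in range(200):
            y = rng.standard_normal(120)
            est = estimate_h2_reml(y, eig)
            ests.append(est.h2)
            pvals.append(est.p_value)
        assert np.mean(ests) <= 0.1
        # boundary test: null p-values stochastically >= uniform
        assert np.mean(pvals) >= 0.5
        assert kstest(pvals, "uniform", alternative="greater").pvalue > 0.01

    def test_planted_half_recovered(self):
        grm = _structured_grm(300, seed=6)
        lam, vecs = grm_eigen(grm)
        chol = np.linalg.cholesky(grm + 1e-8 * np.eye(300))
        rng = np.random.default_rng(7)
        ests = []
        for _ in range(100):
            g = chol @ rng.standard_normal(300) * np.sqrt(0.5)
            y = g + rng.standard_normal(300) * np.sqrt(0.5)
            ests.append(estimate_h2_reml(y, (lam, vecs)).h2)
        assert abs(np.mean(ests) - 0.5) < 0.07

    def test_no_noise_hits_upper_boundary(self):
        grm = _structured_grm(100, seed=8)
        chol = np.linalg.cholesky(grm + 1e-8 * np.eye(100))
        y = chol @ np.random.default_rng(9).standard_normal(100)
        assert estimate_h2_reml(y, grm).h2 >= 0.95

    def test_identity_grm_unidentifiable(self):
        with pytest.raises(ValueError, match="unidentifiable"):
            grm_eigen(np.eye(50))

    def test_non_psd_grm_rejected(self):
        bad = -np.eye(40)
        with pytest.raises(ValueError):
            grm_eigen(bad)

    def test_optimum_matches_dense_grid(self):
        # profiled REML log-likelihood at the optimum vs a dense ratio grid
        grm = _structured_grm(50, seed=10)
        lam, vecs = grm_eigen(grm)
        rng = np.random.default_rng(11)
        for _ in range(5):
            y = rng.standard_normal(50)
            est = estimate_h2_reml(y, (lam, vecs))
            y2 = (vecs.T @ y) ** 2
            grid = np.linspace(0, 1 - 1e-9, 20001)
            grid_best = max(_profile_loglik(h, lam, y2) for h in grid)
            assert est.loglik >= grid_best - 1e-4


class TestFilter:
    def test_all_unit_pvalues_fail(self):
        df = pd.DataFrame({"tissue": ["A"] * 5, "p_value": [1.0] * 5})
        out, removed = h2_significance_filter(df, alpha=0.1)
        assert not out["passed_h2_filter"].any()
        assert removed == 1.0

    def test_single_stratum_equals_plain_bh(self):
        pvals = np.array([0.001, 0.01, 0.02, 0.2, 0.9])
        df = pd.DataFrame({"tissue": ["A"] * 5, "p_value": pvals})
        out, _ = h2_significance_filter(df, alpha=0.05)
        from statsmodels.stats.multitest import multipletests

        expected, *_ = multipletests(pvals, alpha=0.05, method="fdr_bh")
        assert (out["passed_h2_filter"].to_numpy() == expected).all()

    def test_two_strata_match_hand_enumeration(self):
        # BH step-up within each stratum, enumerated by hand:
        # stratum A at alpha=0.10, p=(0.01, 0.04, 0.3, 0.9, 0.95):
        #   sorted thresholds k*alpha/5 = .02,.04,.06,.08,.10 -> reject 2
        # stratum B p=(0.5, 0.6, 0.7, 0.8, 0.9): reject none
        df = pd.DataFrame(
            {
                "tissue": ["A"] * 5 + ["B"] * 5,
                "p_value": [0.01, 0.04, 0.3, 0.9, 0.95,
                            0.5, 0.6, 0.7, 0.8, 0.9],
            }
        )
        out, removed = h2_significance_filter(df, alpha=0.10)
        flags = out.groupby("tissue")["passed_h2_filter"].sum()
        assert flags["A"] == 2 and flags["B"] == 0
        assert removed == pytest.approx(0.8)

    def test_invalid_alpha(self):
        df = pd.DataFrame({"tissue": ["A"], "p_value": [0.5]})
        with pytest.raises(ValueError):
            h2_significance_filter(df, alpha=1.5)


class TestStandardizedEffects:
    def _post(self, var, n=10):
        return posterior_variance(var, 0, VariancePrior(shape=2.0, rate=var))

    def test_zero_fold_change(self):
        eff = standardize_effects(0.0, self._post(4.0))
        assert eff.sd_pheno_units == 0.0

    def test_pheno_units_arithmetic(self):
        post = posterior_variance(0.0, 0, VariancePrior(shape=2.0, rate=4.0))
        assert post.post_mean_var == 4.0
        eff = standardize_effects(2.0, post)
        assert eff.sd_pheno_units == pytest.approx(1.0)

    def test_geno_units_arithmetic(self):
        post = posterior_variance(0.0, 0, VariancePrior(shape=2.0, rate=4.0))
        h2 = HeritabilityEstimate("g", "t", h2=0.25, p_value=0.001, converged=True)
        eff = standardize_effects(2.0, post, h2, passed_h2_filter=True)
        assert eff.sd_geno_units == pytest.approx(2.0)

    def test_geno_dominates_pheno_in_magnitude(self):
        post = posterior_variance(1.0, 50, VariancePrior(shape=3.0, rate=2.0))
        h2 = HeritabilityEstimate("g", "t", h2=0.6, p_value=0.001, converged=True)
        eff = standardize_effects(-1.3, post, h2, passed_h2_filter=True)
        assert abs(eff.sd_geno_units) >= abs(eff.sd_pheno_units)

    def test_zero_h2_with_filter_rejected(self):
        post = posterior_variance(1.0, 10, VariancePrior(shape=3.0, rate=2.0))
        h2 = HeritabilityEstimate("g", "t", h2=0.0, p_value=1.0, converged=True)
        with pytest.raises(ValueError):
            standardize_effects(1.0, post, h2, passed_h2_filter=True)


class TestStandardizeStudy:
    def test_full_run_schema_and_invariant(self, small_config, small_de):
        import exertrait

        cohort = exertrait.generate_human_cohort(small_config)
        std = standardize_study(cohort, small_de, alpha=0.10)
        assert set(std["tissue"]) == set(small_config.tissue_labels)
        both = std.dropna(subset=["sd_geno_units"])
        assert (np.abs(both["sd_geno_units"])
                >= np.abs(both["sd_pheno_units"]) - 1e-12).all()
        assert both["passed_h2_filter"].all()
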