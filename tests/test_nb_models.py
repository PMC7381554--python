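"""Likelihood fitters: NB GLM/GLMM and Gaussian LMM contracts."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from paradetect import (
    InvalidInputError,
    ModelFitError,
    RankDeficientError,
    compare_aic,
    fit_lmm,
    fit_nb_glm,
    fit_nb_glmm,
)
from paradetect.nb_models import K_MAX, nb_loglik

from conftest import nb_draw, two_group_design


class TestNbGlm:
    def test_constant_counts_pin_dispersion_at_poisson_boundary(self):
        y = np.full(40, 5)
        fit = fit_nb_glm(y, pd.DataFrame({"intercept": np.ones(40)}))
        assert fit.coefficients["intercept"] == pytest.approx(math.log(5), abs=1e-5)
        assert fit.dispersion_at_boundary
        assert fit.dispersion_k == pytest.approx(K_MAX, rel=1e-3)

    def test_all_zero_counts_is_a_fit_error(self):
        with pytest.raises(ModelFitError):
            fit_nb_glm(np.zeros(20, dtype=int),
                       pd.DataFrame({"intercept": np.ones(20)}))

    def test_rank_deficient_design_names_aliased_column(self):
        X = pd.DataFrame({"intercept": np.ones(10),
                          "copy": np.ones(10)})
        with pytest.raises(RankDeficientError, match="copy"):
            fit_nb_glm(np.arange(10), X)

    def test_parameter_recovery_two_group(self):
        """Treatment coefficient recovers log 2 within 3 SEs at n=2000."""
        rng = np.random.default_rng(10)
        n, k = 1000, 1.5
        y = np.r_[nb_draw(rng, 5.0, k, n), nb_draw(rng, 10.0, k, n)]
        fit = fit_nb_glm(y, two_group_design(n))
        est = fit.coefficients["treatment"]
        se = fit.standard_errors["treatment"]
        assert abs(est - math.log(2)) < 3 * se
        assert fit.dispersion_k == pytest.approx(k, rel=0.2)

    def test_mean_bias_small_over_replicates(self):
        rng = np.random.default_rng(11)
        n, k = 1000, 1.5
        X = two_group_design(n)
        ests = []
        for _ in range(200):
            y = np.r_[nb_draw(rng, 5.0, k, n), nb_draw(rng, 10.0, k, n)]
            ests.append(fit_nb_glm(y, X).coefficients["treatment"])
        assert abs(np.mean(ests) - math.log(2)) < 0.05

    def test_optimum_beats_random_perturbations(self):
        rng = np.random.default_rng(12)
        n, k = 100, 2.0
        y = np.r_[nb_draw(rng, 3.0, k, n), nb_draw(rng, 4.0, k, n)]
        X = two_group_design(n)
        fit = fit_nb_glm(y, X)
        beta = np.array([fit.coefficients["intercept"],
                         fit.coefficients["treatment"]])
        ll_opt = nb_loglik(y.astype(float), X.to_numpy() @ beta,
                           fit.dispersion_k).sum()
        assert ll_opt == pytest.approx(fit.log_likelihood, abs=1e-6)
        for _ in range(100):
            pert = beta + rng.normal(0, 0.05, 2)
            ll = nb_loglik(y.astype(float), X.to_numpy() @ pert,
                           fit.dispersion_k).sum()
            assert ll <= ll_opt + 1e-8

    def test_matches_statsmodels_oracle(self):
        """Independent general-purpose optimizer agrees to 1e-4."""
        import statsmodels.api as sm

        rng = np.random.default_rng(13)
        n = 150
        y = np.r_[nb_draw(rng, 2.0, 1.2, n), nb_draw(rng, 4.5, 1.2, n)]
        X = two_group_design(n)
        fit = fit_nb_glm(y, X)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.NegativeBinomial(y, X).fit(disp=0)
        assert fit.coefficients["intercept"] == pytest.approx(res.params[0], abs=1e-4)
        assert fit.coefficients["treatment"] == pytest.approx(res.params[1], abs=1e-4)
        assert fit.dispersion_k == pytest.approx(1 / res.params[2], rel=1e-3)
        assert fit.log_likelihood == pytest.approx(res.llf, abs=1e-4)

    def test_poisson_limit_of_loglik(self):
        rng = np.random.default_rng(14)
        y = rng.poisson(3.0, 200).astype(float)
        eta = np.full(200, math.log(3.0))
        ll_nb = nb_loglik(y, eta, 1e6).sum()
        ll_pois = stats.poisson.logpmf(y.astype(int), 3.0).sum()
        assert ll_nb == pytest.approx(ll_pois, rel=1e-4)

    def test_aic_identity(self):
        rng = np.random.default_rng(15)
        y = nb_draw(rng, 3.0, 1.0, 100)
        fit = fit_nb_glm(y, pd.DataFrame({"intercept": np.ones(100)}))
        assert fit.aic == pytest.approx(
            2 * fit.n_params - 2 * fit.log_likelihood, abs=1e-10
        )
        assert fit.n_params == 2  # intercept + dispersion
        for term in fit.coefficients:
            z = fit.coefficients[term] / fit.standard_errors[term]
            assert fit.z_values[term] == pytest.approx(z, rel=1e-10)
            assert fit.p_values[term] == pytest.approx(
                2 * stats.norm.sf(abs(z)), rel=1e-10
            )


class TestNbGlmm:
    @staticmethod
    def _simulate(rng, sigma, n_groups=40, per_group=10, k=1.5,
                  beta=(math.log(3.0), 0.5)):
        groups = np.repeat(np.arange(n_groups), per_group)
        b = rng.normal(0, sigma, n_groups)[groups] if sigma > 0 else 0.0
        treat = rng.integers(0, 2, n_groups * per_group).astype(float)
        mu = np.exp(beta[0] + beta[1] * treat + b)
        y = nb_draw(rng, mu, k)
        X = pd.DataFrame({"intercept": np.ones(len(y)), "treatment": treat})
        return y, X, groups

    def test_sigma_zero_boundary_matches_glm(self):
        """With no true group variance the random-intercept SD collapses to
        the boundary for the typical draw (the MLE is 0 with probability
        ~1/2 under mixture asymptotics) and fixed effects agree with the
        plain GLM."""
        rng = np.random.default_rng(20)
        sds = []
        for _ in range(10):
            y, X, groups = self._simulate(rng, sigma=0.0, n_groups=50,
                                          per_group=15)
            glmm = fit_nb_glmm(y, X, groups)
            glm = fit_nb_glm(y, X)
            sds.append(glmm.random_intercept_sd)
            for term in glm.coefficients:
                assert glmm.coefficients[term] == pytest.approx(
                    glm.coefficients[term], rel=0.01, abs=0.02
                )
            # extra variance parameter can only raise the likelihood
            assert glmm.log_likelihood >= glm.log_likelihood - 1e-6
        assert np.median(sds) < 0.05

    def test_sigma_recovery_across_replicates(self):
        """sigma = 0.5 with 40 tows x 10 fish lands in [0.3, 0.7] for the
        large majority of replicates."""
        rng = np.random.default_rng(21)
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            y, X, groups = self._simulate(rng, sigma=0.5)
            fit = fit_nb_glmm(y, X, groups)
            hits += 0.3 <= fit.random_intercept_sd <= 0.7
        assert hits / n_rep >= 0.90

    def test_quadrature_converged_by_five_nodes(self):
        rng = np.random.default_rng(22)
        y, X, groups = self._simulate(rng, sigma=0.4)
        f5 = fit_nb_glmm(y, X, groups, n_quad=5)
        from paradetect.nb_models import _glmm_nll_factory, _group_structure

        order, starts, _ = _group_structure(groups)
        params = np.array(
            [f5.coefficients["intercept"], f5.coefficients["treatment"],
             math.log(f5.dispersion_k), f5.random_intercept_sd]
        )
        nll5 = _glmm_nll_factory(np.asarray(y, float), X.to_numpy(), order,
                                 starts, 5)(params)
        nll15 = _glmm_nll_factory(np.asarray(y, float), X.to_numpy(), order,
                                  starts, 15)(params)
        assert abs(nll5 - nll15) < 1e-3

    def test_single_group_warns_and_falls_back(self):
        rng = np.random.default_rng(23)
        y = nb_draw(rng, 3.0, 1.0, 50)
        X = pd.DataFrame({"intercept": np.ones(50)})
        with pytest.warns(UserWarning, match="single group"):
            fit = fit_nb_glmm(y, X, np.zeros(50, dtype=int))
        assert fit.method == "nb_glm"

    def test_treatment_recovery_with_clustering(self):
        rng = np.random.default_rng(24)
        y, X, groups = self._simulate(rng, sigma=0.5)
        fit = fit_nb_glmm(y, X, groups)
        assert abs(fit.coefficients["treatment"] - 0.5) < 3 * fit.standard_errors["treatment"]
        assert fit.aic == pytest.approx(
            2 * fit.n_params - 2 * fit.log_likelihood, abs=1e-10
        )
        assert fit.n_params == 4  # 2 fixed + dispersion + random SD


class TestLmm:
    def test_identical_response_gives_zero_estimate(self):
        n = 40
        X = two_group_design(n // 2)
        y = np.full(n, 150.0) + np.r_[np.arange(20), np.arange(20)]
        fit = fit_lmm(y, X)
        assert fit.coefficients["treatment"] == pytest.approx(0.0, abs=1e-10)

    def test_constant_lengths_estimate_exactly_zero(self):
        X = two_group_design(10)
        fit = fit_lmm(np.full(20, 155.0), X)
        assert fit.coefficients["treatment"] == pytest.approx(0.0, abs=1e-12)

    def test_known_shift_recovery(self):
        rng = np.random.default_rng(30)
        n = 250
        X = two_group_design(n)
        groups = np.tile(np.arange(5), 2 * n // 5)
        y = 150 + 10 * X["treatment"].to_numpy() + rng.normal(0, 8, 2 * n) \
            + rng.normal(0, 4, 5)[groups]
        fit = fit_lmm(y, X, groups)
        assert abs(fit.coefficients["treatment"] - 10) < 3 * fit.standard_errors["treatment"]
        assert fit.statistic == "t"
        assert fit.df_resid == 2 * n - 2

    def test_single_group_matches_ols_exactly(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(31)
        X = two_group_design(30)
        y = 100 + 5 * X["treatment"].to_numpy() + rng.normal(0, 3, 60)
        fit = fit_lmm(y, X, group_labels=np.zeros(60, dtype=int))
        ols = sm.OLS(y, X).fit()
        assert fit.coefficients["treatment"] == pytest.approx(
            ols.params["treatment"], abs=1e-10
        )
        assert fit.standard_errors["treatment"] == pytest.approx(
            ols.bse["treatment"], abs=1e-10
        )


class TestCompareAic:
    def test_clear_winner_and_tie(self):
        a = _fake_fit(aic=100.0)
        b = _fake_fit(aic=103.0)
        assert compare_aic(a, b) == {"better": "a", "delta": -3.0}
        c = _fake_fit(aic=101.5)
        assert compare_aic(a, c)["better"] == "tie"

    def test_different_data_rejected(self):
        a = _fake_fit(aic=100.0)
        b = _fake_fit(aic=90.0, n_obs=99)
        with pytest.raises(InvalidInputError):
            compare_aic(a, b)

    def test_aic_margin_is_lrt_threshold_for_one_parameter(self):
        """Null vs treatment NB fits: AIC_null - AIC_trt = LRT - 2, so the
        2-unit margin is exactly an LRT > 4 rule."""
        rng = np.random.default_rng(33)
        n = 60
        X = two_group_design(n)
        Xi = X[["intercept"]]
        for _ in range(50):
            y = np.r_[nb_draw(rng, 2.0, 1.9, n), nb_draw(rng, 3.0, 1.9, n)]
            null = fit_nb_glm(y, Xi)
            trt = fit_nb_glm(y, X)
            lrt = 2 * (trt.log_likelihood - null.log_likelihood)
            assert null.aic - trt.aic == pytest.approx(lrt - 2, abs=1e-8)
            assert (compare_aic(trt, null)["better"] == "a") == (lrt > 4)


def _fake_fit(aic, n_obs=100):
    from paradetect.nb_models import ModelFit

    return ModelFit(
        coefficients={}, standard_errors={}, z_values={}, p_values={},
        log_likelihood=0.0, aic=aic, dispersion_k=1.0, n_obs=n_obs,
        converged=True, n_params=1,
    )
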