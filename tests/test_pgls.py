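"""Generalized least squares, lambda profiling, and BH adjustment."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from camophylo.pgls import (
    ModelSpec,
    RankDeficiencyError,
    bh_adjust,
    estimate_lambda,
    gls_fit,
    pgls,
    profile_loglik,
)
from camophylo.phylo import lambda_transform, phylo_covariance
from camophylo.synthetic_data import sim_bm_trait, sim_tree


def _design(n, k, rng):
    return np.column_stack([np.ones(n), rng.standard_normal((n, k))])


class TestGLS:
    def test_identity_covariance_reduces_to_ols(self, rng):
        X = _design(20, 2, rng)
        y = rng.standard_normal(20)
        fit = gls_fit(X, y, np.eye(20))
        ols = sm.OLS(y, X).fit()
        np.testing.assert_allclose(fit.beta, ols.params, atol=1e-10)
        np.testing.assert_allclose(fit.se, ols.bse, atol=1e-10)

    def test_matches_explicit_inverse_oracle(self, rng):
        tree = sim_tree(10, seed=4)
        V = phylo_covariance(tree).V
        X = _design(10, 2, rng)
        y = rng.standard_normal(10)
        fit = gls_fit(X, y, V)
        Vi = np.linalg.inv(V)
        beta = np.linalg.inv(X.T @ Vi @ X) @ X.T @ Vi @ y
        np.testing.assert_allclose(fit.beta, beta, atol=1e-8)

    def test_exact_linear_response(self, rng):
        X = _design(12, 1, rng)
        y = X @ np.array([1.0, 2.0])
        fit = gls_fit(X, y, np.eye(12))
        assert fit.sigma2 == pytest.approx(0.0, abs=1e-20)

    def test_collinear_design_rejected(self, rng):
        X = np.column_stack([np.ones(10), np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(RankDeficiencyError):
            gls_fit(X, np.random.default_rng(0).standard_normal(10), np.eye(10))


class TestLambdaEstimation:
    def test_optimizer_at_least_as_good_as_grid(self, rng):
        tree = sim_tree(30, seed=9)
        cov = phylo_covariance(tree)
        y = sim_bm_trait(cov, 0.7, 1.0, rng)
        X = np.ones((30, 1))
        lam, profile = estimate_lambda(X, y, cov)
        best = profile_loglik(X, y, cov, lam)
        assert best >= profile[:, 1].max() - 1e-6
        assert best >= profile_loglik(X, y, cov, 0.0) - 1e-10
        assert best >= profile_loglik(X, y, cov, 1.0) - 1e-10

    def test_iid_data_estimates_low_lambda(self):
        ests = []
        for s in range(30):
            r = np.random.default_rng(600 + s)
            tree = sim_tree(100, seed=700 + s)
            lam, _ = estimate_lambda(
                np.ones((100, 1)), r.standard_normal(100), tree
            )
            ests.append(lam)
        assert np.mean(ests) < 0.15

    def test_lambda_zero_matches_ols(self, rng):
        tree = sim_tree(15, seed=13)
        cov = phylo_covariance(tree)
        X = _design(15, 2, rng)
        y = rng.standard_normal(15)
        fit = gls_fit(X, y, lambda_transform(cov, 0.0).V)
        # lambda=0 is weighted OLS with tip-depth weights; on an
        # ultrametric tree depths are constant so it IS plain OLS
        ols = sm.OLS(y, X).fit()
        np.testing.assert_allclose(fit.beta, ols.params, atol=1e-10)


class TestPGLSModel:
    @pytest.fixture()
    def study(self):
        from camophylo.synthetic_data import SimConfig, sim_study_traits

        table, tree = sim_study_traits(SimConfig(seed=21))
        females = table[table.sex == "F"].set_index("taxon")
        return females, tree

    def test_study_degrees_of_freedom(self, study):
        females, tree = study
        spec = ModelSpec("brightness", ("bg_brightness", "PDT", "PWT"))
        fit = pgls(females, spec, tree)
        assert (fit.df_model, fit.df_residual) == (3, 13)
        assert fit.n == 17
        assert 0.0 <= fit.lambda_hat <= 1.0
        assert 0.0 <= fit.multiple_r2 <= 1.0

    def test_fixed_lambda_matches_direct_gls(self, study):
        females, tree = study
        spec = ModelSpec("saturation", ("bg_saturation", "PDT", "PWT"))
        fit = pgls(females, spec, tree, fixed_lambda=0.4)
        cov = phylo_covariance(tree)
        data = np.log(
            females.loc[
                tree.tip_names, ["saturation", "bg_saturation", "PDT", "PWT"]
            ].astype(float)
        )
        X = np.column_stack([np.ones(17), data.iloc[:, 1:].to_numpy()])
        direct = gls_fit(X, data.iloc[:, 0].to_numpy(),
                         lambda_transform(cov, 0.4).V)
        got = [t.coefficient for t in fit.terms]
        np.testing.assert_allclose(got, direct.beta[1:], atol=1e-10)

    def test_nonpositive_value_under_ln_names_offender(self, study):
        females, tree = study
        females = females.copy()
        bad_taxon = females.index[3]
        females.loc[bad_taxon, "hue1"] = -1.0
        spec = ModelSpec("hue1", ("bg_hue1", "PDT", "PWT"))
        with pytest.raises(ValueError, match=str(bad_taxon)):
            pgls(females, spec, tree)

    def test_slope_recovery_with_low_noise(self, study):
        # generated with unit animal-on-background slope; the fitted
        # coefficient should be near 1
        females, tree = study
        spec = ModelSpec("brightness", ("bg_brightness", "PDT", "PWT"))
        fit = pgls(females, spec, tree)
        coef = fit.terms[0]
        assert abs(coef.coefficient - 1.0) < 3 * coef.standard_error


def _bh_oracle(p):
    """Direct step-up computation, independent of the implementation."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    out = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        out[i] = running
    return out


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_oracle_and_bounds(self, seed):
        p = np.random.default_rng(seed).uniform(0, 1, 12)
        adj = bh_adjust(p)
        np.testing.assert_allclose(adj, _bh_oracle(p), atol=1e-12)
        assert np.all(adj >= p - 1e-12) and np.all(adj <= 1.0)

    def test_permutation_invariance(self, rng):
        p = rng.uniform(0, 1, 9)
        perm = rng.permutation(9)
        np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])
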