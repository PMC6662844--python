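"""Regression kernels against closed forms and independent oracles."""

import numpy as np
import pytest

from foragetails import (
    fit_ols,
    fit_poisson,
    fit_quantile,
    fit_random_intercept,
    fit_two_group_poisson,
    pinball_loss,
    semantic_path_distances,
    summarize_child,
    euclidean_path_distances,
)
from foragetails.regression import ConvergenceError, DesignError, _solve_pinball

from conftest import make_semantic_path, make_visual_path


def design_with_intercept(x):
    x = np.asarray(x, dtype=float)
    return {"intercept": np.ones_like(x), "x": x}


class TestSummarizeChild:
    def test_repetition_pattern(self, toy_table):
        path = make_semantic_path(["dog", "dog", "cat"])
        s = semantic_path_distances(path, toy_table)
        cs = summarize_child(s, path)
        assert (cs.n_items, cs.n_unique, cs.immediate_repetitions) == (3, 2, 1)
        assert cs.mean_distance == pytest.approx(np.mean([0.0, 0.71]), abs=1e-6)

    def test_single_event_flagged_degenerate(self, toy_table):
        path = make_semantic_path(["dog"])
        with pytest.warns(UserWarning):
            s = semantic_path_distances(path, toy_table)
        cs = summarize_child(s, path)
        assert cs.n_items == 1 and cs.degenerate

    def test_moments_match_two_pass_oracle(self, rng):
        pts = rng.uniform(0, 200, size=(51, 2))
        path = make_visual_path(pts)
        cs = summarize_child(euclidean_path_distances(path), path)
        d = np.hypot(*np.diff(pts, axis=0).T)
        mean = sum(d) / len(d)
        sd = np.sqrt(sum((x - mean) ** 2 for x in d) / (len(d) - 1))
        assert cs.mean_distance == pytest.approx(mean, abs=1e-12)
        assert cs.sd_distance == pytest.approx(sd, abs=1e-12)


class TestPoisson:
    def test_two_group_closed_form(self):
        # group means 2 and 4: slope must be ln 2
        y = [2, 2, 2, 4, 4, 4]
        g = [0, 0, 0, 1, 1, 1]
        fit = fit_poisson(y, design_with_intercept(g))
        assert fit.coefficients["x"] == pytest.approx(np.log(2), abs=1e-10)
        closed = fit_two_group_poisson(y, g)
        assert closed.coefficients["group"] == pytest.approx(fit.coefficients["x"], abs=1e-10)
        assert closed.standard_errors["group"] == pytest.approx(
            fit.standard_errors["x"], rel=1e-8
        )

    def test_constant_counts_zero_slope(self):
        fit = fit_poisson([3] * 8, design_with_intercept([0, 1] * 4))
        assert fit.coefficients["x"] == pytest.approx(0.0, abs=1e-12)

    def test_irls_beats_grid_oracle(self, rng):
        x = rng.uniform(0, 2, 30)
        y = rng.poisson(np.exp(0.5 + 0.8 * x))
        fit = fit_poisson(y, design_with_intercept(x))

        def loglik(b0, b1):
            eta = b0 + b1 * x
            return np.sum(y * eta - np.exp(eta))

        best = fit.coefficients
        ll_hat = loglik(best["intercept"], best["x"])
        grid = [
            loglik(b0, b1)
            for b0 in np.linspace(-1, 2, 40)
            for b1 in np.linspace(-1, 2, 40)
        ]
        assert ll_hat >= max(grid) - 1e-9

    def test_matches_statsmodels_glm(self, rng):
        import statsmodels.api as sm

        x = rng.uniform(0, 3, 50)
        y = rng.poisson(np.exp(0.2 + 0.5 * x))
        fit = fit_poisson(y, design_with_intercept(x))
        X = np.column_stack([np.ones_like(x), x])
        ref = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        np.testing.assert_allclose(
            [fit.coefficients["intercept"], fit.coefficients["x"]], ref.params, rtol=1e-7
        )
        np.testing.assert_allclose(
            [fit.standard_errors["intercept"], fit.standard_errors["x"]], ref.bse, rtol=1e-4
        )

    def test_slope_error_shrinks_with_n(self):
        # consistency of the MLE at a known (b0, b1): the RMSE of the
        # slope estimate must shrink as n grows
        b0, b1 = 0.3, 0.6
        rmse = {}
        for n in (50, 500):
            rng = np.random.default_rng(99)
            est = []
            for _ in range(40):
                x = rng.uniform(0, 2, n)
                y = rng.poisson(np.exp(b0 + b1 * x))
                est.append(fit_poisson(y, design_with_intercept(x)).coefficients["x"])
            rmse[n] = np.sqrt(np.mean((np.array(est) - b1) ** 2))
        assert rmse[500] < rmse[50]

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError, match="non-negative integers"):
            fit_poisson([1.5, 2], design_with_intercept([0, 1]))
        with pytest.raises(ValueError, match="non-negative integers"):
            fit_poisson([-1, 2], design_with_intercept([0, 1]))

    def test_offset_changes_intercept_only(self):
        y = [4, 4, 8, 8]
        off = np.log([2.0, 2.0, 2.0, 2.0])
        fit = fit_poisson(y, design_with_intercept([0, 0, 1, 1]), offset=off)
        assert fit.coefficients["intercept"] == pytest.approx(np.log(2), abs=1e-9)
        assert fit.coefficients["x"] == pytest.approx(np.log(2), abs=1e-9)


class TestOLS:
    def test_exact_linear_data(self):
        x = np.arange(10.0)
        fit = fit_ols(3.0 + 2.0 * x, design_with_intercept(x))
        assert fit.coefficients["x"] == pytest.approx(2.0, abs=1e-10)
        assert fit.coefficients["intercept"] == pytest.approx(3.0, abs=1e-10)

    def test_constant_response_zero_slope(self):
        fit = fit_ols([5.0] * 9, design_with_intercept(np.arange(9.0)))
        assert fit.coefficients["x"] == pytest.approx(0.0, abs=1e-12)

    def test_normal_equation_oracle(self, rng):
        x = rng.normal(size=40)
        y = 1.0 + 0.7 * x + rng.normal(size=40)
        fit = fit_ols(y, design_with_intercept(x))
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(
            [fit.coefficients["intercept"], fit.coefficients["x"]], beta, atol=1e-10
        )

    def test_collinear_design_names_columns(self):
        x = np.arange(6.0)
        with pytest.raises(DesignError, match=r"collinear columns: \['x2?'\]"):
            fit_ols(x, {"intercept": np.ones(6), "x": x, "x2": 2 * x})

    def test_pvalues_invariant_to_column_order(self, rng):
        x1, x2 = rng.normal(size=30), rng.normal(size=30)
        y = x1 - x2 + rng.normal(size=30)
        a = fit_ols(y, {"intercept": np.ones(30), "x1": x1, "x2": x2})
        b = fit_ols(y, {"x2": x2, "intercept": np.ones(30), "x1": x1})
        for k in a.p_values:
            assert a.p_values[k] == pytest.approx(b.p_values[k], rel=1e-9)


class TestRandomIntercept:
    def test_zero_between_variance_reduces_to_ols(self, rng):
        ids = np.repeat(np.arange(10), 6)
        x = rng.normal(size=60)
        e = rng.normal(size=60)
        # remove all between-cluster variation so REML hits the 0 boundary
        for c in range(10):
            e[ids == c] -= e[ids == c].mean()
        y = 2.0 + 1.5 * x + e
        with pytest.warns(UserWarning, match="boundary"):
            fit = fit_random_intercept(y, x, ids)
        ols = fit_ols(y, design_with_intercept(x))
        assert fit.coefficients["x"] == pytest.approx(ols.coefficients["x"], abs=1e-10)
        assert "ols" in fit.model_tag

    def test_balanced_opposite_intercepts_recover_slope_exactly(self):
        x = np.tile(np.arange(8.0), 2)
        y = np.concatenate([1.0 + 2.0 * x[:8], -1.0 + 2.0 * x[8:]])
        ids = np.repeat([0, 1], 8)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_random_intercept(y, x, ids)
        assert fit.coefficients["x"] == pytest.approx(2.0, abs=1e-8)

    def test_singleton_clusters_equal_ols(self, rng):
        x = rng.normal(size=20)
        y = 0.5 * x + rng.normal(size=20)
        with pytest.warns(UserWarning, match="singleton"):
            fit = fit_random_intercept(y, x, np.arange(20))
        ols = fit_ols(y, design_with_intercept(x))
        assert fit.coefficients["x"] == pytest.approx(ols.coefficients["x"], abs=1e-12)

    def test_reml_objective_beats_variance_ratio_grid(self, rng):
        # oracle: profile restricted log-likelihood over the variance ratio
        n_clusters, m = 20, 15
        ids = np.repeat(np.arange(n_clusters), m)
        x = rng.uniform(0, 1, n_clusters * m)
        u = rng.normal(0, 0.8, n_clusters)
        y = 1.0 + 2.0 * x + u[ids] + rng.normal(0, 1.0, n_clusters * m)
        fit = fit_random_intercept(y, x, ids)
        lam_hat = fit.extra["var_between"] / fit.extra["var_residual"]

        X = np.column_stack([np.ones_like(x), x])
        n, p = X.shape

        def restricted_ll(lam):
            # V_i = I + lam * 1 1' per cluster; GLS profile of beta and sigma^2
            XtVX = np.zeros((p, p))
            XtVy = np.zeros(p)
            logdet = 0.0
            for c in range(n_clusters):
                idx = ids == c
                Xi, yi = X[idx], y[idx]
                Vi = np.eye(m) + lam * np.ones((m, m))
                Vinv = np.linalg.inv(Vi)
                XtVX += Xi.T @ Vinv @ Xi
                XtVy += Xi.T @ Vinv @ yi
                logdet += np.linalg.slogdet(Vi)[1]
            beta = np.linalg.solve(XtVX, XtVy)
            rss = 0.0
            for c in range(n_clusters):
                idx = ids == c
                r = y[idx] - X[idx] @ beta
                rss += r @ np.linalg.inv(np.eye(m) + lam * np.ones((m, m))) @ r
            s2 = rss / (n - p)
            return -0.5 * (
                (n - p) * np.log(s2) + logdet + np.linalg.slogdet(XtVX / s2)[1] + (n - p)
            )

        ll_hat = restricted_ll(lam_hat)
        grid = [restricted_ll(lam) for lam in np.linspace(0.01, 3.0, 60)]
        assert ll_hat >= max(grid) - 1e-4

    def test_fewer_than_two_clusters_rejected(self):
        with pytest.raises(ValueError, match="2 clusters"):
            fit_random_intercept([1.0, 2.0], [0.0, 1.0], ["a", "a"])


class TestQuantile:
    def test_median_regression_intercept_only(self):
        y = np.array([3.0, 1.0, 7.0, 5.0, 9.0, 2.0, 8.0])
        ids = np.arange(7)
        fit = fit_quantile(y, {"intercept": np.ones(7)}, 0.5, ids, n_boot=5, seed=0)
        assert fit.coefficients["intercept"] == pytest.approx(np.median(y), abs=1e-9)

    def test_q90_on_1_to_10_within_minimizer_interval(self):
        y = np.arange(1.0, 11.0)
        fit = fit_quantile(y, {"intercept": np.ones(10)}, 0.9, np.arange(10), n_boot=2, seed=0)
        assert 9.0 - 1e-9 <= fit.coefficients["intercept"] <= 10.0 + 1e-9

    @pytest.mark.parametrize("q", [0.5, 0.8, 0.95])
    def test_beats_200x200_grid_oracle(self, q, rng):
        n = 60
        x = rng.uniform(0, 5, n)
        y = 2.0 + 1.2 * x + rng.standard_normal(n) * (1 + 0.3 * x)
        X = np.column_stack([np.ones(n), x])
        beta = _solve_pinball(y, X, q)
        loss = pinball_loss(y, X, beta, q)
        b0g = np.linspace(-2, 8, 200)
        b1g = np.linspace(-1, 3, 200)
        resid = y[None, None, :] - b0g[:, None, None] - b1g[None, :, None] * x[None, None, :]
        grid_loss = np.where(resid >= 0, q * resid, (q - 1) * resid).sum(axis=2)
        assert loss <= grid_loss.min() + 1e-8 * max(1.0, abs(grid_loss.min()))

    def test_scale_equivariance(self, rng):
        n = 40
        x = rng.uniform(0, 3, n)
        y = 1.0 + 0.5 * x + rng.standard_normal(n)
        ids = np.repeat(np.arange(8), 5)
        design = {"intercept": np.ones(n), "x": x}
        a = fit_quantile(y, design, 0.8, ids, n_boot=2, seed=3)
        b = fit_quantile(10.0 * y, design, 0.8, ids, n_boot=2, seed=3)
        for k in a.coefficients:
            assert b.coefficients[k] == pytest.approx(10.0 * a.coefficients[k], rel=1e-7, abs=1e-9)

    def test_matches_statsmodels_quantreg_loss(self, rng):
        import statsmodels.api as sm

        n = 80
        x = rng.uniform(0, 4, n)
        y = 1.0 + 0.8 * x + rng.standard_normal(n)
        X = np.column_stack([np.ones(n), x])
        ours = _solve_pinball(y, X, 0.75)
        ref = sm.QuantReg(y, X).fit(q=0.75)
        assert pinball_loss(y, X, ours, 0.75) <= pinball_loss(y, X, ref.params, 0.75) + 1e-8

    def test_bad_level_and_too_few_clusters(self):
        y = np.arange(6.0)
        d = {"intercept": np.ones(6)}
        with pytest.raises(ValueError, match=r"\(0, 1\)"):
            fit_quantile(y, d, 1.5, np.arange(6))
        with pytest.raises(ValueError, match="3 clusters"):
            fit_quantile(y, d, 0.5, np.repeat([0, 1], 3))

    def test_cluster_bootstrap_seed_reproducible(self, rng):
        n = 50
        x = rng.uniform(size=n)
        y = x + rng.standard_normal(n)
        ids = np.repeat(np.arange(10), 5)
        d = {"intercept": np.ones(n), "x": x}
        a = fit_quantile(y, d, 0.7, ids, n_boot=20, seed=11)
        b = fit_quantile(y, d, 0.7, ids, n_boot=20, seed=11)
        assert a.standard_errors == b.standard_errors
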