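"""Fisher-scoring engine, weighted cross-product and spectral diagnostics."""

import numpy as np
import pytest
from scipy.optimize import minimize

from pklreg import (
    CountDataset,
    FitError,
    condition_number,
    fit_pmle,
    poisson_loglik,
    spectral,
    weighted_crossproduct,
)
from conftest import random_count_dataset


def optimize_loglik_directly(data, x0=None):
    """Independent oracle: generic BFGS maximization of the log-likelihood."""
    X, y = data.X, data.y
    x0 = np.zeros(X.shape[1]) if x0 is None else x0
    res = minimize(
        lambda b: -poisson_loglik(b, X, y),
        x0,
        jac=lambda b: -(X.T @ (y - np.exp(X @ b))),
        method="BFGS",
        options={"gtol": 1e-10, "maxiter": 500},
    )
    return res.x


class TestFitPmle:
    def test_intercept_only_closed_form(self):
        """Intercept-only MLE is ln(ybar) in closed form."""
        data = CountDataset(np.ones((3, 1)), np.array([1, 2, 3]))
        fit = fit_pmle(data)
        assert fit.converged
        assert fit.beta_hat[0] == pytest.approx(np.log(2.0), abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("convention", ["mu", "mu_squared"])
    def test_matches_generic_optimizer(self, seed, convention):
        """IRLS coefficients agree with a direct likelihood maximizer."""
        rng = np.random.default_rng(seed)
        data, _ = random_count_dataset(rng)
        fit = fit_pmle(data, weight_convention=convention)
        assert fit.converged
        oracle = optimize_loglik_directly(data, x0=fit.beta_hat * 0.0)
        np.testing.assert_allclose(fit.beta_hat, oracle, atol=1e-6)

    def test_weight_conventions_same_mle(self, rng):
        """Both scoring metrics converge to the same maximum-likelihood point."""
        data, _ = random_count_dataset(rng)
        f1 = fit_pmle(data, weight_convention="mu")
        f2 = fit_pmle(data, weight_convention="mu_squared")
        np.testing.assert_allclose(f1.beta_hat, f2.beta_hat, atol=1e-7)

    def test_consistency_on_noiseless_rounded_response(self, rng):
        """y = round(exp(X beta0)) at large counts recovers beta0 closely."""
        n = 200
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        beta0 = np.array([3.0, 0.5])
        y = np.round(np.exp(X @ beta0))
        fit = fit_pmle(CountDataset(X, y))
        np.testing.assert_allclose(fit.beta_hat, beta0, atol=0.01)

    def test_statsmodels_cross_check(self, rng):
        """Coefficients agree with statsmodels' independent GLM implementation."""
        sm = pytest.importorskip("statsmodels.api")
        data, _ = random_count_dataset(rng)
        fit = fit_pmle(data)
        ref = sm.GLM(data.y, data.X, family=sm.families.Poisson()).fit()
        np.testing.assert_allclose(fit.beta_hat, ref.params, atol=1e-6)

    def test_normal_equations_hold_at_convergence(self, fitted):
        """Converged beta satisfies (X'WX)^{-1} X'W z = beta at the final weights."""
        data, fit, _ = fitted
        X = data.X
        G = (X * fit.w_diag[:, None]).T @ X
        rhs = (X * fit.w_diag[:, None]).T @ fit.z_hat
        np.testing.assert_allclose(np.linalg.solve(G, rhs), fit.beta_hat, atol=1e-8)

    def test_likelihood_ascent(self, rng):
        """Log-likelihood is non-decreasing across scoring iterations."""
        data, _ = random_count_dataset(rng, n=30)
        fit = fit_pmle(data)
        lls = [st.loglik for st in fit.history]
        assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))

    def test_invariants_of_fit(self, fitted):
        data, fit, _ = fitted
        np.testing.assert_allclose(fit.mu_hat, np.exp(fit.eta_hat), rtol=1e-12)
        np.testing.assert_allclose(fit.eta_hat, data.X @ fit.beta_hat, atol=1e-12)
        assert np.all(fit.mu_hat > 0)
        score = data.X.T @ (data.y - fit.mu_hat)
        assert np.max(np.abs(score)) < 1e-6

    def test_all_zero_response_rejected(self):
        data = CountDataset(np.column_stack([np.ones(5), np.arange(5.0)]), np.zeros(5))
        with pytest.raises(FitError, match="identically zero"):
            fit_pmle(data)

    def test_nonconvergence_flagged_with_last_state(self, rng):
        data, _ = random_count_dataset(rng)
        fit = fit_pmle(data, max_iter=1)
        assert not fit.converged
        assert fit.n_iter == 1
        assert fit.beta_hat.shape == (data.p + 1,)


class TestCountDataset:
    def test_rejects_negative_and_noninteger_y(self):
        X = np.column_stack([np.ones(4), np.arange(4.0)])
        with pytest.raises(ValueError, match="non-negative"):
            CountDataset(X, np.array([1, -1, 2, 0]))
        with pytest.raises(ValueError, match="non-negative"):
            CountDataset(X, np.array([1.0, 2.5, 2.0, 0.0]))

    def test_rejects_missing_intercept_and_rank_deficiency(self):
        with pytest.raises(ValueError, match="intercept"):
            CountDataset(np.arange(8.0).reshape(4, 2), np.ones(4))
        X = np.column_stack([np.ones(5), np.arange(5.0), 2 * np.arange(5.0)])
        with pytest.raises(ValueError, match="rank"):
            CountDataset(X, np.ones(5))


class TestCrossProductAndSpectrum:
    def test_single_element_product(self):
        """n=1 conceptual check via a tiny fit: G entries equal sum w_i x_i x_i'."""
        rng = np.random.default_rng(3)
        data, _ = random_count_dataset(rng, n=25, p=2)
        fit = fit_pmle(data)
        G = weighted_crossproduct(data, fit)
        brute = sum(w * np.outer(x, x) for w, x in zip(fit.w_diag, data.X))
        np.testing.assert_allclose(G, brute, atol=1e-10)
        assert np.allclose(G, G.T)

    def test_trace_inverse_equals_sum_reciprocal_eigenvalues(self, fitted):
        """tr((X'WX)^{-1}) = sum_i 1/lambda_i, the MLE risk identity."""
        _, fit, spec = fitted
        np.testing.assert_allclose(
            np.trace(np.linalg.inv(spec.G)), np.sum(1.0 / spec.lambdas), atol=1e-10
        )

    def test_diagonal_matrix_spectrum(self, fitted):
        _, fit, _ = fitted
        spec = spectral(np.diag([4.0, 1.0, 0.5, 0.2]), fit)
        np.testing.assert_allclose(spec.lambdas, [4.0, 1.0, 0.5, 0.2])
        np.testing.assert_allclose(np.abs(spec.Q), np.eye(4), atol=1e-12)

    def test_spectrum_invariants_random_spd(self, fitted, rng):
        """Orthogonality, reconstruction and alpha round-trip on random SPD matrices."""
        _, fit, _ = fitted
        for _ in range(10):
            A = rng.standard_normal((4, 4))
            G = A @ A.T + 4 * np.eye(4)
            spec = spectral(G, fit)
            np.testing.assert_allclose(spec.Q.T @ spec.Q, np.eye(4), atol=1e-10)
            np.testing.assert_allclose(
                spec.Q @ np.diag(spec.lambdas) @ spec.Q.T, G, atol=1e-8
            )
            assert np.all(np.diff(spec.lambdas) <= 1e-12)
            np.testing.assert_allclose(spec.Q @ spec.alpha_hat, fit.beta_hat, atol=1e-12)

    def test_sign_convention_reproducible(self, fitted):
        """Largest-magnitude entry of each eigenvector is positive."""
        _, _, spec = fitted
        idx = np.argmax(np.abs(spec.Q), axis=0)
        assert np.all(spec.Q[idx, np.arange(spec.Q.shape[1])] > 0)


class TestConditionNumber:
    @pytest.mark.parametrize(
        "lams, expected",
        [
            ((100.0, 1.0), 10.0),
            ((7.0, 7.0, 7.0), 1.0),
            ((2085.2251, 374.8961, 4.3333), np.sqrt(2085.2251 / 4.3333)),
        ],
    )
    def test_values(self, lams, expected):
        assert condition_number(np.array(lams)) == pytest.approx(expected, rel=1e-12)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            condition_number(np.array([1.0, 0.0]))
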