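"""Poisson log-linear model fitting by Fisher scoring.

The Poisson regression model assumes counts y_i ~ Poisson(mu_i) with
log link, mu_i = exp(x_i' beta).  Fisher scoring (equivalently IRLS for
the canonical log link) maximizes the log-likelihood

    l(beta) = sum_i [ y_i * eta_i - mu_i - ln(y_i!) ],   eta_i = x_i' beta.

Every shrinkage estimator in this package is built on top of the converged
maximum-likelihood fit: the weighted cross-product G = X' W_hat X, its
eigendecomposition G = Q Lambda Q', and the canonical coefficients
alpha_hat = Q' beta_hat.  Under collinearity the smallest eigenvalues of G
collapse toward zero and the MLE variance sum(1/lambda_i) explodes; the
condition number sqrt(lambda_max / lambda_min) diagnoses this.

Two weight conventions are supported.  The canonical Fisher-scoring weights
for the log link are W = diag(mu_i) with working response
z = eta + (y - mu)/mu.  The alternative convention W = diag(mu_i^2),
z = eta + (y - mu)/mu^2 appears in parts of the shrinkage literature; both
share the same score X'(y - mu) and hence the same MLE, but they induce
different weighted cross-products and therefore different shrinkage spectra.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

logger = logging.getLogger(__name__)

__all__ = [
    "CountDataset",
    "PoissonFit",
    "IterationState",
    "Spectrum",
    "FitError",
    "fit_pmle",
    "poisson_loglik",
    "weighted_crossproduct",
    "spectral",
    "condition_number",
]

WEIGHT_CONVENTIONS = ("mu", "mu_squared")


class FitError(RuntimeError):
    """Raised when the maximum-likelihood fit cannot be computed."""


@dataclass
class CountDataset:
    """Design matrix with intercept column plus integer count response.

    Parameters
    ----------
    X : (n, p+1) ndarray
        Design matrix whose first column is the constant 1.
    y : (n,) ndarray
        Non-negative integer counts.
    names : list of str, optional
        Labels for the non-intercept regressors.
    """

    X: np.ndarray
    y: np.ndarray
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-d array")
        n, m = self.X.shape
        if y.shape != (n,):
            raise ValueError(f"y has shape {y.shape}, expected ({n},)")
        if not np.allclose(self.X[:, 0], 1.0):
            raise ValueError("first column of X must be the constant 1 (intercept)")
        if np.any(y < 0) or not np.allclose(y, np.round(y)):
            bad = np.nonzero((y < 0) | ~np.isclose(y, np.round(y)))[0]
            raise ValueError(f"y must be non-negative integers; offending rows: {bad.tolist()}")
        self.y = np.round(y).astype(float)
        if n <= m:
            raise ValueError(f"need n > p+1 (got n={n}, p+1={m})")
        rank = np.linalg.matrix_rank(self.X)
        if rank < m:
            raise ValueError(f"X is rank deficient (rank {rank} < {m} columns)")
        if not self.names:
            self.names = [f"x{j}" for j in range(1, m)]
        elif len(self.names) != m - 1:
            raise ValueError("names must label the non-intercept columns")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        """Number of regressors, excluding the intercept."""
        return self.X.shape[1] - 1


@dataclass
class IterationState:
    """Score, expected information and step size at one scoring iteration."""

    score: np.ndarray
    information: np.ndarray
    step_norm: float
    loglik: float = float("nan")


@dataclass
class PoissonFit:
    """Converged (or last-attempted) maximum-likelihood state."""

    beta_hat: np.ndarray
    mu_hat: np.ndarray
    eta_hat: np.ndarray
    w_diag: np.ndarray
    z_hat: np.ndarray
    converged: bool
    n_iter: int
    loglik: float
    weight_convention: str = "mu"
    history: list[IterationState] = field(default_factory=list, repr=False)


@dataclass
class Spectrum:
    """Eigendecomposition of the weighted cross-product G = X' W X.

    ``lambdas`` are sorted descending; columns of ``Q`` match.  The
    canonical coefficients ``alpha_hat = Q' beta_hat`` diagonalize every
    shrinkage operator in this package.
    """

    G: np.ndarray
    lambdas: np.ndarray
    Q: np.ndarray
    alpha_hat: np.ndarray


def poisson_loglik(beta: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    """Poisson log-likelihood at ``beta`` (including the ln y! constant)."""
    eta = X @ beta
    with np.errstate(over="ignore"):
        mu = np.exp(eta)
    return float(np.sum(y * eta - mu - gammaln(y + 1.0)))


def _weights_and_working_response(
    eta: np.ndarray, mu: np.ndarray, y: np.ndarray, convention: str
) -> tuple[np.ndarray, np.ndarray]:
    if convention == "mu":
        w = mu
        z = eta + (y - mu) / mu
    elif convention == "mu_squared":
        w = mu**2
        z = eta + (y - mu) / mu**2
    else:
        raise ValueError(f"unknown weight_convention {convention!r}; use one of {WEIGHT_CONVENTIONS}")
    return w, z


def fit_pmle(
    data: CountDataset,
    tol: float = 1e-8,
    max_iter: int = 100,
    score_tol: float = 1e-6,
    weight_convention: str = "mu",
) -> PoissonFit:
    """Fit the Poisson log-linear model by Fisher scoring.

    Iterates beta <- beta + I(beta)^{-1} S(beta) with the expected
    information I = X' W X and score S = X'(y - mu), using step-halving
    whenever a full step would decrease the log-likelihood.  Starting
    values come from an OLS regression of ln(y + 0.5) on X.

    Parameters
    ----------
    data : CountDataset
    tol : float
        Sup-norm tolerance on the coefficient update.
    max_iter : int
        Maximum number of scoring iterations.
    score_tol : float
        Convergence additionally requires the score sup-norm below this.
    weight_convention : {"mu", "mu_squared"}
        Weight matrix used for the scoring metric and the cross-product
        reported in the fit.  The MLE is the same under both.

    Returns
    -------
    PoissonFit
        ``converged`` is False if the iteration budget was exhausted; the
        last state is still returned so callers can inspect it.

    Raises
    ------
    FitError
        If the response is identically zero (the intercept MLE diverges)
        or the information matrix becomes numerically singular.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if weight_convention not in WEIGHT_CONVENTIONS:
        raise ValueError(f"unknown weight_convention {weight_convention!r}")
    X, y = data.X, data.y
    if np.all(y == 0):
        raise FitError("y is identically zero: the Poisson MLE diverges (intercept -> -inf)")

    # OLS of ln(y + 0.5) on X: robust deterministic start.
    beta = np.linalg.lstsq(X, np.log(y + 0.5), rcond=None)[0]
    ll = poisson_loglik(beta, X, y)
    history: list[IterationState] = []
    converged = False
    n_iter = 0

    # The iteration always uses the canonical Newton/Fisher metric diag(mu):
    # both conventions share the score X'(y - mu) and hence the same MLE, and
    # the canonical metric gives quadratic convergence.  The requested
    # convention applies to the reported final weights and cross-product.
    for n_iter in range(1, max_iter + 1):
        eta = X @ beta
        mu = np.exp(np.clip(eta, -700, 700))
        w = mu
        score = X.T @ (y - mu)
        info = (X * w[:, None]).T @ X
        cond = np.linalg.cond(info)
        if not np.isfinite(cond) or cond > 1e15:
            raise FitError(
                f"information matrix numerically singular at iteration {n_iter} "
                f"(condition number {cond:.3e})"
            )
        step = np.linalg.solve(info, score)

        # Step-halving: retreat until the log-likelihood does not decrease.
        scale = 1.0
        for _ in range(20):
            ll_new = poisson_loglik(beta + scale * step, X, y)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step
        ll = poisson_loglik(beta, X, y)
        step_norm = float(np.max(np.abs(scale * step)))
        history.append(IterationState(score=score, information=info, step_norm=step_norm, loglik=ll))
        logger.debug("iter %d: loglik=%.10g step_norm=%.3e", n_iter, ll, step_norm)
        if step_norm < tol and np.max(np.abs(score)) < score_tol:
            converged = True
            break

    eta = X @ beta
    mu = np.exp(np.clip(eta, -700, 700))
    w, z = _weights_and_working_response(eta, mu, y, weight_convention)
    if not converged:
        logger.warning("fit_pmle did not converge in %d iterations", max_iter)
    return PoissonFit(
        beta_hat=beta,
        mu_hat=mu,
        eta_hat=eta,
        w_diag=w,
        z_hat=z,
        converged=converged,
        n_iter=n_iter,
        loglik=ll,
        weight_convention=weight_convention,
        history=history,
    )


def weighted_crossproduct(data: CountDataset, fit: PoissonFit) -> np.ndarray:
    """Weighted cross-product G = X' W_hat X at the fitted weights.

    G is the expected information at the MLE; its inverse is the asymptotic
    covariance of beta_hat.
    """
    if not fit.converged:
        raise FitError("fit did not converge; cross-product undefined")
    X = data.X
    G = (X * fit.w_diag[:, None]).T @ X
    G = 0.5 * (G + G.T)
    min_eig = float(np.linalg.eigvalsh(G)[0])
    if min_eig <= 0:
        raise FitError(f"X'WX is not positive definite (smallest eigenvalue {min_eig:.3e})")
    return G


def spectral(G: np.ndarray, fit: PoissonFit, eig_floor: float = 1e-10) -> Spectrum:
    """Eigendecomposition of G with a reproducible sign convention.

    Eigenvalues are sorted descending; each eigenvector is flipped so its
    largest-magnitude entry is positive, making alpha_hat reproducible
    across linear-algebra backends.  An eigenvalue below ``eig_floor``
    triggers a warning (severe ill-conditioning) but not a failure.
    """
    G = np.asarray(G, dtype=float)
    lam, Q = np.linalg.eigh(0.5 * (G + G.T))
    order = np.argsort(lam)[::-1]
    lam, Q = lam[order], Q[:, order]
    if lam[-1] <= 0:
        raise FitError(f"G is not positive definite (smallest eigenvalue {lam[-1]:.3e})")
    if lam[-1] < eig_floor:
        warnings.warn(
            f"smallest eigenvalue {lam[-1]:.3e} below {eig_floor:.1e}: severe ill-conditioning",
            RuntimeWarning,
            stacklevel=2,
        )
    # sign convention: largest-|entry| of each eigenvector positive
    idx = np.argmax(np.abs(Q), axis=0)
    signs = np.sign(Q[idx, np.arange(Q.shape[1])])
    signs[signs == 0] = 1.0
    Q = Q * signs
    alpha = Q.T @ fit.beta_hat
    return Spectrum(G=G, lambdas=lam, Q=Q, alpha_hat=alpha)


def condition_number(lambdas: np.ndarray) -> float:
    """Condition number sqrt(lambda_max / lambda_min) of X' W X.

    Values well above ~10 signal harmful collinearity.
    """
    lam = np.asarray(lambdas, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("all eigenvalues must be strictly positive")
    return float(np.sqrt(lam.max() / lam.min()))
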