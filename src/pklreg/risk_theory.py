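"""Closed-form risk of the shrinkage estimators and dominance conditions.

In canonical coordinates every estimator here is alpha -> A alpha with a
diagonal shrinkage matrix A = diag(a_i) and Cov(alpha_hat) = Lambda^{-1},
so the matrix mean squared error decomposes as

    MSEM = Q ( A Lambda^{-1} A' + b b' ) Q',      b = (A - I) alpha,

whose trace is the scalar risk

    MSE = sum_i a_i^2 / lambda_i  +  sum_i b_i^2
        =      variance           +   squared bias.

Shrinkage factors: a_i = 1 (MLE), lambda_i/(lambda_i+k) (ridge),
(lambda_i+d)/(lambda_i+1) (Liu), (lambda_i-k)/(lambda_i+k) (Kibria-Lukman).
For the Kibria-Lukman estimator the scalar risk is minimized coordinate-wise
at k = lambda_i / (1 + 2 lambda_i alpha_i^2), the basis of its selection
rules.  The dominance checks report both the analytic per-coordinate
sufficient conditions and an independent smallest-eigenvalue computation of
the MSEM difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RiskResult",
    "DominanceReport",
    "shrinkage_factors",
    "mse_pmle",
    "mse_prre",
    "mse_ple",
    "mse_pkle",
    "scalar_mse",
    "msem",
    "dominance_check",
]


@dataclass
class RiskResult:
    """Scalar and matrix risk of one estimator at one parameterization."""

    estimator: str
    param: float | None
    mse: float
    msem: np.ndarray | None
    bias_sq: float
    variance: float


@dataclass
class DominanceReport:
    """Per-coordinate sufficient-condition values and a numeric MSEM check."""

    versus: str
    condition_values: np.ndarray
    conditions_hold: bool
    msem_diff_min_eig: float
    dominates: bool


def _check_lambdas(lambdas: np.ndarray) -> np.ndarray:
    lam = np.asarray(lambdas, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("all eigenvalues must be strictly positive")
    return lam


def shrinkage_factors(estimator: str, lambdas: np.ndarray, param: float | None) -> np.ndarray:
    """Diagonal canonical shrinkage factors a_i for a named estimator."""
    lam = _check_lambdas(lambdas)
    name = estimator.upper()
    if name == "PMLE":
        return np.ones_like(lam)
    if name == "PRRE":
        if param is None or param < 0:
            raise ValueError("ridge k must be >= 0")
        return lam / (lam + param)
    if name == "PLE":
        if param is None or not 0.0 <= param <= 1.0:
            raise ValueError("Liu d must lie in [0, 1]")
        return (lam + param) / (lam + 1.0)
    if name in ("PKLE", "PKLE1", "PKLE2"):
        if param is None or param < 0:
            raise ValueError("Kibria-Lukman k must be >= 0")
        return (lam - param) / (lam + param)
    raise ValueError(f"unknown estimator {estimator!r}")


def _risk(estimator: str, lambdas: np.ndarray, alpha: np.ndarray | None,
          param: float | None, Q: np.ndarray | None = None) -> RiskResult:
    lam = _check_lambdas(lambdas)
    a = shrinkage_factors(estimator, lam, param)
    variance = float(np.sum(a**2 / lam))
    if alpha is None:
        alpha = np.zeros_like(lam)
    alpha = np.asarray(alpha, dtype=float)
    b = (a - 1.0) * alpha
    bias_sq = float(np.sum(b**2))
    M = None
    if Q is not None:
        core = np.diag(a**2 / lam) + np.outer(b, b)
        M = Q @ core @ Q.T
    return RiskResult(
        estimator=estimator.upper(), param=param, mse=variance + bias_sq,
        msem=M, bias_sq=bias_sq, variance=variance,
    )


def mse_pmle(lambdas: np.ndarray) -> float:
    """MLE risk sum_i 1/lambda_i (pure variance, zero bias)."""
    return float(np.sum(1.0 / _check_lambdas(lambdas)))


def mse_prre(lambdas: np.ndarray, alpha: np.ndarray, k: float) -> RiskResult:
    """Ridge risk: sum lambda/(lambda+k)^2 + k^2 sum alpha^2/(lambda+k)^2."""
    return _risk("PRRE", lambdas, alpha, k)


def mse_ple(lambdas: np.ndarray, alpha: np.ndarray, d: float) -> RiskResult:
    """Liu risk: sum (lambda+d)^2/(lambda(lambda+1)^2) + (d-1)^2 alpha^2/(lambda+1)^2."""
    return _risk("PLE", lambdas, alpha, d)


def mse_pkle(lambdas: np.ndarray, alpha: np.ndarray, k: float) -> RiskResult:
    """Kibria-Lukman risk: sum (lambda-k)^2/(lambda(lambda+k)^2) + 4k^2 alpha^2/(lambda+k)^2."""
    return _risk("PKLE", lambdas, alpha, k)


def scalar_mse(estimator: str, lambdas: np.ndarray, alpha: np.ndarray, param: float | None) -> float:
    """Scalar risk of any named estimator at (Lambda, alpha, param)."""
    return _risk(estimator, lambdas, alpha, param).mse


def msem(estimator: str, lambdas: np.ndarray, Q: np.ndarray, alpha: np.ndarray,
         param: float | None) -> RiskResult:
    """Matrix mean squared error Q (A Lambda^{-1} A' + b b') Q' in original coordinates.

    The trace of the returned matrix equals the matching scalar risk.
    """
    Q = np.asarray(Q, dtype=float)
    return _risk(estimator, lambdas, alpha, param, Q=Q)


def dominance_check(versus: str, lambdas: np.ndarray, alpha: np.ndarray,
                    k: float = 0.0, d: float = 0.0) -> DominanceReport:
    """Check whether the Kibria-Lukman estimator dominates a competitor.

    ``versus`` names the competitor: "pmle" (the MLE), "prre" (ridge at the
    same k), or "ple" (Liu with parameter d).  The report carries the
    per-coordinate analytic condition values (positive in every coordinate
    means the variance-part sufficient condition holds), and independently
    the smallest eigenvalue of the full MSEM difference
    MSEM(competitor) - MSEM(PKLE); ``dominates`` is True when that
    difference is positive definite, which accounts for the bias parts the
    sufficient conditions ignore.
    """
    lam = _check_lambdas(lambdas)
    alpha = np.asarray(alpha, dtype=float)
    Q = np.eye(lam.size)
    pkle = msem("PKLE", lam, Q, alpha, k)
    name = versus.lower()
    if name == "pmle":
        other = msem("PMLE", lam, Q, alpha, None)
        cond = lam * (lam + k) ** 2 - lam * (lam - k) ** 2
    elif name == "prre":
        other = msem("PRRE", lam, Q, alpha, k)
        cond = 2.0 * lam - k
    elif name == "ple":
        other = msem("PLE", lam, Q, alpha, d)
        cond = lam * (lam + k) ** 2 * (lam + d) ** 2 - lam * (lam + 1.0) ** 2 * (lam - k) ** 2
    else:
        raise ValueError(f"unknown competitor {versus!r}; use 'pmle', 'prre' or 'ple'")
    diff = other.msem - pkle.msem
    min_eig = float(np.linalg.eigvalsh(0.5 * (diff + diff.T))[0])
    return DominanceReport(
        versus=name,
        condition_values=cond,
        conditions_hold=bool(np.all(cond > 0)),
        msem_diff_min_eig=min_eig,
        dominates=min_eig > 0,
    )
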