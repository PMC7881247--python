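"""Shrinkage estimators for the collinear Poisson regression model.

All four estimators act on the canonical coefficients alpha_hat = Q' beta_hat
by a diagonal shrinkage factor f_i applied coordinate-wise:

    ridge (PRRE):        f_i = lambda_i / (lambda_i + k)
    Liu (PLE):           f_i = (lambda_i + d) / (lambda_i + 1),  0 <= d <= 1
    Kibria-Lukman (PKLE): f_i = (lambda_i - k) / (lambda_i + k)

The Kibria-Lukman factor shrinks strictly more than ridge for the same k
(and can cross zero when k > lambda_i), trading extra bias for a larger
variance reduction.  Data-driven rules pick the biasing parameter from the
fitted spectrum: the ridge rule k = 1/max_i(alpha_i^2), the Liu rule
d = max(0, min_i (alpha_i^2 - 1)/(1/lambda_i + alpha_i^2)), and for the
Kibria-Lukman estimator the per-coordinate risk minimizers
k_i = lambda_i / (1 + 2 lambda_i alpha_i^2), aggregated either as their
clamped minimum (k1) or its square root (k2).
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from .poisson_core import PoissonFit, Spectrum

__all__ = [
    "BiasingParams",
    "ShrinkageEstimate",
    "select_k_ridge",
    "select_d_liu",
    "k_kl_candidates",
    "select_k1",
    "select_k2",
    "select_biasing_params",
    "estimate_pmle",
    "estimate_prre",
    "estimate_ple",
    "estimate_pkle",
    "all_estimates",
]

ESTIMATOR_NAMES = ("PMLE", "PRRE", "PLE", "PKLE1", "PKLE2")


@dataclass
class BiasingParams:
    """All data-driven biasing parameters computed from one spectrum."""

    k_ridge: float
    d_liu: float
    k_candidates: np.ndarray
    k1: float
    k2: float


@dataclass
class ShrinkageEstimate:
    """A named estimator's biasing parameter and coefficient vector."""

    name: str
    param: float | None
    beta: np.ndarray
    alpha: np.ndarray


def select_k_ridge(spectrum: Spectrum) -> float:
    """Ridge biasing parameter k = 1 / max_i(alpha_i^2)."""
    a2 = spectrum.alpha_hat**2
    amax = float(np.max(a2))
    if amax == 0.0:
        raise ValueError("all canonical coefficients are zero: ridge k rule undefined")
    return 1.0 / amax


def select_d_liu(spectrum: Spectrum) -> float:
    """Liu parameter d = max(0, min_i (alpha_i^2 - 1)/(1/lambda_i + alpha_i^2)).

    Clamped into [0, 1]: the raw rule can exceed 1 for large alpha^2 lambda,
    while the Liu estimator is only defined for d in [0, 1].
    """
    lam = spectrum.lambdas
    a2 = spectrum.alpha_hat**2
    d = float(np.min((a2 - 1.0) / (1.0 / lam + a2)))
    return min(max(d, 0.0), 1.0)


def k_kl_candidates(spectrum: Spectrum) -> np.ndarray:
    """Per-coordinate risk-minimizing k_i = lambda_i / (1 + 2 lambda_i alpha_i^2)."""
    lam = spectrum.lambdas
    a2 = spectrum.alpha_hat**2
    return lam / (1.0 + 2.0 * lam * a2)


def select_k1(candidates: np.ndarray) -> float:
    """k1 = max(0, min over the per-coordinate candidates)."""
    return max(0.0, float(np.min(candidates)))


def select_k2(k1: float) -> float:
    """k2 = sqrt(k1)."""
    if k1 < 0:
        raise ValueError("k1 must be >= 0")
    return float(np.sqrt(k1))


def select_biasing_params(spectrum: Spectrum) -> BiasingParams:
    """Evaluate every selection rule on one fitted spectrum."""
    cand = k_kl_candidates(spectrum)
    k1 = select_k1(cand)
    return BiasingParams(
        k_ridge=select_k_ridge(spectrum),
        d_liu=select_d_liu(spectrum),
        k_candidates=cand,
        k1=k1,
        k2=select_k2(k1),
    )


def _assemble(name: str, param: float | None, spectrum: Spectrum, factors: np.ndarray) -> ShrinkageEstimate:
    alpha = factors * spectrum.alpha_hat
    return ShrinkageEstimate(name=name, param=param, beta=spectrum.Q @ alpha, alpha=alpha)


def estimate_pmle(fit: PoissonFit, spectrum: Spectrum) -> ShrinkageEstimate:
    """The unshrunken maximum-likelihood estimate, as a ShrinkageEstimate."""
    return _assemble("PMLE", None, spectrum, np.ones_like(spectrum.lambdas))


def estimate_prre(fit: PoissonFit, spectrum: Spectrum, k: float) -> ShrinkageEstimate:
    """Poisson ridge: alpha_i -> lambda_i/(lambda_i + k) * alpha_i."""
    if k < 0:
        raise ValueError("ridge k must be >= 0")
    lam = spectrum.lambdas
    return _assemble("PRRE", k, spectrum, lam / (lam + k))


def estimate_ple(fit: PoissonFit, spectrum: Spectrum, d: float) -> ShrinkageEstimate:
    """Poisson Liu: alpha_i -> (lambda_i + d)/(lambda_i + 1) * alpha_i."""
    if not 0.0 <= d <= 1.0:
        raise ValueError("Liu d must lie in [0, 1]")
    lam = spectrum.lambdas
    return _assemble("PLE", d, spectrum, (lam + d) / (lam + 1.0))


def estimate_pkle(fit: PoissonFit, spectrum: Spectrum, k: float, name: str = "PKLE") -> ShrinkageEstimate:
    """Kibria-Lukman: alpha_i -> (lambda_i - k)/(lambda_i + k) * alpha_i.

    Warns (but proceeds) when k >= min(lambda): the affected canonical
    coefficients flip sign.
    """
    if k < 0:
        raise ValueError("Kibria-Lukman k must be >= 0")
    lam = spectrum.lambdas
    if k > 0 and k >= lam[-1]:
        warnings.warn(
            f"k={k:.4g} >= smallest eigenvalue {lam[-1]:.4g}: "
            "some canonical coefficients change sign",
            RuntimeWarning,
            stacklevel=2,
        )
    return _assemble(name, k, spectrum, (lam - k) / (lam + k))


def all_estimates(fit: PoissonFit, spectrum: Spectrum) -> dict[str, ShrinkageEstimate]:
    """PMLE, PRRE, PLE, PKLE1 and PKLE2 with their data-driven parameters."""
    params = select_biasing_params(spectrum)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return {
            "PKLE1": estimate_pkle(fit, spectrum, params.k1, name="PKLE1"),
            "PKLE2": estimate_pkle(fit, spectrum, params.k2, name="PKLE2"),
            "PLE": estimate_ple(fit, spectrum, params.d_liu),
            "PRRE": estimate_prre(fit, spectrum, params.k_ridge),
            "PMLE": estimate_pmle(fit, spectrum),
        }
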