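"""The Liu estimator and its closed-form mean squared error.

For a chosen ``d`` in [0, 1] the canonical Liu coefficients are the
componentwise shrinkage

    alpha_liu_j = (lambda_j + d) / (lambda_j + 1) * alpha_hat_j,

equivalently ``beta_liu = (X'X + I)^-1 (X'X + d I) beta_ols`` in the original
coordinates.  ``d = 1`` recovers OLS exactly; smaller ``d`` trades bias for
variance, which pays off under multicollinearity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import OLSFit, SpectralForm

__all__ = ["LiuFit", "liu_fit", "mse_ols_analytic", "mse_liu_analytic"]


@dataclass
class LiuFit:
    """Liu-regression coefficients for one value of ``d``."""

    d: float
    alpha_liu: np.ndarray
    beta_liu: np.ndarray
    rule_name: str = "fixed"
    intercept_estimate: float | None = None


def liu_fit(
    fit: OLSFit,
    spec: SpectralForm,
    d: float,
    rule_name: str = "fixed",
    allow_out_of_range: bool = False,
) -> LiuFit:
    """Shrink an OLS fit by ``d``.

    ``d`` outside [0, 1] raises unless ``allow_out_of_range`` is set (the
    estimator is defined for 0 <= d <= 1; values outside are research use
    only).  When the OLS fit centered an intercept, the Liu intercept is
    recovered from the same centering means.
    """
    d = float(d)
    if not np.isfinite(d):
        raise ValueError("d must be finite")
    if not allow_out_of_range and not 0.0 <= d <= 1.0:
        raise ValueError(f"d = {d} is outside [0, 1]")
    lam = spec.eigenvalues
    alpha_liu = (lam + d) / (lam + 1.0) * spec.alpha_hat
    beta_liu = spec.D @ alpha_liu
    intercept = (
        float(fit.y_mean - fit.x_mean @ beta_liu) if fit.intercept_ is not None else None
    )
    return LiuFit(
        d=d,
        alpha_liu=alpha_liu,
        beta_liu=beta_liu,
        rule_name=rule_name,
        intercept_estimate=intercept,
    )


def mse_ols_analytic(eigenvalues: np.ndarray, sigma2: float) -> float:
    """Closed-form scalar MSE of OLS: ``sigma^2 * sum_j 1/lambda_j``."""
    lam = np.asarray(eigenvalues, dtype=float)
    if np.any(lam <= 0.0):
        raise ValueError("eigenvalues must be strictly positive")
    return float(sigma2 * np.sum(1.0 / lam))


def mse_liu_analytic(
    eigenvalues: np.ndarray,
    alpha_hat: np.ndarray,
    sigma2: float,
    d: float,
) -> float:
    """Closed-form scalar MSE of the Liu estimator at shrinkage ``d``:

        sigma^2 sum_j (lambda_j + d)^2 / (lambda_j (lambda_j + 1)^2)
        + (d - 1)^2 sum_j alpha_hat_j^2 / (lambda_j + 1)^2

    The bias term plugs in ``alpha_hat_j^2`` directly (no bias correction),
    which is the standard plug-in evaluation used for estimator comparison.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    a = np.asarray(alpha_hat, dtype=float)
    if lam.shape != a.shape:
        raise ValueError("eigenvalues and alpha_hat must have equal length")
    if np.any(lam <= 0.0):
        raise ValueError("eigenvalues must be strictly positive")
    var = sigma2 * np.sum((lam + d) ** 2 / (lam * (lam + 1.0) ** 2))
    bias = (d - 1.0) ** 2 * np.sum(a**2 / (lam + 1.0) ** 2)
    return float(var + bias)
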