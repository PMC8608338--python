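"""t-based 100(1-level)% mean prediction intervals for OLS and Liu fits.

At a new predictor point ``x0`` the mean-response interval is

    OLS:  x0' beta_hat  +-  t_{1-a/2, v} * sqrt(s2 * x0' (X'X)^-1 x0)
    Liu:  x0' beta_liu  +-  t_{1-a/2, v} * sqrt(s2 * x0' Q_d (X'X)^-1 Q_d' x0)

with ``Q_d = (X'X + I)^-1 (X'X + d I)`` and ``v`` the residual degrees of
freedom (``n - p``, or ``n - p - 1`` when an intercept was estimated).  Because
``Q_d`` shrinks every eigendirection by ``(lambda + d)/(lambda + 1) <= 1``,
the Liu interval is never wider than the OLS one, with equality at ``d = 1``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .liu_estimation import LiuFit
from .model_core import DesignResponse, OLSFit

__all__ = ["IntervalResult", "predict_interval_ols", "predict_interval_liu"]


@dataclass
class IntervalResult:
    point_estimate: float
    lower: float
    upper: float
    level: float
    width: float


def _prepare(fit: OLSFit, data: DesignResponse, x0, level: float):
    x0 = np.asarray(x0, dtype=float).ravel()
    if x0.shape[0] != data.p:
        raise ValueError(f"x0 must have length p = {data.p}")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie strictly between 0 and 1")
    # variance is evaluated on the same (centered) system the fit used
    x0c = x0 - fit.x_mean
    spec = fit.spectral
    t_crit = float(stats.t.ppf(0.5 + level / 2.0, fit.df_resid))
    return x0, x0c, spec, t_crit


def _interval(point: float, half_width: float, level: float) -> IntervalResult:
    return IntervalResult(
        point_estimate=float(point),
        lower=float(point - half_width),
        upper=float(point + half_width),
        level=level,
        width=float(2.0 * half_width),
    )


def predict_interval_ols(
    fit: OLSFit, data: DesignResponse, x0, level: float = 0.95
) -> IntervalResult:
    """Mean prediction interval for the OLS fit at ``x0`` (raw scale)."""
    x0, x0c, spec, t_crit = _prepare(fit, data, x0, level)
    point = float(x0 @ fit.beta_hat + (fit.intercept_ or 0.0))
    # x0c' (X'X)^-1 x0c in spectral coordinates: sum (D' x0c)_j^2 / lambda_j
    u = spec.D.T @ x0c
    var = fit.sigma2_hat * float(np.sum(u**2 / spec.eigenvalues))
    return _interval(point, t_crit * np.sqrt(var), level)


def predict_interval_liu(
    liu: LiuFit,
    ols: OLSFit,
    data: DesignResponse,
    x0,
    level: float = 0.95,
) -> IntervalResult:
    """Mean prediction interval for a Liu fit at ``x0`` (raw scale)."""
    x0, x0c, spec, t_crit = _prepare(ols, data, x0, level)
    point = float(x0 @ liu.beta_liu + (liu.intercept_estimate or 0.0))
    # Q_d (X'X)^-1 Q_d' = D diag(((lam+d)/(lam+1))^2 / lam) D'
    u = spec.D.T @ x0c
    lam = spec.eigenvalues
    shrink = (lam + liu.d) / (lam + 1.0)
    var = ols.sigma2_hat * float(np.sum((shrink * u) ** 2 / lam))
    return _interval(point, t_crit * np.sqrt(var), level)
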