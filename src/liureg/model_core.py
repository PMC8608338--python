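"""Linear-model containers, OLS estimation, canonical (eigen) form and
multicollinearity diagnostics.

The canonical form rotates the model ``y = X beta + eps`` into
``y = Z alpha + eps`` with ``Z = X D`` and ``Z'Z = Lambda`` diagonal, where
``D`` holds the eigenvectors of ``X'X`` and ``Lambda`` its eigenvalues.  All
per-component shrinkage rules operate on the canonical coefficients
``alpha_hat`` and the eigenvalues, so this module is the foundation for
everything else in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SingularDesignError",
    "DegreesOfFreedomError",
    "DesignResponse",
    "SpectralForm",
    "OLSFit",
    "read_csv",
    "spectral_decompose",
    "fit_ols",
    "condition_number",
    "classify_collinearity",
]

#: eigenvalues of X'X below RANK_TOL * lambda_max count as rank deficiency
RANK_TOL = 1e-12


class SingularDesignError(ValueError):
    """X'X is (numerically) singular: the design has no full column rank."""


class DegreesOfFreedomError(ValueError):
    """Too few observations to leave positive residual degrees of freedom."""


@dataclass
class DesignResponse:
    """A fixed design matrix ``X`` (n x p) with its response vector ``y``.

    Parameters
    ----------
    X, y
        Predictors and response.  ``n > p`` is required (``n > p + 1`` when an
        intercept is estimated) so the residual variance is identifiable.
    intercept
        If true, an intercept is handled by centering: ``y`` and the columns
        of ``X`` are mean-centered before any (shrinkage) fit and the
        intercept is recovered afterwards as ``ybar - xbar' beta``.
    """

    X: np.ndarray
    y: np.ndarray
    intercept: bool = True
    column_names: Sequence[str] | None = None
    response_name: str = "y"

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.y = np.asarray(self.y, dtype=float).ravel()
        if not np.all(np.isfinite(self.X)) or not np.all(np.isfinite(self.y)):
            raise ValueError("X and y must contain only finite values")
        n, p = self.X.shape
        if p < 1:
            raise ValueError("X needs at least one predictor column")
        if self.y.shape[0] != n:
            raise ValueError(f"len(y) = {self.y.shape[0]} does not match n = {n}")
        if n - p - int(self.intercept) <= 0:
            raise DegreesOfFreedomError(
                f"n = {n} leaves no residual degrees of freedom for p = {p}"
                + (" plus an intercept" if self.intercept else "")
            )
        if self.column_names is None:
            self.column_names = [f"x{j + 1}" for j in range(p)]
        else:
            self.column_names = list(self.column_names)
            if len(self.column_names) != p:
                raise ValueError("column_names length does not match p")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def centered(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
        """Return ``(Xc, yc, x_mean, y_mean)`` honouring the intercept flag."""
        if self.intercept:
            x_mean = self.X.mean(axis=0)
            y_mean = float(self.y.mean())
            return self.X - x_mean, self.y - y_mean, x_mean, y_mean
        return self.X, self.y, np.zeros(self.p), 0.0


@dataclass
class SpectralForm:
    """Eigen decomposition of ``X'X`` plus the canonical OLS coefficients.

    ``eigenvalues`` are sorted descending, the columns of the orthogonal
    matrix ``D`` match that order, ``Z = X D`` and
    ``alpha_hat = Lambda^-1 Z' y``.  Each eigenvector's entry of largest
    magnitude is made positive (ties broken by lowest index) so repeated
    decompositions are reproducible.
    """

    eigenvalues: np.ndarray
    D: np.ndarray
    Z: np.ndarray
    alpha_hat: np.ndarray


@dataclass
class OLSFit:
    """Ordinary least squares fit, in both original and canonical coordinates."""

    beta_hat: np.ndarray
    alpha_hat: np.ndarray
    sigma2_hat: float
    df_resid: int
    residuals: np.ndarray
    intercept_: float | None
    x_mean: np.ndarray
    y_mean: float
    spectral: SpectralForm = field(repr=False)


def _fix_signs(D: np.ndarray) -> np.ndarray:
    """Flip eigenvector signs so the largest-magnitude entry is positive."""
    idx = np.argmax(np.abs(D), axis=0)
    signs = np.sign(D[idx, np.arange(D.shape[1])])
    signs[signs == 0] = 1.0
    return D * signs


def spectral_decompose(data: DesignResponse) -> SpectralForm:
    """Eigen-decompose ``X'X`` (of the centered design when an intercept is
    fitted) and compute the canonical OLS coefficients."""
    Xc, yc, _, _ = data.centered()
    G = Xc.T @ Xc
    w, V = np.linalg.eigh(G)
    order = np.argsort(w)[::-1]
    lam = w[order]
    if lam[-1] <= RANK_TOL * lam[0] or lam[-1] <= 0.0:
        raise SingularDesignError(
            f"smallest eigenvalue of X'X is {lam[-1]:.3e} "
            f"(largest {lam[0]:.3e}): design is rank deficient"
        )
    D = _fix_signs(V[:, order])
    Z = Xc @ D
    alpha_hat = (Z.T @ yc) / lam
    return SpectralForm(eigenvalues=lam, D=D, Z=Z, alpha_hat=alpha_hat)


def fit_ols(data: DesignResponse) -> OLSFit:
    """Fit OLS through the canonical form: ``beta_hat = D alpha_hat``.

    ``sigma2_hat`` is the unbiased residual variance RSS / df with
    ``df = n - p`` (no intercept) or ``n - p - 1`` (intercept estimated).
    """
    spec = spectral_decompose(data)
    Xc, yc, x_mean, y_mean = data.centered()
    beta_hat = spec.D @ spec.alpha_hat
    intercept = float(y_mean - x_mean @ beta_hat) if data.intercept else None
    fitted = data.X @ beta_hat + (intercept or 0.0)
    residuals = data.y - fitted
    df_resid = data.n - data.p - int(data.intercept)
    rss = float(residuals @ residuals)
    return OLSFit(
        beta_hat=beta_hat,
        alpha_hat=spec.alpha_hat,
        sigma2_hat=rss / df_resid,
        df_resid=df_resid,
        residuals=residuals,
        intercept_=intercept,
        x_mean=x_mean,
        y_mean=y_mean,
        spectral=spec,
    )


def condition_number(data: DesignResponse, mode: str = "sqrt") -> float:
    """Condition number of ``X'X``: ``lambda_max / lambda_min`` (``ratio``) or
    its square root (``sqrt``, the default — the singular-value convention the
    usual 10/30/100 severity thresholds refer to)."""
    if mode not in ("sqrt", "ratio"):
        raise ValueError(f"unknown condition-number mode {mode!r}")
    lam = spectral_decompose(data).eigenvalues
    ratio = float(lam[0] / lam[-1])
    return float(np.sqrt(ratio)) if mode == "sqrt" else ratio


def classify_collinearity(cn: float) -> str:
    """Severity band for a condition number: ``low`` below 10, ``moderate``
    for 10 <= CN <= 30, ``high`` for 30 < CN <= 100, ``severe`` above 100."""
    if not np.isfinite(cn) or cn < 1.0:
        raise ValueError("condition number must be a finite value >= 1")
    if cn < 10.0:
        return "low"
    if cn <= 30.0:
        return "moderate"
    if cn <= 100.0:
        return "high"
    return "severe"


def read_csv(
    path,
    response: str,
    predictors: Sequence[str] | None = None,
    intercept: bool = True,
) -> DesignResponse:
    """Load a header-row CSV into a :class:`DesignResponse`.

    The response column is selected by name; all remaining numeric columns
    are predictors unless an explicit ``predictors`` list is given.
    """
    df = pd.read_csv(path)
    if response not in df.columns:
        raise ValueError(f"response column {response!r} not found in {path}")
    if predictors is None:
        num = df.select_dtypes(include=[np.number])
        predictors = [c for c in num.columns if c != response]
    else:
        missing = [c for c in predictors if c not in df.columns]
        if missing:
            raise ValueError(f"predictor columns not found: {missing}")
    if not predictors:
        raise ValueError("no numeric predictor columns found")
    return DesignResponse(
        X=df[list(predictors)].to_numpy(dtype=float),
        y=df[response].to_numpy(dtype=float),
        intercept=intercept,
        column_names=list(predictors),
        response_name=response,
    )
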