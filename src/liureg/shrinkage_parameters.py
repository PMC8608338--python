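"""Data-driven rules for the Liu shrinkage parameter ``d``.

Every rule maps the canonical OLS coefficients ``alpha_hat``, the eigenvalues
``lambda_j`` of ``X'X`` and the residual variance estimate ``sigma2_hat`` to a
scalar ``d`` in [0, 1]:

* ``d_j = (alpha_j^2 - s2) / (s2/lambda_j + alpha_j^2)`` — per-component rule;
  D1 evaluates it at ``max_j alpha_j^2`` paired with ``lambda_max``, while
  D2/D3/D4 take the median / mean / max of the components.
* ``q_j = (alpha_j^2 - 1) / (1/lambda_min + alpha_j^2)``; D5/D6/D7 take the
  median / mean / max.
* The quantile family ``D_gamma = max(0, (Q_gamma - s2) /
  (s2/lambda_min + max_j alpha_j^2))`` where ``Q_gamma`` is the empirical
  gamma-quantile of ``{alpha_j^2}``; D8, D9 and D10 fix gamma at 0 (minimum),
  0.25 (first quartile) and 0.50 (median).

Aggregated rules are clipped below at zero; the upper bound 1 holds
algebraically for every rule under the default quantile base (numerators never
exceed denominators), so no upper clip is needed there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import OLSFit

__all__ = [
    "ShrinkageInputs",
    "ShrinkageResult",
    "RULES",
    "GAMMA_BY_RULE",
    "d_components",
    "q_components",
    "estimate_d",
    "estimate_all",
]

#: all aggregated rule tokens, in the conventional order
RULES = ("D1", "D2", "D3", "D4", "D5", "D6", "D7", "D8", "D9", "D10")

#: fixed quantile probabilities behind the named members of the D_gamma family
GAMMA_BY_RULE = {"D8": 0.0, "D9": 0.25, "D10": 0.50}


@dataclass
class ShrinkageInputs:
    """Canonical-form quantities every rule consumes."""

    alpha_hat: np.ndarray
    eigenvalues: np.ndarray
    sigma2_hat: float

    def __post_init__(self) -> None:
        self.alpha_hat = np.asarray(self.alpha_hat, dtype=float).ravel()
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float).ravel()
        if self.alpha_hat.size == 0:
            raise ValueError("alpha_hat must be non-empty")
        if self.alpha_hat.shape != self.eigenvalues.shape:
            raise ValueError("alpha_hat and eigenvalues must have equal length")
        if not (np.all(np.isfinite(self.alpha_hat)) and np.all(np.isfinite(self.eigenvalues))):
            raise ValueError("inputs must be finite")
        if np.any(self.eigenvalues <= 0.0):
            raise ValueError("eigenvalues must be strictly positive")
        # sigma2 == 0 means an exactly interpolating fit upstream; every rule
        # would degenerate, so it is rejected rather than silently handled.
        if not (np.isfinite(self.sigma2_hat) and self.sigma2_hat > 0.0):
            raise ValueError("sigma2_hat must be strictly positive")

    @classmethod
    def from_fit(cls, fit: OLSFit) -> "ShrinkageInputs":
        return cls(
            alpha_hat=fit.alpha_hat,
            eigenvalues=fit.spectral.eigenvalues,
            sigma2_hat=fit.sigma2_hat,
        )


@dataclass
class ShrinkageResult:
    """A selected shrinkage parameter with its per-component diagnostics."""

    name: str
    d: float
    gamma: float | None = None
    components: np.ndarray | None = None


def d_components(inp: ShrinkageInputs) -> np.ndarray:
    """Per-component ``d_j`` values (may be negative; no clipping here)."""
    a2 = inp.alpha_hat**2
    return (a2 - inp.sigma2_hat) / (inp.sigma2_hat / inp.eigenvalues + a2)


def q_components(inp: ShrinkageInputs) -> np.ndarray:
    """Per-component ``q_j`` values with the shared ``1/lambda_min`` term."""
    a2 = inp.alpha_hat**2
    return (a2 - 1.0) / (1.0 / inp.eigenvalues.min() + a2)


def _normalise_rule(rule: str) -> str:
    token = rule.strip().upper().replace("_", "").replace("-", "")
    if token in ("DGAMMA", "DG"):
        return "D_gamma"
    return token


def estimate_d(
    inp: ShrinkageInputs,
    rule: str,
    gamma: float | None = None,
    quantile_base: str = "alpha_squared",
) -> ShrinkageResult:
    """Evaluate one shrinkage rule.

    Parameters
    ----------
    rule
        Case-insensitive token among ``D1`` … ``D10`` or ``Dgamma``.
    gamma
        Quantile probability, required iff ``rule`` is ``Dgamma``.
    quantile_base
        ``alpha_squared`` (default) takes quantiles of ``alpha_j^2``, which
        keeps every member of the family inside [0, 1] by construction;
        ``alpha`` takes quantiles of the signed coefficients (a sensitivity
        reading of the family's definition) and clips the result into [0, 1].
    """
    token = _normalise_rule(rule)
    a2 = inp.alpha_hat**2
    lam = inp.eigenvalues
    s2 = inp.sigma2_hat

    if token == "D1":
        d = max(0.0, (a2.max() - s2) / (s2 / lam.max() + a2.max()))
        return ShrinkageResult("D1", float(d))

    if token in ("D2", "D3", "D4"):
        comp = d_components(inp)
        agg = {"D2": np.median, "D3": np.mean, "D4": np.max}[token]
        return ShrinkageResult(token, float(max(0.0, agg(comp))), components=comp)

    if token in ("D5", "D6", "D7"):
        comp = q_components(inp)
        agg = {"D5": np.median, "D6": np.mean, "D7": np.max}[token]
        return ShrinkageResult(token, float(max(0.0, agg(comp))), components=comp)

    if token in GAMMA_BY_RULE or token == "D_gamma":
        if token in GAMMA_BY_RULE:
            g = GAMMA_BY_RULE[token]
            name = token
        else:
            if gamma is None:
                raise ValueError("gamma is required for the Dgamma rule")
            g = float(gamma)
            name = "D_gamma"
        if not 0.0 <= g <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        if quantile_base == "alpha_squared":
            base = a2
        elif quantile_base == "alpha":
            base = inp.alpha_hat
        else:
            raise ValueError(f"unknown quantile_base {quantile_base!r}")
        # "type 7" empirical quantile: linear interpolation between order
        # statistics; gamma=0 is the minimum, gamma=0.5 the sample median.
        q = float(np.quantile(base, g))
        d = (q - s2) / (s2 / lam.min() + a2.max())
        d = min(max(0.0, d), 1.0) if quantile_base == "alpha" else max(0.0, d)
        return ShrinkageResult(name, float(d), gamma=g, components=base)

    raise ValueError(f"unknown shrinkage rule {rule!r}")


def estimate_all(
    inp: ShrinkageInputs,
    rules=RULES,
    gammas: dict[str, float] | None = None,
) -> list[ShrinkageResult]:
    """Evaluate a list of rules; ``gammas`` supplies probabilities for any
    explicit ``Dgamma`` entries."""
    out = []
    for rule in rules:
        g = (gammas or {}).get(rule)
        out.append(estimate_d(inp, rule, gamma=g))
    return out
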