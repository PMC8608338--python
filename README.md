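# liureg

Liu regression for multicollinear linear models, with the full family of
data-driven shrinkage-parameter rules (D1–D10, including the quantile-based
family D8–D10), closed-form MSE expressions, condition-number diagnostics,
t-based mean prediction intervals, and a Monte Carlo engine that compares the
rules by estimated MSE / MAE over a factorial design.

It is written for applied statisticians and epidemiologists who fit linear
models whose predictors are strongly correlated (e.g. concentrations of
chemically related compounds), where ordinary least squares is unbiased but
wildly variable.

## The model

For `y = Xβ + ε`, `ε ~ N(0, σ²Iₙ)`, the Liu estimator shrinks OLS linearly:

```
β̂_LIU = (X′X + I)⁻¹ (X′X + dI) β̂_OLS ,   0 ≤ d ≤ 1 ,
```

with `d = 1` recovering OLS.  In the canonical form `y = Zα + ε`
(`Z = XD`, `Z′Z = Λ = diag(λ₁ ≥ … ≥ λ_p)` from the eigendecomposition of
`X′X`) the shrinkage is componentwise,
`α̂_LIU,j = ((λⱼ + d)/(λⱼ + 1)) α̂ⱼ`, which makes per-component rules for
choosing `d` tractable.  The rules implemented are:

| rule | definition |
|------|------------|
| `d̂ⱼ` | `(α̂ⱼ² − σ̂²) / (σ̂²/λⱼ + α̂ⱼ²)` (the unconstrained one-dimensional MSE minimizer) |
| D1 | `max(0, (α̂²_max − σ̂²)/(σ̂²/λ_max + α̂²_max))` |
| D2 / D3 / D4 | `max(0, median / mean / max of d̂ⱼ)` |
| `q̂ⱼ` | `(α̂ⱼ² − 1) / (1/λ_min + α̂ⱼ²)` |
| D5 / D6 / D7 | `max(0, median / mean / max of q̂ⱼ)` |
| Dγ | `max(0, (Q_γ − σ̂²)/(σ̂²/λ_min + α̂²_max))`, `Q_γ` the empirical γ-quantile of `{α̂ⱼ²}` |
| D8 / D9 / D10 | Dγ at γ = 0 (minimum), 0.25 (first quartile), 0.50 (median) |

Every aggregated rule provably lands in `[0, 1]`.  Under severe
multicollinearity the quantile rules — D8 in particular — choose very small
`d` and dominate both OLS and the older rules in Monte Carlo risk.

## Worked example

The package ships a deterministic generator for a synthetic 30-observation,
4-predictor dataset with high collinearity (a stand-in, drawn from the
package's own simulation design, for classic heat-evolved-by-tobacco-blend
style datasets that cannot be redistributed):

```sh
$ liureg make-fixture --out tobacco_like.csv --seed 0
$ liureg diagnose tobacco_like.csv --quiet
eigenvalues: 103.001 0.379287 0.14393 0.0773187
cn_sqrt: 36.49881
cn_ratio: 1332.16319
classification (sqrt mode): high
```

The condition number 36.5 (square-root convention) sits in the "high" band
(30–100), so shrinkage is warranted:

```sh
$ liureg fit tobacco_like.csv --rules D1,D5,D8,D9,D10 --quiet
estimator        d       mse       x1       x2       x3        x4
      OLS      NaN 14.661079 2.491040 0.796218 0.075987 -1.557786
       D1 0.857782 11.333550 2.239082 0.745128 0.114276 -1.292081
       D5 0.071742  6.397317 0.846510 0.462751 0.325903  0.176465
       D8 0.000000  7.081594 0.719409 0.436979 0.345219  0.310501
       D9 0.003414  7.044732 0.725457 0.438205 0.344299  0.304123
      D10 0.118790  6.051635 0.929862 0.479653 0.313236  0.088566
```

`d` is each rule's selected shrinkage parameter and `mse` the plug-in
closed-form MSE `σ̂²Σⱼ(λⱼ+d)²/(λⱼ(λⱼ+1)²) + (d−1)²Σⱼα̂ⱼ²/(λⱼ+1)²` (for OLS,
`σ̂²Σⱼ1/λⱼ`): every Liu fit roughly halves the OLS risk here, and the heavily
shrunk quantile rules pull the unstable coefficients (note the sign flip on
x4) toward stability.  Mean prediction intervals at a new point are
correspondingly never wider than the OLS interval:

```sh
$ liureg interval tobacco_like.csv --x0 0.5,0.5,0.5,0.5 --rules D1,D8 --quiet
estimator        d    lower    upper  difference
      OLS      NaN 0.245757 0.764290    0.518534
       D1 0.857782 0.241739 0.756213    0.514474
       D8 0.000000 0.213121 0.711884    0.498762
```

A single Monte Carlo cell of the estimator comparison (collinearity level
ρ = 0.999, n = 25, p = 4, σ = 1, M = 2000 replications):

```sh
$ liureg simulate --n 25 --p 4 --rho 0.999 --M 2000 --seed 1 --quiet
 n  p   rho  sigma    M  seed rule       emse  emse_se      emae  emae_se   mean_d
25  4 0.999    1.0 2000     1  OLS 148.676864 2.988062 19.252186 0.195913      NaN
25  4 0.999    1.0 2000     1   D1 145.775106 2.988595 18.948749 0.199479 0.967367
...
25  4 0.999    1.0 2000     1   D8   0.084073 0.001470  0.457607 0.004203 0.000780
```

OLS risk explodes with the collinearity while D8 (mean selected d ≈ 0.001)
cuts it by three orders of magnitude.  Full factorials run from a flat
config file via `liureg grid --config my.cfg`.

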