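# cqrsurv

Censored quantile regression (CQR) survival analysis of a breast-cancer
cohort, built as a reusable, tested Python package with a calibrated
synthetic-cohort generator.

## The problem

Classical survival models (Cox, parametric AFT) summarise covariate effects
through the hazard or the mean and assume the *shape* of the survival
distribution is preserved across subgroups. For a hospital cohort of 522
breast-cancer patients (age 23–80, mean ± SD 47.04 ± 10.70; ~35 % deaths
during follow-up) the question was instead: how do age at diagnosis, tumor
size and the number of involved lymph nodes move *individual quantiles* of
overall survival — the median, the quartiles, the tails?

Censored quantile regression answers this directly. The conditional
τ-quantile of survival time `T` given covariates `x` is modelled linearly
(months scale),

    Q_τ(T | x) = x'β(τ),      x = (1, z², z, tumor size, n_nodes),

with `z` the age z-score. Right censoring is handled by locally weighted
redistribution of mass: for each censored subject the conditional
distribution value at the censoring time, `F(C_i | x_i)`, is estimated by a
**locally weighted Kaplan–Meier** estimator (product-limit with
Nadaraya–Watson kernel weights around `x_i`), and the subject's unit mass
is split between its censoring time — weight
`w_i = (τ − F̂) / (1 − F̂)` when `F̂ ≤ τ`, else 1 — and a pseudo-point at
an arbitrarily large time `Y⁺∞`. The estimate minimises the weighted check
loss `ρ_τ(u) = u·(τ − 1[u<0])`

    Σ_i  w_i ρ_τ(Y_i − x_i'β) + (1 − w_i) ρ_τ(Y⁺∞ − x_i'β),

solved exactly as a linear program; standard errors come from a
patient-level bootstrap.

The registry data are unpublished, so the package ships a
**synthetic-cohort generator** whose defaults are calibrated once to the
cohort's published marginal summaries (survival 90 / 73 / 62.5 % at
1 / 3 / 5 years, 35.4 % deaths, 62.1 % of tumors < 2 cm, …) under a linear
conditional-quantile truth, giving every downstream stage a known oracle.

## What is in the box

| module | contents |
|---|---|
| `cqrsurv.cohort` | cohort table I/O + validation, age standardization, stratification bands, design matrix |
| `cqrsurv.simulate` | `CohortConfig`, calibrated generator, exact `true_quantile` oracle |
| `cqrsurv.km` | Kaplan–Meier with Greenwood variance, median, restricted-mean survival, k-sample log-rank |
| `cqrsurv.cqr` | check loss, kernel weights, local Kaplan–Meier, redistribution weights, exact LP fit, bootstrap SEs, quantile-process fits |
| `cqrsurv.scenarios` | quantile predictions on covariate grids (the scenario tables) |
| `cqrsurv.reference` | published coefficient rows, scenario grid and cohort summaries |

`analysis/01…04` are thin numbered drivers that generate the cohort,
describe it (KM curves, log-rank screening, restricted means), fit the
quantile process with bootstrap SEs, and evaluate the 18-scenario grid;
tables land in `results/`.

## Worked example

```python
import cqrsurv as cs
from cqrsurv import reference as ref

# the published median-row coefficients, a 40-year-old with a 1.5 cm tumor
# and 3 involved nodes:
q50 = cs.predict_quantile(ref.PUBLISHED_COEFFICIENTS[0.50],
                          age=40, tumor_size=1.5, n_nodes=3,
                          params=ref.AGE_STANDARDIZATION)
q25 = cs.predict_quantile(ref.PUBLISHED_COEFFICIENTS[0.25],
                          age=40, tumor_size=1.5, n_nodes=3,
                          params=ref.AGE_STANDARDIZATION)
print(round(q50, 2), round(q25, 2))
# 65.09 42.9

# a calibrated synthetic cohort and its crude survival:
syn = cs.generate_cohort(cs.CohortConfig(n=5000, seed=7))
f = syn.cohort.frame
curve = cs.km_fit(f.time, f.event)
print(round(f.event.mean(), 3),
      [round(float(cs.survival_at(curve, t)), 3) for t in (12, 36, 60)])
# 0.347 [0.903, 0.73, 0.628]

# censored quantile regression on that cohort:
X = cs.design_matrix(syn.cohort, ref.AGE_STANDARDIZATION)
fit = cs.fit_cqr(cs.CQRProblem(X=X, Y=f.time.to_numpy(),
                               delta=f.event.to_numpy(), tau=0.5))
print([round(float(b), 2) for b in fit.beta])
# [68.33, -0.98, -2.28, -0.73, -0.37]   (truth: 68, -0.75, -2.5, -0.65, -0.4)
```

The first two numbers are the predicted conditional median and lower
quartile of overall survival in months for a comparatively favourable
patient — the model says half of such patients survive beyond ~65 months,
a quarter die before ~43. The fitted coefficients on the synthetic cohort
recover the generator's truth: each additional involved node costs about
0.4 months of median survival, each centimetre of tumor about 0.65 months,
with a concave age effect.

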