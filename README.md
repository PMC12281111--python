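# causalreport

Complete causal reporting for average-treatment-effect analyses of
tabular data.

Most statistical software answers a causal question with a single
coefficient and its p-value. That is incomplete reporting: a causal
effect estimate is only interpretable together with the estimand it
targets, the modeling assumptions behind the estimator, and the
identification assumptions that connect data to counterfactuals.
`causalreport` produces all of it in one pass. Given a CSV, a binary
exposure *A*, an outcome *Y* and an adjustment set *W*, it reports:

- **The estimand** in counterfactual notation — the average treatment
  effect (ATE) `E[Y^A=1] − E[Y^A=0]` — so the target of the analysis is
  explicit.
- **Five estimators with different modeling assumptions**: outcome
  regression, inverse probability of treatment weighting (IPTW),
  S- and T-standardization (g-computation with a single outcome model
  or one model per arm), and targeted maximum likelihood estimation
  (TMLE). When their estimates disagree materially, at least one
  model is misspecified — the report prompts the user to look.
- **The six identification assumptions** — conditional exchangeability,
  positivity, consistency, no interference, no measurement error,
  well-specified models — templated to the user's variable names, with
  a ready-to-adapt methods paragraph.
- **Diagnostics** linked to those assumptions: per-arm propensity-score
  ranges and overlap histograms (positivity), and standardized mean
  differences before and after weighting (exchangeability).

The effect table deliberately omits the adjustment-covariate
coefficients (the "Table 2 fallacy": covariate coefficients are not
causal effects).

It is aimed at applied epidemiologists and biostatisticians analysing
observational studies with a binary exposure and a numeric (gaussian
family) or binary (binomial family) outcome.

## Worked example

Generate a confounded observational study with a known true effect
(τ = 3) and analyse it:

```bash
causalreport simulate --scenario linear --n 2000 --seed 1 --out demo
causalreport run --data demo.csv --outcome Y --exposure A \
    --covariates w1,w2,w3,w4,w5 --seed 1 -B 500 --out-dir demo_out
```

The run prints (abridged):

```
Estimand: Average Treatment Effect
E[Y^A=1] - E[Y^A=0]
Adjustment set: w1, w2, w3, w4, w5
*Please see output at $Estimand_interpretation for details

Treatment effect:

                       Estimate  Std. error  P-value  S-value  95% CI lower  95% CI upper
A1 outcome regression     2.994       0.093    0.000  605.582         2.811         3.176
A1 IPTW                   3.032       0.124    0.000  432.957         2.788         3.275
A1 S-standardization      2.994       0.093    0.000      Inf         2.811         3.170
A1 T-standardization      2.986       0.096    0.000      Inf         2.795         3.181
A1 TMLE                   3.001       0.092    0.000  766.222         2.820         3.182

Reference exposure level: 0

Please evaluate whether the difference between the lowest estimate: 2.9857
and highest: 3.0315 is of substance, given the nature of the data. ...

To interpret these effects as causal, the following key assumptions must be satisfied:
[1] Conditional exchangeability requires that adjusting for "w1, w2, w3, w4, w5" ...
[2] Positivity: ...
Note: PS=propensity score
  PS range for 1
  observed exposure: 0 0.0731, 0.8925
  observed exposure: 1 0.1478, 0.8678
...
```

All five estimates surround the true τ = 3 and their spread (0.046) is
small relative to the standard errors, as expected when every model is
correctly specified. The S-value column is the surprisal −log2(p): the
bootstrap rows print `Inf` because no resample crossed zero. The full
hierarchical report (including balance tables, overlap data and
long-form explanations) is saved as `demo_out/report.json`; re-render
it any time with `causalreport report demo_out/report.json`.

The same analysis is available as a library call:

```python
import pandas as pd
from causalreport import CausalQuery, analyze, render_text

query = CausalQuery("Y", "A", ("w1", "w2", "w3", "w4", "w5"), seed=1)
report = analyze(pd.read_csv("demo.csv"), query)
print(render_text(report))
```

## Scope

Binary exposures only; gaussian or binomial outcome families; additive
main-effects nuisance models. Out of scope: multi-level or
time-varying exposures, survival outcomes, ATT/ATC estimands,
mediation, instrumental variables, machine-learning nuisance models.
See `docs/methods.md` for the statistical details and design choices.
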