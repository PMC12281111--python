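# Methods

## The estimand and the reporting model

The package targets one estimand: the population average treatment
effect (ATE) of a binary exposure A on an outcome Y,

    psi = E[Y^{A=a1}] - E[Y^{A=a0}],

a contrast of counterfactual means, reported as a difference in means
(gaussian family) or a risk difference (binomial family). The report
that surrounds the estimate is part of the method, not decoration: a
causal point estimate is interpretable only alongside (i) the estimand,
(ii) estimates from estimators that lean on different models, and
(iii) the identification assumptions with diagnostics. The package
therefore always emits the estimand expression, a five-row effect
table, a disagreement prompt quoting the smallest and largest point
estimates, the six assumptions templated to the user's variables, and
positivity/balance diagnostics.

Identification requires conditional exchangeability given the
adjustment set W, positivity (0 < P(A=a1|W) < 1 almost surely),
consistency, no interference, no measurement error, and well-specified
models. None of these is testable from data alone; the diagnostics are
indicative, not confirmatory.

## Estimators

All five estimators share one design-matrix convention: additive main
effects, numeric covariates entered linearly, non-numeric covariates
reference-cell dummy coded with the first level in sorted order as
reference. Sharing the convention is deliberate — differences between
estimates should reflect modeling assumptions, not coding accidents.
Columns with numeric dtype (including integer-coded ordinal variables)
are treated as numeric; only string/categorical dtypes are dummy coded.
Users who want an ordinal variable treated as categorical can cast the
column to strings before the call.

1. **Outcome regression.** GLM of Y on A and W (gaussian-identity or
   binomial-logit). For gaussian outcomes the ATE is the coefficient on
   A, with model-based t inference. For binomial outcomes the
   coefficient would be a conditional log odds ratio, which is not the
   estimand; instead the marginal risk difference is computed by
   averaging predicted probabilities at A=a1 and A=a0 over the sample,
   with bootstrap inference.
2. **IPTW.** The propensity score g(W) = P(A=a1|W) is a main-effects
   logistic regression. Unstabilized weights w = A/g + (1-A)/(1-g) use
   scores truncated to [0.025, 0.975]; the marginal structural model
   E[Y^a] = b0 + psi*a is fit by weighted least squares and the SE is
   the HC1 sandwich. Treating the estimated g as known makes this SE
   mildly conservative (the parameter-recovery test bounds the ratio of
   empirical SD to reported SE); it never understates uncertainty,
   which is the right direction for a reporting tool.
3. **S-standardization** (g-computation, single learner). One outcome
   GLM including A; every unit is predicted under both exposure levels
   and the predictions averaged. For a gaussian additive model this
   collapses algebraically to the outcome-regression coefficient — the
   identity is kept as a permanent cross-check in the tests.
4. **T-standardization** (one learner per arm). Separate outcome GLMs
   of Y on W within each arm, each predicting for all n units. With the
   exposure modeled implicitly by stratification, exposure-covariate
   interactions are saturated, so S- and T-standardization genuinely
   embody different modeling assumptions.
5. **TMLE.** Doubly robust targeting of the S-standardization initial
   fit. The outcome is mapped to (0,1) (min-max scaling for gaussian;
   identity for binomial), initial predictions are bounded to
   [0.005, 0.995] so logits stay finite, and a one-parameter logistic
   fluctuation with offset logit(Q(A,W)) and covariate
   H = A/g - (1-A)/(1-g) is fit by Newton's method on its score
   equation (the problem is concave in epsilon; iteration stops when
   the mean score falls below 1e-12). The ATE is the rescaled mean
   difference of targeted predictions; the SE is the sample SD of the
   efficient influence curve over sqrt(n), rescaled. At the fluctuation
   optimum the influence curve has mean zero by construction, which the
   tests enforce to 1e-8.

The propensity model is fit once and shared by IPTW, TMLE and the
diagnostics. With an empty adjustment set it is intercept-only, every
score equals the sample exposure proportion, and all four non-TMLE
estimators reduce exactly to the difference in arm means — the
randomization limit.

Nuisance models are deliberately plain GLMs rather than cross-validated
ensembles: estimates are then deterministic given the data and seed,
reproducible to the byte, and auditable at desk scale. The cost is that
TMLE's double robustness only protects against misspecification of one
of two *parametric* models.

## Uncertainty

Analytic inference is used where a standard SE exists (t-based for the
gaussian outcome-regression coefficient; normal sandwich for IPTW;
influence-curve normal for TMLE). The standardization estimators and
the binomial marginal risk difference use a nonparametric bootstrap:
B row-resamples with replacement (default B = 1000), refitting every
model inside the estimator per replicate. The CI is the percentile
interval; the SE is the SD of the replicates; the p-value is the
two-sided sign-crossing proportion

    p = min(1, 2 * min(#{rep <= 0}, #{rep >= 0}) / B),

which is exactly 0 when all replicates share a sign. The S-value
-log2(p) is then infinite — printed as `Inf` — meaning "no resample
contradicted the sign of the effect at this B", not infinite evidence.
A continuity-corrected variant ((k+1)/(B+1)) is available as an option
for users who prefer p bounded away from 0. Percentile rather than
BCa/basic intervals: asymmetry of the sampling distribution is carried
into the interval, and the choice has no tuning constants. Replicates
whose refit fails (e.g. a resample that loses an exposure arm) are
dropped and counted; more than 20% failures aborts with an error rather
than reporting inference from a selected subset.

Randomness is controlled by one master seed; each estimator draws its
bootstrap resamples from a child stream derived from (seed, fixed
estimator code), so adding or removing an estimator never changes
another's replicates.

## Diagnostics

Positivity: per-arm min/max of the *untruncated* propensity score
(truncation stabilizes weights; diagnostics must reveal, not hide,
extreme scores), plus shared-bin histograms and kernel densities of the
truncated scores on [0,1]. Exchangeability (indirectly): standardized
mean differences d = (m1 - m0)/sqrt((s1^2 + s0^2)/2) per covariate
(per non-reference level for categoricals), unweighted and
IPT-weighted, flagged at the conventional |d| > 0.1. Weighted variances
normalize weights to sum to the arm size (frequency-weight convention)
for stable small-sample behavior. A constant covariate returns d = 0:
there is nothing to balance.

## Tunable parameters

| parameter | default | rationale |
|---|---|---|
| `conf_level` | 0.95 | convention |
| `bootstrap_reps` (B) | 1000 | percentile-CI stability; SE noise ~2% |
| `ps_bound` (g_min) | 0.025 | common truncation default for IPT weights |
| initial-Q bounds | [0.005, 0.995] | finite logits in the targeting step |
| SMD flag threshold | 0.1 | conventional imbalance cut-off |
| overlap bins | 20 | readable histograms at typical n |

## The synthetic-data generator

Five scenarios share one covariate layout — W1..W3 standard normal,
W4, W5 Bernoulli(0.5) — exposure A ~ Bernoulli(expit(alpha·[1,W])), and
an additive treatment effect tau (log-odds scale for the binary
outcome). Defaults: tau = 3, noise SD = 2, alpha = (0, .4, -.3, .2,
.5, -.4), beta = (1, 1, -1, .5, 1, -.5) — moderate confounding with
P(A=1) near 0.5 and propensity scores spanning roughly 0.05–0.95,
i.e. a well-behaved observational study.

- `linear`: both nuisance models correct; the marginal ATE equals tau
  exactly (additive effect), so parameter-recovery and coverage studies
  have an exact truth.
- `nonlinear_outcome`: adds 2·W1² + 1.5·W1·W2 to the outcome mean. The
  propensity model stays correct but uses an off-center, steeper
  coefficient vector (-0.9, 1.2, -0.4, .2, .5, -.4): with the logistic
  curve evaluated away from its inflection point, exposure correlates
  with the omitted W1² term and an additive outcome regression is
  biased by about +0.4, while IPTW is not. This is the scenario in
  which the report's disagreement prompt earns its keep.
- `poor_overlap`: propensity coefficients scaled up ~5x so scores pile
  near 0 and 1 and the positivity diagnostics have a real violation to
  detect.
- `binary_outcome`: tau defaults to 1 (log odds ratio) with smaller
  outcome coefficients so risks stay away from the boundary; the true
  marginal risk difference has no closed form and is supplied by a
  Monte-Carlo oracle: 200 000 fresh covariate draws, averaging the
  structural contrast expit(tau + beta·W) - expit(beta·W). No outcome
  noise is sampled and nothing is estimated, so the MC standard error
  (~6e-4) is the only error. The oracle is recomputed at call time —
  it costs milliseconds, and a cached value could silently go stale.
- `randomized`: alpha = 0, the benchmark in which all estimators
  coincide with the difference in means.

What the generator does *not* emulate: missing data (the generator is
complete; complete-case handling is exercised separately), measurement
error, categorical covariates with many levels, heavy-tailed outcomes,
clustering/interference, and real-data quirks such as ceiling effects.
Passing the simulation suite therefore demonstrates correctness of the
estimators under their stated assumptions, not robustness to every
real-data pathology — which is exactly why the report prints the
assumptions next to the estimates.

## Numerical and design choices

- **Complete-case analysis** on the query columns only; the dropped-row
  count is logged and kept in the report. Transparent, if inefficient;
  imputation is out of scope.
- **Reference level** defaults to the smaller observed exposure value.
- **Empty adjustment sets** are legal and render a marginal estimand
  with an explicit "(none — marginal estimand)" marker; assumption
  texts switch to their unconditional variants.
- **Rank-deficient designs** fail loudly, naming the collinear columns
  (QR with column pivoting), rather than letting a pseudo-inverse pick
  an arbitrary solution that differs across estimators.
- **Rounding** is presentation-only: estimates/SE/CI to 3 decimals,
  p to 3 (so tiny p prints as 0.000), S to 3 with `Inf`, propensity
  scores to 4; the JSON report keeps full precision, and re-rendering
  from JSON reproduces the printed text byte for byte.
- **Binomial outcomes** may be coded with any two values; the larger
  (sorted) value is recoded to 1 with a log notice.

## Problem sizes in the test suite

The simulation studies run at sizes chosen to keep the full suite at
desk scale while leaving Monte-Carlo error well below the margins being
asserted: parameter recovery at n = 2000 with 200 replicates (B = 200),
percentile-CI coverage at n = 500 with 300 replicates (B = 200),
misspecification disagreement at n = 5000 with 200 replicates (B = 60),
and asymptotic balance/overlap checks on a single n = 50 000 draw.

## Known limitations

- Binary exposures only; no ATT/ATC, no time-varying treatments, no
  survival outcomes, no mediation or instrumental-variable analyses.
- Nuisance models are additive main-effects GLMs; there is no formula
  language for interactions or transformations. T-standardization and
  TMLE provide partial protection; assumption [6] in the report exists
  precisely because the user's additive model may be wrong.
- The IPTW sandwich SE ignores propensity estimation (conservative);
  the bootstrap rows' p-values have resolution 2/B.
- Balance is reported raw and IPT-weighted only; no TMLE-weighted
  balance, no e-values or negative-control diagnostics.
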