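"""Five average-treatment-effect estimators with distinct modeling assumptions.

All estimators target the same estimand, the marginal ATE
``E[Y^a1] - E[Y^a0]`` on the outcome's natural scale (difference in means
for gaussian outcomes, risk difference for binomial), but lean on
different models:

* **outcome regression** — a single GLM of Y on A and the adjustment set;
  for a gaussian family the ATE is the exposure coefficient itself.
* **IPTW** — weight each unit by the inverse probability of its observed
  exposure given covariates, then fit a weighted regression of Y on A
  alone; correct when the propensity model is correct.
* **S-standardization** — g-computation with one outcome model including
  the exposure: predict every unit's outcome under A=a1 and A=a0 and
  average the difference; correct when the outcome model is correct.
* **T-standardization** — g-computation with one outcome model per arm,
  so exposure-covariate interactions are implicitly saturated.
* **TMLE** — doubly robust: an initial outcome regression is fluctuated
  along a propensity-based "clever covariate" so that the efficient
  influence curve has mean zero, and the SE comes from that curve.

The propensity model g(W) = P(A=a1 | W) is shared by IPTW, TMLE and the
positivity/balance diagnostics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit, logit

from .exceptions import (
    ArmSizeError,
    CollinearityError,
    DegenerateOutcomeError,
    DegenerateWeightsError,
    EstimationError,
)
from .query import (
    ESTIMATOR_LABELS,
    ESTIMATOR_ORDER,
    AnalysisDataset,
    CausalQuery,
)
from .uncertainty import bootstrap, child_rng, s_value, wald_interval

#: Bounds applied to initial outcome predictions on the (0,1) scale before
#: taking logits in the targeting step.
_Q_BOUNDS = (0.005, 0.995)


@dataclass(frozen=True)
class PropensityFit:
    """Fitted propensity scores g_i = P(A = exposure_level | W_i)."""

    scores: np.ndarray
    bounded_scores: np.ndarray
    model_coefficients: pd.Series
    bound: float
    converged: bool = True
    warnings: tuple = ()


@dataclass(frozen=True)
class EffectEstimate:
    """One estimator's ATE estimate with its statistical inference."""

    method: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    s_value: float
    reference_level: object
    inference: str = "normal"  # "t", "normal" or "bootstrap"
    warnings: tuple = ()

    @property
    def label(self) -> str:
        return ESTIMATOR_LABELS[self.method]


@dataclass(frozen=True)
class TmleComponents:
    """Internals of the targeting step, kept for auditability."""

    clever_covariate: np.ndarray
    epsilon: float
    targeted_q1: np.ndarray
    targeted_q0: np.ndarray
    influence_curve: np.ndarray
    scale_bounds: tuple


@dataclass(frozen=True)
class RunResults:
    """Output of :func:`run_all_estimators`: the full effect table."""

    effects: tuple
    propensity: PropensityFit
    tmle_components: Optional[TmleComponents]
    min_estimate: float
    max_estimate: float


def _check_full_rank(X: pd.DataFrame) -> None:
    """Raise CollinearityError naming redundant columns if X is rank deficient."""
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank >= arr.shape[1]:
        return
    # QR with column pivoting: the columns pivoted beyond the numerical
    # rank are the redundant ones.
    from scipy.linalg import qr

    _, r, piv = qr(arr, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(arr.shape) * np.finfo(float).eps if diag.size else 0.0
    bad = [X.columns[j] for j in piv[np.sum(diag > tol):]]
    raise CollinearityError(bad)


def _design(data: AnalysisDataset, include_exposure: bool) -> pd.DataFrame:
    """Intercept + (exposure indicator) + coded adjustment covariates."""
    W = data.covariate_matrix()
    parts = [pd.Series(1.0, index=data.df.index, name="const")]
    if include_exposure:
        parts.append(
            pd.Series(data.exposure_indicator, index=data.df.index, name="__A__")
        )
    X = pd.concat(parts + [W], axis=1)
    return X


def estimate_propensity(data: AnalysisDataset, query: CausalQuery) -> PropensityFit:
    """Logistic regression of the exposure indicator on the adjustment set.

    With an empty adjustment set this is intercept-only, so every score
    equals the sample exposure proportion.  Scores are additionally
    truncated to [g_min, 1 - g_min] for use in weighting and targeting;
    diagnostics use the untruncated scores.
    """
    a = data.exposure_indicator
    X = _design(data, include_exposure=False)
    if a.sum() < 1 or (1 - a).sum() < 1:
        raise ArmSizeError("each exposure arm needs at least one unit")
    _check_full_rank(X)
    warn_msgs = []
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = sm.GLM(a, X, family=sm.families.Binomial()).fit(maxiter=100)
            params = res.params
            scores = np.asarray(res.fittedvalues)
            converged = bool(getattr(res, "converged", True))
        except Exception as exc:  # perfect separation or IRLS breakdown
            warn_msgs.append(f"propensity model did not converge cleanly: {exc}")
            res = sm.GLM(a, X, family=sm.families.Binomial()).fit_regularized(
                alpha=1e-8, L1_wt=0.0
            )
            params = pd.Series(np.asarray(res.params), index=X.columns)
            scores = expit(X.to_numpy(dtype=float) @ np.asarray(res.params))
            converged = False
    for w in caught:
        if "separation" in str(w.message).lower() or "converge" in str(w.message).lower():
            warn_msgs.append(f"propensity model: {w.message}")
            converged = False
    g_min = query.ps_bound
    return PropensityFit(
        scores=np.clip(scores, 0.0, 1.0),
        bounded_scores=np.clip(scores, g_min, 1.0 - g_min),
        model_coefficients=pd.Series(params, index=X.columns),
        bound=g_min,
        converged=converged,
        warnings=tuple(warn_msgs),
    )


def _fit_glm(y, X, family, warn_msgs):
    """GLM fit with rank checking and convergence-warning capture."""
    _check_full_rank(X)
    if family == "gaussian":
        return sm.OLS(np.asarray(y), X).fit()
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        res = sm.GLM(np.asarray(y), X, family=sm.families.Binomial()).fit(maxiter=100)
    for w in caught:
        if "converge" in str(w.message).lower():
            warn_msgs.append(str(w.message))
    if not getattr(res, "converged", True):
        warn_msgs.append("binomial outcome model did not converge; using last iterate")
    return res


def _standardize_s(data: AnalysisDataset, query: CausalQuery) -> float:
    """Point estimate: single outcome model, counterfactual averaging."""
    X = _design(data, include_exposure=True)
    res = _fit_glm(data.outcome, X, query.family, [])
    X1 = X.copy()
    X1["__A__"] = 1.0
    X0 = X.copy()
    X0["__A__"] = 0.0
    return float(np.mean(res.predict(X1)) - np.mean(res.predict(X0)))


def _standardize_t(data: AnalysisDataset, query: CausalQuery) -> float:
    """Point estimate: per-arm outcome models, counterfactual averaging."""
    a = data.exposure_indicator.astype(bool)
    X = _design(data, include_exposure=False)
    preds = {}
    for arm, mask in (("treated", a), ("control", ~a)):
        n_arm, p = int(mask.sum()), X.shape[1]
        if n_arm <= p:
            raise ArmSizeError(
                f"{arm} arm has {n_arm} units but the outcome model needs more "
                f"than {p}"
            )
        res = _fit_glm(data.outcome[mask], X.loc[mask], query.family, [])
        preds[arm] = np.asarray(res.predict(X))
    return float(np.mean(preds["treated"]) - np.mean(preds["control"]))


def _marginal_rd_point(data: AnalysisDataset, query: CausalQuery) -> float:
    # binomial outcome regression reports the marginal risk difference,
    # which is the same counterfactual averaging as S-standardization
    return _standardize_s(data, query)


def fit_outcome_regression(data: AnalysisDataset, query: CausalQuery) -> EffectEstimate:
    """Single GLM of Y on exposure + adjustment set.

    Gaussian family: the ATE is the exposure coefficient, with
    model-based t inference.  Binomial family: the reported contrast is
    the marginal risk difference from averaged predicted probabilities,
    with bootstrap inference — never a conditional odds ratio.
    """
    warn_msgs: list = []
    if query.family == "gaussian":
        X = _design(data, include_exposure=True)
        res = _fit_glm(data.outcome, X, "gaussian", warn_msgs)
        est = float(res.params["__A__"])
        se = float(res.bse["__A__"])
        lo, hi, p = wald_interval(est, se, query.conf_level, df=res.df_resid)
        return EffectEstimate(
            method="outcome_regression",
            estimate=est,
            se=se,
            ci_low=lo,
            ci_high=hi,
            p_value=p,
            s_value=s_value(p),
            reference_level=query.reference_level,
            inference="t",
            warnings=tuple(warn_msgs),
        )
    est = _marginal_rd_point(data, query)
    rng = child_rng(query.seed, "outcome_regression")
    bs = bootstrap(_marginal_rd_point, data, query, query.bootstrap_reps, rng)
    return EffectEstimate(
        method="outcome_regression",
        estimate=est,
        se=bs.se,
        ci_low=bs.ci_low,
        ci_high=bs.ci_high,
        p_value=bs.p_value,
        s_value=s_value(bs.p_value),
        reference_level=query.reference_level,
        inference="bootstrap",
        warnings=tuple(warn_msgs),
    )


def fit_iptw(
    data: AnalysisDataset, query: CausalQuery, ps: PropensityFit
) -> EffectEstimate:
    """Inverse-probability-of-treatment weighting.

    Unstabilized weights w_i = A_i/g_i + (1-A_i)/(1-g_i) from truncated
    scores; the marginal structural model E[Y^a] = b0 + psi*a is fit by
    weighted least squares and the SE is the HC1 sandwich, which ignores
    the estimation of g and is therefore mildly conservative.
    """
    a = data.exposure_indicator
    g = ps.bounded_scores
    w = a / g + (1.0 - a) / (1.0 - g)
    if not np.all(np.isfinite(w)):
        raise EstimationError("non-finite IPT weight; scores escaped their bounds")
    for arm, mask in (("treated", a == 1), ("control", a == 0)):
        ess = w[mask].sum() ** 2 / np.sum(w[mask] ** 2)
        if ess < 2:
            raise DegenerateWeightsError(
                f"effective sample size {ess:.2f} < 2 in {arm} arm"
            )
    X = pd.DataFrame({"const": 1.0, "__A__": a}, index=data.df.index)
    res = sm.WLS(data.outcome, X, weights=w).fit(cov_type="HC1")
    est = float(res.params["__A__"])
    se = float(res.bse["__A__"])
    lo, hi, p = wald_interval(est, se, query.conf_level)
    return EffectEstimate(
        method="iptw",
        estimate=est,
        se=se,
        ci_low=lo,
        ci_high=hi,
        p_value=p,
        s_value=s_value(p),
        reference_level=query.reference_level,
        inference="normal",
    )


def _bootstrap_effect(method, point_fn, data, query) -> EffectEstimate:
    est = point_fn(data, query)
    rng = child_rng(query.seed, method)
    bs = bootstrap(point_fn, data, query, query.bootstrap_reps, rng)
    return EffectEstimate(
        method=method,
        estimate=float(est),
        se=bs.se,
        ci_low=bs.ci_low,
        ci_high=bs.ci_high,
        p_value=bs.p_value,
        s_value=s_value(bs.p_value),
        reference_level=query.reference_level,
        inference="bootstrap",
    )


def fit_s_standardization(data: AnalysisDataset, query: CausalQuery) -> EffectEstimate:
    """G-computation with a single outcome model including the exposure."""
    return _bootstrap_effect("s_standardization", _standardize_s, data, query)


def fit_t_standardization(data: AnalysisDataset, query: CausalQuery) -> EffectEstimate:
    """G-computation with one outcome model per exposure arm."""
    return _bootstrap_effect("t_standardization", _standardize_t, data, query)


def _fluctuate(ys, h, offset, tol=1e-12, maxiter=100):
    """One-parameter logistic fluctuation MLE by Newton's method.

    Solves the score equation sum(h * (ys - expit(offset + eps*h))) = 0,
    which is concave in eps. Returns (epsilon, converged).
    """
    eps = 0.0
    for _ in range(maxiter):
        mu = expit(offset + eps * h)
        score = np.sum(h * (ys - mu))
        info = np.sum(h * h * mu * (1.0 - mu))
        if info <= 0:
            break
        step = score / info
        eps += step
        if abs(score) / len(ys) < tol and abs(step) < 1e-10:
            return eps, True
    mu = expit(offset + eps * h)
    return eps, bool(abs(np.sum(h * (ys - mu))) / len(ys) < 1e-8)


def fit_tmle(
    data: AnalysisDataset, query: CausalQuery, ps: PropensityFit
) -> tuple:
    """Targeted maximum likelihood estimation of the ATE.

    The outcome is mapped to (0,1) (gaussian: min-max scaling; binomial:
    identity), an initial outcome regression supplies Q(A,W), and a
    single logistic fluctuation along the clever covariate
    H = A/g - (1-A)/(1-g) updates it so that the empirical mean of the
    efficient influence curve is zero. The SE is the sample SD of that
    curve over sqrt(n), rescaled to the natural outcome scale.

    Returns ``(EffectEstimate, TmleComponents)``.
    """
    warn_msgs: list = []
    y = data.outcome
    a = data.exposure_indicator
    n = len(y)
    if query.family == "binomial":
        lo_b, hi_b = 0.0, 1.0
    else:
        lo_b, hi_b = float(y.min()), float(y.max())
        if hi_b <= lo_b:
            raise DegenerateOutcomeError("outcome is constant; cannot scale to (0,1)")
    ys = (y - lo_b) / (hi_b - lo_b)

    X = _design(data, include_exposure=True)
    res = _fit_glm(ys, X, query.family if query.family == "binomial" else "gaussian",
                   warn_msgs)
    X1 = X.copy()
    X1["__A__"] = 1.0
    X0 = X.copy()
    X0["__A__"] = 0.0
    q_lo, q_hi = _Q_BOUNDS
    q_aw = np.clip(np.asarray(res.predict(X)), q_lo, q_hi)
    q1 = np.clip(np.asarray(res.predict(X1)), q_lo, q_hi)
    q0 = np.clip(np.asarray(res.predict(X0)), q_lo, q_hi)

    g = ps.bounded_scores
    h = a / g - (1.0 - a) / (1.0 - g)
    eps, converged = _fluctuate(ys, h, logit(q_aw))
    if not converged:
        warn_msgs.append("fluctuation did not fully converge; using last iterate")

    q1s = expit(logit(q1) + eps / g)
    q0s = expit(logit(q0) - eps / (1.0 - g))
    qas = expit(logit(q_aw) + eps * h)
    psi_s = float(np.mean(q1s) - np.mean(q0s))
    ic = h * (ys - qas) + q1s - q0s - psi_s

    scale = hi_b - lo_b
    est = scale * psi_s
    se = scale * float(np.std(ic, ddof=1)) / np.sqrt(n)
    lo, hi, p = wald_interval(est, se, query.conf_level)
    effect = EffectEstimate(
        method="tmle",
        estimate=est,
        se=se,
        ci_low=lo,
        ci_high=hi,
        p_value=p,
        s_value=s_value(p),
        reference_level=query.reference_level,
        inference="normal",
        warnings=tuple(warn_msgs),
    )
    components = TmleComponents(
        clever_covariate=h,
        epsilon=float(eps),
        targeted_q1=q1s,
        targeted_q0=q0s,
        influence_curve=ic,
        scale_bounds=(lo_b, hi_b),
    )
    return effect, components


def run_all_estimators(
    data: AnalysisDataset,
    query: CausalQuery,
    estimators: Optional[Sequence[str]] = None,
) -> RunResults:
    """Run the requested estimators (all five by default) in fixed order.

    The propensity model is fit once and shared by IPTW, TMLE and the
    diagnostics. Each estimator's bootstrap uses its own child stream of
    the master seed. Errors from a member estimator are re-raised with
    the estimator's name attached.
    """
    selected = tuple(estimators) if estimators is not None else ESTIMATOR_ORDER
    unknown = [e for e in selected if e not in ESTIMATOR_ORDER]
    if unknown:
        raise EstimationError(f"unknown estimator(s): {', '.join(unknown)}")
    selected = tuple(e for e in ESTIMATOR_ORDER if e in selected)

    ps = estimate_propensity(data, query)
    effects = []
    tmle_components = None
    for name in selected:
        try:
            if name == "outcome_regression":
                effects.append(fit_outcome_regression(data, query))
            elif name == "iptw":
                effects.append(fit_iptw(data, query, ps))
            elif name == "s_standardization":
                effects.append(fit_s_standardization(data, query))
            elif name == "t_standardization":
                effects.append(fit_t_standardization(data, query))
            elif name == "tmle":
                eff, tmle_components = fit_tmle(data, query, ps)
                effects.append(eff)
        except Exception as exc:
            exc.add_note(f"estimator: {ESTIMATOR_LABELS[name]}")
            raise
    points = [e.estimate for e in effects]
    return RunResults(
        effects=tuple(effects),
        propensity=ps,
        tmle_components=tmle_components,
        min_estimate=float(min(points)),
        max_estimate=float(max(points)),
    )
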