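"""Synthetic confounded observational studies with known true ATEs.

Every scenario uses the same 5-covariate layout — W1, W2, W3 standard
normal, W4, W5 Bernoulli(0.5) — so results are comparable across
scenarios.  Exposure is assigned by a logistic model
A ~ Bernoulli(expit(alpha . [1, W])) and the outcome by a scenario-specific
structural model with additive treatment effect tau (on the logit scale
for the binary outcome):

* ``linear``            Y = tau*A + beta.[1,W] + Normal(0, noise_sd); the
                        additive effect makes the marginal ATE equal tau
                        exactly, and both nuisance models are correct.
* ``nonlinear_outcome`` adds W1^2 and W1*W2 terms to the outcome, so an
                        additive outcome regression is misspecified while
                        the propensity model stays correct — the scenario
                        in which estimators should visibly disagree.
* ``poor_overlap``      large propensity coefficients push scores toward
                        0/1 so positivity diagnostics have something to
                        detect.
* ``binary_outcome``    Y ~ Bernoulli(expit(tau*A + beta.[1,W])); the
                        marginal risk difference has no closed form and is
                        supplied by a Monte-Carlo oracle.
* ``randomized``        alpha = 0: exposure independent of covariates.

The oracle in :func:`true_ate_oracle` never estimates anything: it
averages the structural arm contrast E[Y|A=1,W] - E[Y|A=0,W] over fresh
covariate draws, which is exact (zero MC error) for the additive-effect
scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit

from .exceptions import ScenarioError
from .query import CausalQuery

COVARIATE_NAMES = ("w1", "w2", "w3", "w4", "w5")

#: Shared coefficient defaults: index 0 is the intercept, 1..5 follow
#: COVARIATE_NAMES. One source of truth for every scenario and test.
DEFAULT_ALPHA = (0.0, 0.4, -0.3, 0.2, 0.5, -0.4)
DEFAULT_BETA = (1.0, 1.0, -1.0, 0.5, 1.0, -0.5)
POOR_OVERLAP_ALPHA = (0.0, 2.5, -2.0, 1.5, 2.0, -1.5)
#: nonlinear_outcome uses an off-center, steeper propensity in W1: the
#: curvature of expit then correlates exposure with the omitted W1^2 term,
#: so an additive outcome regression is materially biased while the
#: (still correctly specified) propensity model is not.
NONLINEAR_ALPHA = (-0.9, 1.2, -0.4, 0.2, 0.5, -0.4)
BINARY_BETA = (-0.5, 0.8, -0.5, 0.3, 0.6, -0.4)
#: Coefficients of the W1^2 and W1*W2 terms in nonlinear_outcome.
NONLINEAR_GAMMA = (2.0, 1.5)

SCENARIO_NAMES = (
    "linear",
    "nonlinear_outcome",
    "poor_overlap",
    "binary_outcome",
    "randomized",
)


@dataclass(frozen=True)
class SyntheticScenario:
    """A named data-generating process with a known-truth oracle."""

    name: str
    n: int = 2000
    tau: float = 3.0
    alpha: tuple = DEFAULT_ALPHA
    beta: tuple = DEFAULT_BETA
    noise_sd: float = 2.0
    seed: int = 42

    def __post_init__(self):
        if self.name not in SCENARIO_NAMES:
            raise ScenarioError(
                f"unknown scenario {self.name!r}; choose from {SCENARIO_NAMES}"
            )
        if self.n < 10:
            raise ScenarioError("scenario requires n >= 10")
        if self.noise_sd <= 0:
            raise ScenarioError("noise_sd must be positive")


def make_scenario(
    name: str,
    n: int = 2000,
    seed: int = 42,
    tau: Optional[float] = None,
    noise_sd: Optional[float] = None,
) -> SyntheticScenario:
    """Scenario with per-name defaults applied.

    ``binary_outcome`` defaults to tau=1 (a log odds ratio; tau=3 would
    put nearly everyone's risk at the boundary) and uses smaller outcome
    coefficients; ``poor_overlap`` swaps in large propensity
    coefficients; ``randomized`` zeroes them.
    """
    kw = dict(name=name, n=n, seed=seed)
    if name == "poor_overlap":
        kw["alpha"] = POOR_OVERLAP_ALPHA
    elif name == "nonlinear_outcome":
        kw["alpha"] = NONLINEAR_ALPHA
    elif name == "randomized":
        kw["alpha"] = (0.0,) * 6
    elif name == "binary_outcome":
        kw["beta"] = BINARY_BETA
        kw["tau"] = 1.0
    if tau is not None:
        kw["tau"] = tau
    if noise_sd is not None:
        kw["noise_sd"] = noise_sd
    return SyntheticScenario(**kw)


def _draw_covariates(rng: np.random.Generator, n: int) -> np.ndarray:
    w = np.empty((n, 5))
    w[:, 0:3] = rng.standard_normal((n, 3))
    w[:, 3:5] = rng.binomial(1, 0.5, size=(n, 2))
    return w


def _design(w: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(len(w)), w])


def _mean_outcome(scenario: SyntheticScenario, a: np.ndarray, w: np.ndarray):
    """Structural conditional mean E[Y | A=a, W=w] (probability if binary)."""
    lin = _design(w) @ np.asarray(scenario.beta)
    if scenario.name == "nonlinear_outcome":
        g1, g2 = NONLINEAR_GAMMA
        lin = lin + g1 * w[:, 0] ** 2 + g2 * w[:, 0] * w[:, 1]
    if scenario.name == "binary_outcome":
        return expit(scenario.tau * a + lin)
    return scenario.tau * a + lin


def generate(scenario: SyntheticScenario) -> tuple:
    """Draw one dataset; returns ``(DataFrame, truth_record)``.

    The frame has columns w1..w5, A, Y — the same rectangular shape a
    user's CSV would have. The truth record carries the scenario
    parameters and the true marginal ATE (exact for additive-effect
    scenarios, Monte-Carlo with its SE for binary_outcome).
    Deterministic given the scenario seed.
    """
    rng = np.random.default_rng(scenario.seed)
    w = _draw_covariates(rng, scenario.n)
    p_a = expit(_design(w) @ np.asarray(scenario.alpha))
    a = rng.binomial(1, p_a).astype(float)
    mu = _mean_outcome(scenario, a, w)
    if scenario.name == "binary_outcome":
        y = rng.binomial(1, mu).astype(float)
    else:
        y = mu + rng.normal(0.0, scenario.noise_sd, size=scenario.n)
    df = pd.DataFrame(w, columns=COVARIATE_NAMES)
    df["A"] = a.astype(int)
    df["Y"] = y.astype(int) if scenario.name == "binary_outcome" else y
    true_ate, mc_se = true_ate_oracle(scenario)
    truth = {
        "scenario": scenario.name,
        "n": scenario.n,
        "tau": scenario.tau,
        "alpha": list(scenario.alpha),
        "beta": list(scenario.beta),
        "noise_sd": scenario.noise_sd,
        "seed": scenario.seed,
        "true_ate": true_ate,
        "true_ate_mc_se": mc_se,
    }
    return df, truth


def true_ate_oracle(
    scenario: SyntheticScenario, n_oracle: int = 200_000
) -> tuple:
    """True marginal ATE with its Monte-Carlo standard error.

    Averages the structural contrast E[Y|A=1,W] - E[Y|A=0,W] over
    ``n_oracle`` fresh covariate draws; no outcome noise is sampled and
    no model is estimated. For every scenario except binary_outcome the
    contrast is the constant tau, returned exactly with MC error 0.
    """
    if scenario.name != "binary_outcome":
        return float(scenario.tau), 0.0
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=int(scenario.seed), spawn_key=(99,))
    )
    w = _draw_covariates(rng, int(n_oracle))
    diff = _mean_outcome(scenario, np.ones(len(w)), w) - _mean_outcome(
        scenario, np.zeros(len(w)), w
    )
    return float(diff.mean()), float(diff.std(ddof=1) / np.sqrt(len(w)))


def default_query(scenario: SyntheticScenario, **overrides) -> CausalQuery:
    """The natural query for a generated dataset: Y on A adjusting for W."""
    kw = dict(
        outcome_name="Y",
        exposure_name="A",
        adjustment_set=COVARIATE_NAMES,
        family="binomial" if scenario.name == "binary_outcome" else "gaussian",
        seed=scenario.seed,
    )
    kw.update(overrides)
    return CausalQuery(**kw)
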