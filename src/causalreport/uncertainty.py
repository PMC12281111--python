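"""Shared inference machinery: bootstrap, S-values, Wald intervals.

The standardization estimators (and the binomial-family outcome-regression
contrast) have no convenient closed-form variance, so their SE, CI and
p-value come from a nonparametric bootstrap: resample rows with
replacement, refit every model inside the estimator, and summarise the B
replicate estimates.  The CI is the percentile interval and the p-value is
the two-sided sign-crossing proportion

    p = min(1, 2 * min(#{rep <= 0}, #{rep >= 0}) / B),

which can be exactly 0 when every replicate falls on one side of zero —
the corresponding S-value, -log2(p), is then +infinity.

Seeding: one master seed per run; each estimator draws from its own child
stream derived from (master seed, fixed estimator code), so adding or
removing an estimator never perturbs another's replicates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy import stats

from .exceptions import UnstableBootstrapError

#: Fixed per-estimator codes for child-seed derivation. Append only.
STREAM_CODES = {
    "outcome_regression": 1,
    "iptw": 2,
    "s_standardization": 3,
    "t_standardization": 4,
    "tmle": 5,
}


def child_rng(master_seed: int, name: str) -> np.random.Generator:
    """Deterministic child stream for one estimator."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(master_seed), spawn_key=(STREAM_CODES[name],))
    )


@dataclass(frozen=True)
class BootstrapResult:
    """Summary of B nonparametric bootstrap replicates."""

    replicates: np.ndarray
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    B_requested: int
    B_converged: int


def bootstrap(
    estimator: Callable,
    data,
    query,
    B: int,
    rng: np.random.Generator,
    continuity_correction: bool = False,
) -> BootstrapResult:
    """Nonparametric bootstrap of a point-estimate procedure.

    Parameters
    ----------
    estimator : callable(AnalysisDataset, CausalQuery) -> float
        Refit from scratch on each resample.
    B : int
        Number of resamples, >= 2.
    rng : numpy Generator
        Drives the resampling; pass a child stream for determinism.
    continuity_correction : bool
        If True, use (k + 1) / (B + 1) instead of k / B for the sign
        proportions, so p can never be exactly 0 (and S never infinite).

    Raises
    ------
    UnstableBootstrapError
        If more than 20% of replicates fail to produce an estimate.
    """
    if B < 2:
        raise ValueError("B must be at least 2")
    n = len(data.df)
    reps = []
    failed = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        try:
            reps.append(float(estimator(data.resample(idx), query)))
        except Exception:
            failed += 1
    if failed > 0.2 * B:
        raise UnstableBootstrapError(
            f"{failed}/{B} bootstrap replicates failed; estimates unstable"
        )
    reps = np.asarray(reps)
    b = len(reps)
    alpha = 1.0 - query.conf_level
    lo, hi = np.quantile(reps, [alpha / 2.0, 1.0 - alpha / 2.0])
    n_le = int(np.sum(reps <= 0.0))
    n_ge = int(np.sum(reps >= 0.0))
    if continuity_correction:
        p = 2.0 * min(n_le + 1, n_ge + 1) / (b + 1)
    else:
        p = 2.0 * min(n_le, n_ge) / b
    return BootstrapResult(
        replicates=reps,
        se=float(np.std(reps, ddof=1)),
        ci_low=float(lo),
        ci_high=float(hi),
        p_value=float(min(p, 1.0)),
        B_requested=B,
        B_converged=b,
    )


def s_value(p: float) -> float:
    """Surprisal of a p-value in bits: -log2(p).

    0 at p=1, 1 at p=0.5, +infinity at p=0. Measures the information
    against the test hypothesis contained in the p-value.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value must lie in [0, 1], got {p}")
    if p == 0.0:
        return float("inf")
    return float(-np.log2(p))


def wald_interval(
    estimate: float,
    se: float,
    conf_level: float = 0.95,
    df: Optional[float] = None,
) -> tuple:
    """Symmetric Wald interval and two-sided p-value.

    Uses the t distribution with ``df`` degrees of freedom when supplied
    (model-based coefficient inference), the standard normal otherwise.

    Returns ``(low, high, p)``.
    """
    if se <= 0:
        raise ValueError(f"se must be positive, got {se}")
    z = abs(estimate) / se
    alpha = 1.0 - conf_level
    if df is not None:
        q = stats.t.ppf(1.0 - alpha / 2.0, df)
        p = 2.0 * stats.t.sf(z, df)
    else:
        q = stats.norm.ppf(1.0 - alpha / 2.0)
        p = 2.0 * stats.norm.sf(z)
    return (estimate - q * se, estimate + q * se, float(p))
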