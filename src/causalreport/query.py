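"""Causal query definition, dataset validation, and estimand rendering.

A :class:`CausalQuery` states the causal question: which column is the
outcome Y, which is the binary exposure A, which covariates L form the
adjustment set, and on which scale (gaussian or binomial) the outcome
lives.  :func:`validate_query` turns a raw table plus a query into an
:class:`AnalysisDataset` — complete cases on the query columns, exposure
coerced to the two stated levels — and :func:`render_estimand` writes the
counterfactual contrast E[Y^A=a1] - E[Y^A=a0] that every estimator
downstream targets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    EmptyDataError,
    InputError,
    MissingColumnError,
    UnsupportedExposureError,
)

logger = logging.getLogger(__name__)

FAMILIES = ("gaussian", "binomial")

#: Order and labels of the estimators in the effect table.
ESTIMATOR_ORDER = (
    "outcome_regression",
    "iptw",
    "s_standardization",
    "t_standardization",
    "tmle",
)

ESTIMATOR_LABELS = {
    "outcome_regression": "outcome regression",
    "iptw": "IPTW",
    "s_standardization": "S-standardization",
    "t_standardization": "T-standardization",
    "tmle": "TMLE",
}

EMPTY_SET_MARKER = "(none — marginal estimand)"


@dataclass(frozen=True)
class CausalQuery:
    """The user's causal question.

    Parameters
    ----------
    outcome_name, exposure_name : str
        Column names of the outcome Y and the binary exposure A.
    adjustment_set : sequence of str
        Covariate columns L, in user order.  May be empty, in which case
        the estimand is marginal.
    family : {"gaussian", "binomial"}
        Outcome model family; binomial requires a two-valued outcome and
        reports effects as risk differences.
    exposure_level, reference_level
        Values of A defining the "treated" and "control" arms.  When
        unspecified they default to the larger / smaller of the two
        observed exposure values.
    conf_level : float
        Two-sided confidence level, default 0.95.
    bootstrap_reps : int
        Resamples B for bootstrap-based inference, default 1000.
    seed : int
        Master seed; every random stream in a run derives from it.
    ps_bound : float
        Truncation bound g_min for propensity scores, default 0.025.
    """

    outcome_name: str
    exposure_name: str
    adjustment_set: tuple = ()
    family: str = "gaussian"
    exposure_level: object = None
    reference_level: object = None
    conf_level: float = 0.95
    bootstrap_reps: int = 1000
    seed: int = 42
    ps_bound: float = 0.025

    def __post_init__(self):
        object.__setattr__(self, "adjustment_set", tuple(self.adjustment_set))
        names = [self.outcome_name, self.exposure_name, *self.adjustment_set]
        if len(set(names)) != len(names):
            raise InputError(
                "outcome, exposure and adjustment-set names must be distinct; "
                f"got {names}"
            )
        if self.family not in FAMILIES:
            raise InputError(f"family must be one of {FAMILIES}, got {self.family!r}")
        if not 0.0 < self.conf_level < 1.0:
            raise InputError("conf_level must lie in (0, 1)")
        if self.bootstrap_reps < 2:
            raise InputError("bootstrap_reps must be at least 2")
        if not 0.0 < self.ps_bound < 0.5:
            raise InputError("ps_bound must lie in (0, 0.5)")
        if (
            self.exposure_level is not None
            and self.reference_level is not None
            and self.exposure_level == self.reference_level
        ):
            raise InputError("exposure_level and reference_level must differ")

    @property
    def columns(self) -> list:
        return [self.outcome_name, self.exposure_name, *self.adjustment_set]


@dataclass(frozen=True)
class AnalysisDataset:
    """Validated complete-case data restricted to the query columns.

    ``df`` holds one row per retained unit; the exposure column contains
    exactly the two levels of the resolved query.  ``query`` is the query
    with exposure/reference levels resolved.
    """

    df: pd.DataFrame
    query: CausalQuery
    n_total: int
    n_complete: int

    @property
    def n_dropped(self) -> int:
        return self.n_total - self.n_complete

    @property
    def exposure_indicator(self) -> np.ndarray:
        """0/1 array: 1 where A equals the exposure (treated) level."""
        a = self.df[self.query.exposure_name]
        return (a == self.query.exposure_level).to_numpy(dtype=float)

    @property
    def outcome(self) -> np.ndarray:
        return self.df[self.query.outcome_name].to_numpy(dtype=float)

    def covariate_matrix(self) -> pd.DataFrame:
        """Design columns for the adjustment set, no intercept.

        Numeric covariates enter as-is; non-numeric covariates are
        reference-cell dummy coded with the first level in sorted order
        as reference — identically for every estimator.
        """
        pieces = []
        for col in self.query.adjustment_set:
            s = self.df[col]
            if pd.api.types.is_numeric_dtype(s):
                pieces.append(s.astype(float).rename(col))
            else:
                levels = sorted(s.astype(str).unique())
                for lev in levels[1:]:
                    pieces.append(
                        (s.astype(str) == lev).astype(float).rename(f"{col}[{lev}]")
                    )
        if not pieces:
            return pd.DataFrame(index=self.df.index)
        return pd.concat(pieces, axis=1)

    def resample(self, index: np.ndarray) -> "AnalysisDataset":
        """Row-resampled copy (used by the bootstrap)."""
        new = self.df.iloc[index].reset_index(drop=True)
        return replace(self, df=new, n_total=len(new), n_complete=len(new))


@dataclass(frozen=True)
class Estimand:
    """The target quantity, rendered in counterfactual notation."""

    label: str
    expression: str
    adjustment_text: str
    interpretation: str


def validate_query(query: CausalQuery, table: pd.DataFrame) -> AnalysisDataset:
    """Validate ``table`` against ``query`` and return the analysis dataset.

    Performs complete-case filtering on the query columns, resolves the
    exposure contrast levels, and enforces the binary-exposure and (for
    binomial) two-valued-outcome contracts.

    Raises
    ------
    MissingColumnError, UnsupportedExposureError, EmptyDataError, InputError
    """
    if len(table) == 0:
        raise EmptyDataError("input table has no rows")
    missing = [c for c in query.columns if c not in table.columns]
    if missing:
        raise MissingColumnError(
            f"columns not found in data: {', '.join(missing)}"
        )

    sub = table.loc[:, query.columns]
    n_total = len(sub)
    sub = sub.dropna().reset_index(drop=True)
    n_complete = len(sub)
    if n_complete == 0:
        raise EmptyDataError("no complete cases on the query columns")
    if n_complete < n_total:
        logger.info(
            "dropped %d of %d rows with missing values in query columns",
            n_total - n_complete,
            n_total,
        )

    observed = sorted(pd.unique(sub[query.exposure_name]).tolist())
    if len(observed) != 2:
        raise UnsupportedExposureError(
            f"exposure {query.exposure_name!r} must have exactly 2 observed "
            f"levels among complete cases, found {len(observed)}: {observed}"
        )
    ref, exp_lvl = query.reference_level, query.exposure_level
    if ref is None and exp_lvl is None:
        ref, exp_lvl = observed[0], observed[1]
    elif ref is None:
        rest = [v for v in observed if v != exp_lvl]
        if len(rest) != 1:
            raise UnsupportedExposureError(
                f"exposure level {exp_lvl!r} not among observed levels {observed}"
            )
        ref = rest[0]
    elif exp_lvl is None:
        rest = [v for v in observed if v != ref]
        if len(rest) != 1:
            raise UnsupportedExposureError(
                f"reference level {ref!r} not among observed levels {observed}"
            )
        exp_lvl = rest[0]
    if set(observed) != {ref, exp_lvl}:
        raise UnsupportedExposureError(
            f"observed exposure levels {observed} do not match the requested "
            f"contrast {exp_lvl!r} vs {ref!r}"
        )

    if query.family == "binomial":
        y_vals = pd.unique(sub[query.outcome_name]).tolist()
        if len(y_vals) != 2:
            raise InputError(
                "binomial family requires an outcome with exactly two observed "
                f"values; found {len(y_vals)}"
            )
        lo, hi = sorted(y_vals)
        if not (lo == 0 and hi == 1):
            sub[query.outcome_name] = (sub[query.outcome_name] == hi).astype(float)
            logger.info("recoded binomial outcome: %r -> 1, %r -> 0", hi, lo)

    resolved = replace(query, exposure_level=exp_lvl, reference_level=ref)
    return AnalysisDataset(df=sub, query=resolved, n_total=n_total, n_complete=n_complete)


_INTERPRETATION = (
    "The estimand is the Average Treatment Effect (ATE): the difference "
    "between the mean of the counterfactual outcome {y!r} had every unit in "
    "the population received exposure {a!r} = {lvl!r} and the mean had every "
    "unit received {a!r} = {ref!r}. It is a population-level contrast of "
    "potential outcomes, not an association: it refers to the same units "
    "under two different interventions. Identification from observational "
    "data additionally requires the causal assumptions listed in this "
    "report, with confounding addressed through the adjustment set: {adj}."
)


def render_estimand(query: CausalQuery) -> Estimand:
    """Render the ATE estimand for a (resolved) query.

    A pure function of the query: identical queries yield byte-identical
    expressions.
    """
    if query.exposure_level is None or query.reference_level is None:
        raise InputError(
            "estimand requires resolved exposure/reference levels; "
            "run validate_query first or set them explicitly"
        )
    y, a = query.outcome_name, query.exposure_name
    expr = (
        f"E[{y}^{a}={query.exposure_level}] - E[{y}^{a}={query.reference_level}]"
    )
    adj = ", ".join(query.adjustment_set) if query.adjustment_set else EMPTY_SET_MARKER
    interp = _INTERPRETATION.format(
        y=y, a=a, lvl=query.exposure_level, ref=query.reference_level, adj=adj
    )
    return Estimand(
        label="Average Treatment Effect",
        expression=expr,
        adjustment_text=adj,
        interpretation=interp,
    )
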