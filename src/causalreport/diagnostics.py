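"""Assumption-linked diagnostics.

Positivity is probed with the per-arm range of the estimated propensity
score and with overlap histograms/densities; conditional exchangeability
is probed indirectly with covariate balance before and after
inverse-probability weighting, measured by the standardized mean
difference

    d = (m1 - m0) / sqrt((s1^2 + s0^2) / 2),

computed per continuous covariate and per non-reference level of each
categorical covariate (proportions in place of means).  |d| > 0.1 is the
conventional imbalance flag.

The propensity summary deliberately uses the *untruncated* scores:
truncation exists to stabilize weights, not to hide extreme scores from
the person judging positivity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .estimators import PropensityFit
from .query import AnalysisDataset, CausalQuery

#: Conventional |SMD| threshold above which a covariate is flagged.
SMD_THRESHOLD = 0.1


@dataclass(frozen=True)
class PsSummaryTable:
    """Min/max of the propensity score within each observed exposure arm."""

    label: str
    table: pd.DataFrame  # index: observed exposure level; columns: min, max

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "rows": {
                str(idx): {"min": float(r["min"]), "max": float(r["max"])}
                for idx, r in self.table.iterrows()
            },
        }


@dataclass(frozen=True)
class OverlapPlotData:
    """Histogram + density of the bounded propensity score per arm."""

    bin_edges: np.ndarray
    counts: dict  # exposure level -> counts per bin
    density_grid: np.ndarray
    densities: dict  # exposure level -> density values (or None)

    def to_dict(self) -> dict:
        return {
            "bin_edges": self.bin_edges.tolist(),
            "counts": {str(k): v.tolist() for k, v in self.counts.items()},
            "density_grid": self.density_grid.tolist(),
            "densities": {
                str(k): (v.tolist() if v is not None else None)
                for k, v in self.densities.items()
            },
        }


def smd(
    values: np.ndarray,
    treated: np.ndarray,
    weights: Optional[np.ndarray] = None,
) -> float:
    """Signed standardized mean difference, treated minus control.

    ``weights`` (if given) are normalized within each arm to sum to the
    arm's size, i.e. treated as frequency weights, which keeps the
    weighted variance stable in small samples.  Constant covariates
    (zero pooled SD) return 0 rather than raising: there is nothing to
    balance.
    """
    values = np.asarray(values, dtype=float)
    treated = np.asarray(treated, dtype=bool)
    if treated.all() or (~treated).all():
        raise ValueError("both arms must be non-empty")
    if weights is None:
        weights = np.ones_like(values)
    weights = np.asarray(weights, dtype=float)

    stats = {}
    for arm, mask in ((1, treated), (0, ~treated)):
        w = weights[mask]
        x = values[mask]
        w = w * (len(x) / w.sum())  # frequency normalization
        m = np.sum(w * x) / np.sum(w)
        denom = np.sum(w) - 1.0
        var = np.sum(w * (x - m) ** 2) / denom if denom > 0 else 0.0
        stats[arm] = (m, var)
    m1, v1 = stats[1]
    m0, v0 = stats[0]
    pooled = np.sqrt((v1 + v0) / 2.0)
    if pooled == 0.0:
        return 0.0
    return float((m1 - m0) / pooled)


def balance_table(
    data: AnalysisDataset, query: CausalQuery, ps: PropensityFit
) -> pd.DataFrame:
    """SMDs for every adjustment covariate, raw and IPT-weighted.

    One row per continuous covariate, one per non-reference level of
    each categorical covariate. Columns: ``smd_raw``, ``smd_weighted``,
    and the corresponding |d| > 0.1 flags.
    """
    a = data.exposure_indicator.astype(bool)
    g = ps.bounded_scores
    w = np.where(a, 1.0 / g, 1.0 / (1.0 - g))
    X = data.covariate_matrix()
    rows = []
    for col in X.columns:
        x = X[col].to_numpy(dtype=float)
        d_raw = smd(x, a)
        d_wt = smd(x, a, weights=w)
        rows.append(
            {
                "covariate": col,
                "smd_raw": d_raw,
                "smd_weighted": d_wt,
                "imbalanced_raw": abs(d_raw) > SMD_THRESHOLD,
                "imbalanced_weighted": abs(d_wt) > SMD_THRESHOLD,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "covariate",
            "smd_raw",
            "smd_weighted",
            "imbalanced_raw",
            "imbalanced_weighted",
        ],
    )


def ps_summary(
    ps: PropensityFit, data: AnalysisDataset, query: CausalQuery
) -> PsSummaryTable:
    """Range of the (untruncated) propensity score within each exposure arm.

    Exact values are retained in the table; rendering rounds to 4
    decimals. A treated-arm minimum near 0 or control-arm maximum near 1
    signals positivity problems.
    """
    a = data.exposure_indicator.astype(bool)
    rows = {}
    for level, mask in (
        (query.reference_level, ~a),
        (query.exposure_level, a),
    ):
        s = ps.scores[mask]
        rows[level] = {"min": float(s.min()), "max": float(s.max())}
    table = pd.DataFrame.from_dict(rows, orient="index")
    return PsSummaryTable(label=f"PS range for {query.exposure_level}", table=table)


def overlap_data(
    ps: PropensityFit,
    data: AnalysisDataset,
    query: CausalQuery,
    n_bins: int = 20,
) -> OverlapPlotData:
    """Histogram counts and kernel-density points of bounded scores per arm.

    Bin edges are shared across arms and span [0, 1] so the two
    histograms are directly comparable.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    from scipy.stats import gaussian_kde

    a = data.exposure_indicator.astype(bool)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    grid = np.linspace(0.0, 1.0, 101)
    counts, densities = {}, {}
    for level, mask in (
        (query.reference_level, ~a),
        (query.exposure_level, a),
    ):
        s = ps.bounded_scores[mask]
        counts[level], _ = np.histogram(s, bins=edges)
        try:
            densities[level] = gaussian_kde(s)(grid)
        except (np.linalg.LinAlgError, ValueError):
            densities[level] = None  # degenerate (e.g. constant) scores
    return OverlapPlotData(
        bin_edges=edges, counts=counts, density_grid=grid, densities=densities
    )
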