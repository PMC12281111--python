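"""Report assembly and rendering.

A :class:`CausalReport` bundles everything a causal analysis should
disclose: the estimand, the effect table from all estimators (never the
adjustment-covariate coefficients, which invite the Table 2 fallacy), a
prompt to examine disagreement between estimators, the six identification
assumptions templated to the user's variable names, and the positivity
and balance diagnostics.

The saved output is a nested tree addressed by ``$``-separated path
segments (``$Assumptions$positivity$ps_table``); the assumption texts
reference those paths, and :func:`resolve_path` checks that every
referenced path exists.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import asdict, dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import _templates as T
from .diagnostics import OverlapPlotData, PsSummaryTable
from .estimators import EffectEstimate, PropensityFit, RunResults
from .exceptions import CausalReportError
from .query import AnalysisDataset, CausalQuery, Estimand, render_estimand


class AssemblyError(CausalReportError):
    """A required upstream component is missing from report assembly."""


@dataclass(frozen=True)
class CausalReport:
    """Hierarchical report of one causal analysis."""

    estimand: Estimand
    effects: tuple
    exposure_name: str
    exposure_level: object
    reference_level: object
    disagreement_note: Optional[str]
    substantial_disagreement: Optional[bool]
    assumptions: dict
    ps_table: PsSummaryTable
    balance: pd.DataFrame
    overlap: OverlapPlotData
    methods_paragraph: str
    n_total: int
    n_complete: int
    seed: int
    conf_level: float
    warnings: tuple = ()

    @property
    def reference_level_note(self) -> str:
        return f"Reference exposure level: {self.reference_level}"


def render_assumptions(query: CausalQuery) -> dict:
    """The six identification assumptions, templated to the query.

    Returns the keyed subtree stored under ``$Assumptions``: texts in the
    fixed order exchangeability, positivity, consistency, no_interference,
    no_measurement_error, well_specified_models, plus long-form
    explanation entries. An empty adjustment set switches the
    exchangeability and positivity texts to their marginal variants.
    """
    adj = ", ".join(query.adjustment_set)
    sub = dict(
        adj=adj,
        a=query.exposure_name,
        y=query.outcome_name,
        lvl=query.exposure_level,
        ref=query.reference_level,
    )
    marginal = len(query.adjustment_set) == 0
    exch = (T.EXCHANGEABILITY_MARGINAL if marginal else T.EXCHANGEABILITY).format(**sub)
    posi = (T.POSITIVITY_MARGINAL if marginal else T.POSITIVITY).format(**sub)
    return {
        "exchangeability": {
            "text": exch,
            "explanation": T.EXPLANATION_EXCHANGEABILITY,
        },
        "positivity": {
            "text": posi,
            "explanation": T.EXPLANATION_POSITIVITY,
        },
        "consistency": {
            "text": T.CONSISTENCY.format(**sub),
            "explanation": T.EXPLANATION_CONSISTENCY,
        },
        "no_interference": {"text": T.NO_INTERFERENCE.format(**sub)},
        "no_measurement_error": {
            "text": T.NO_MEASUREMENT_ERROR.format(**sub),
            "explanation": T.EXPLANATION_NO_MEASUREMENT_ERROR,
        },
        "well_specified_models": {"text": T.WELL_SPECIFIED.format(**sub)},
    }


def methods_paragraph(query: CausalQuery) -> str:
    """One paragraph stating all six assumptions with the user's names."""
    adj = ", ".join(query.adjustment_set)
    if query.adjustment_set:
        adj_clause = f", adjusting for {adj}"
        adj_or_nothing = f"adjustment for {adj}"
    else:
        adj_clause = ", without covariate adjustment (marginal estimand)"
        adj_or_nothing = "the comparison without adjustment"
    return T.METHODS_PARAGRAPH.format(
        a=query.exposure_name,
        y=query.outcome_name,
        lvl=query.exposure_level,
        ref=query.reference_level,
        adj_clause=adj_clause,
        adj_or_nothing=adj_or_nothing,
    )


def assemble_report(
    data: AnalysisDataset,
    query: CausalQuery,
    results: RunResults,
    ps_table: PsSummaryTable,
    balance: pd.DataFrame,
    overlap: OverlapPlotData,
) -> CausalReport:
    """Assemble the full report from upstream results.

    Ordering is deterministic: estimand, effect table, reference note,
    disagreement note, assumptions, diagnostics. The disagreement note is
    suppressed when fewer than two estimators ran; it is marked
    *substantial* when the min-max spread exceeds twice the smallest SE.
    """
    for name, obj in (
        ("data", data),
        ("query", query),
        ("results", results),
        ("ps_table", ps_table),
        ("balance", balance),
        ("overlap", overlap),
    ):
        if obj is None:
            raise AssemblyError(f"missing upstream component: {name}")

    estimand = render_estimand(query)
    if len(results.effects) >= 2:
        note = T.DISAGREEMENT_NOTE.format(
            low=results.min_estimate, high=results.max_estimate
        )
        spread = results.max_estimate - results.min_estimate
        substantial = bool(spread > 2.0 * min(e.se for e in results.effects))
    else:
        note, substantial = None, None

    warn = list(results.propensity.warnings)
    for e in results.effects:
        warn.extend(f"{e.label}: {w}" for w in e.warnings)

    return CausalReport(
        estimand=estimand,
        effects=results.effects,
        exposure_name=query.exposure_name,
        exposure_level=query.exposure_level,
        reference_level=query.reference_level,
        disagreement_note=note,
        substantial_disagreement=substantial,
        assumptions=render_assumptions(query),
        ps_table=ps_table,
        balance=balance,
        overlap=overlap,
        methods_paragraph=methods_paragraph(query),
        n_total=data.n_total,
        n_complete=data.n_complete,
        seed=query.seed,
        conf_level=query.conf_level,
        warnings=tuple(warn),
    )


# --- serialization ---------------------------------------------------------


def _effect_to_dict(e: EffectEstimate) -> dict:
    d = asdict(e)
    d["s_value"] = "Inf" if math.isinf(e.s_value) else e.s_value
    return d


def _effect_from_dict(d: dict) -> EffectEstimate:
    d = dict(d)
    if d["s_value"] == "Inf":
        d["s_value"] = float("inf")
    return EffectEstimate(**d)


def report_to_dict(report: CausalReport) -> dict:
    """Serialize to the nested ``$``-addressable tree (JSON-safe)."""
    assumptions = {k: dict(v) for k, v in report.assumptions.items()}
    assumptions["exchangeability"]["covariate_balance"] = report.balance.to_dict(
        orient="records"
    )
    assumptions["positivity"]["ps_table"] = report.ps_table.to_dict()
    assumptions["positivity"]["plots"] = report.overlap.to_dict()
    return {
        "Estimand": {
            "label": report.estimand.label,
            "expression": report.estimand.expression,
            "adjustment_set": report.estimand.adjustment_text,
        },
        "Estimand_interpretation": report.estimand.interpretation,
        "Treatment_effect": [_effect_to_dict(e) for e in report.effects],
        "Reference_exposure_level": report.reference_level,
        "Exposure": {
            "name": report.exposure_name,
            "exposure_level": report.exposure_level,
            "reference_level": report.reference_level,
        },
        "Disagreement": {
            "note": report.disagreement_note,
            "substantial": report.substantial_disagreement,
        },
        "Assumptions": assumptions,
        "Methods_paragraph": report.methods_paragraph,
        "Sample": {"n_total": report.n_total, "n_complete": report.n_complete},
        "Settings": {"seed": report.seed, "conf_level": report.conf_level},
        "Warnings": list(report.warnings),
    }


def report_from_dict(d: dict) -> CausalReport:
    """Inverse of :func:`report_to_dict` (structural round trip)."""
    assumptions = {k: dict(v) for k, v in d["Assumptions"].items()}
    balance_records = assumptions["exchangeability"].pop("covariate_balance")
    ps_dict = assumptions["positivity"].pop("ps_table")
    overlap_dict = assumptions["positivity"].pop("plots")

    balance = pd.DataFrame(
        balance_records,
        columns=[
            "covariate",
            "smd_raw",
            "smd_weighted",
            "imbalanced_raw",
            "imbalanced_weighted",
        ],
    )
    ps_rows = pd.DataFrame.from_dict(
        {k: v for k, v in ps_dict["rows"].items()}, orient="index"
    )
    ps_table = PsSummaryTable(label=ps_dict["label"], table=ps_rows)
    overlap = OverlapPlotData(
        bin_edges=np.asarray(overlap_dict["bin_edges"]),
        counts={k: np.asarray(v) for k, v in overlap_dict["counts"].items()},
        density_grid=np.asarray(overlap_dict["density_grid"]),
        densities={
            k: (np.asarray(v) if v is not None else None)
            for k, v in overlap_dict["densities"].items()
        },
    )
    return CausalReport(
        estimand=Estimand(
            label=d["Estimand"]["label"],
            expression=d["Estimand"]["expression"],
            adjustment_text=d["Estimand"]["adjustment_set"],
            interpretation=d["Estimand_interpretation"],
        ),
        effects=tuple(_effect_from_dict(e) for e in d["Treatment_effect"]),
        exposure_name=d["Exposure"]["name"],
        exposure_level=d["Exposure"]["exposure_level"],
        reference_level=d["Exposure"]["reference_level"],
        disagreement_note=d["Disagreement"]["note"],
        substantial_disagreement=d["Disagreement"]["substantial"],
        assumptions=assumptions,
        ps_table=ps_table,
        balance=balance,
        overlap=overlap,
        methods_paragraph=d["Methods_paragraph"],
        n_total=d["Sample"]["n_total"],
        n_complete=d["Sample"]["n_complete"],
        seed=d["Settings"]["seed"],
        conf_level=d["Settings"]["conf_level"],
        warnings=tuple(d["Warnings"]),
    )


def save_report(report: CausalReport, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report_to_dict(report), fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_report(path) -> CausalReport:
    with open(path, encoding="utf-8") as fh:
        return report_from_dict(json.load(fh))


def resolve_path(tree: dict, dollar_path: str):
    """Resolve a ``$Assumptions$positivity$ps_table``-style path.

    Raises KeyError when a segment is absent, so link integrity between
    assumption texts and the saved tree can be checked mechanically.
    """
    node = tree
    for segment in dollar_path.strip().lstrip("$").split("$"):
        node = node[segment]
    return node


def referenced_paths(report: CausalReport) -> list:
    """All ``$``-paths mentioned in the report's assumption texts."""
    pat = re.compile(r"\$[A-Za-z_$]+")
    found = []
    texts = [v["text"] for v in report.assumptions.values()]
    texts.append(T.ESTIMAND_POINTER)
    for t in texts:
        found.extend(m.rstrip("$.") for m in pat.findall(t))
    return sorted(set(found))


# --- text rendering --------------------------------------------------------


def _fmt(x: float, nd: int) -> str:
    if isinstance(x, float) and math.isinf(x):
        return "Inf"
    return f"{x:.{nd}f}"


def render_text(report: CausalReport) -> str:
    """Printable report: a pure function of the assembled report.

    Rounding follows the package convention: estimates, SEs and CI
    bounds to 3 decimals, p-values to 3 decimals (so a tiny p prints as
    0.000 while the exact value stays in the saved report), S-values to
    3 decimals with infinity printed as ``Inf``, propensity scores to 4
    decimals.
    """
    lines = []
    lines.append(f"Estimand: {report.estimand.label}")
    lines.append(report.estimand.expression)
    lines.append(f"Adjustment set: {report.estimand.adjustment_text}")
    lines.append(T.ESTIMAND_POINTER)
    lines.append("")
    lines.append("Treatment effect:")
    lines.append("")

    cl = int(round(report.conf_level * 100))
    headers = [
        "Estimate",
        "Std. error",
        "P-value",
        "S-value",
        f"{cl}% CI lower",
        f"{cl}% CI upper",
    ]
    rows = []
    for e in report.effects:
        rows.append(
            (
                f"{report.exposure_name}{report.exposure_level} {e.label}",
                [
                    _fmt(e.estimate, 3),
                    _fmt(e.se, 3),
                    _fmt(e.p_value, 3),
                    _fmt(e.s_value, 3),
                    _fmt(e.ci_low, 3),
                    _fmt(e.ci_high, 3),
                ],
            )
        )
    label_w = max(len(r[0]) for r in rows)
    col_ws = [
        max(len(h), max(len(r[1][j]) for r in rows)) for j, h in enumerate(headers)
    ]
    lines.append(
        " " * label_w + "  " + "  ".join(h.rjust(w) for h, w in zip(headers, col_ws))
    )
    for label, vals in rows:
        lines.append(
            label.ljust(label_w)
            + "  "
            + "  ".join(v.rjust(w) for v, w in zip(vals, col_ws))
        )
    lines.append("")
    lines.append(report.reference_level_note)
    if report.disagreement_note:
        lines.append("")
        lines.append(report.disagreement_note)
    lines.append("")
    lines.append(T.ASSUMPTIONS_PREAMBLE)
    lines.append("")
    for key in (
        "exchangeability",
        "positivity",
        "consistency",
        "no_interference",
        "no_measurement_error",
        "well_specified_models",
    ):
        lines.append(report.assumptions[key]["text"])
        if key == "positivity":
            lines.append("")
            lines.append("Note: PS=propensity score")
            lines.append(f"  {report.ps_table.label}")
            for lvl, row in report.ps_table.table.iterrows():
                lines.append(
                    f"  observed exposure: {lvl} "
                    f"{row['min']:.4f}, {row['max']:.4f}"
                )
        lines.append("")
    if report.n_total > report.n_complete:
        lines.append(
            f"Note: {report.n_total - report.n_complete} of {report.n_total} rows "
            "were dropped (missing values in analysis columns)."
        )
        lines.append("")
    for w in report.warnings:
        lines.append(f"Warning: {w}")
    return "\n".join(lines).rstrip() + "\n"
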