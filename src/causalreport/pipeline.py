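"""One-call pipeline: validate, estimate, diagnose, assemble."""

from __future__ import annotations

from typing import Optional, Sequence

import pandas as pd

from .diagnostics import balance_table, overlap_data, ps_summary
from .estimators import run_all_estimators
from .query import CausalQuery, validate_query
from .report import CausalReport, assemble_report


def analyze(
    table: pd.DataFrame,
    query: CausalQuery,
    estimators: Optional[Sequence[str]] = None,
) -> CausalReport:
    """Run a complete causal analysis and return the assembled report.

    Equivalent to validate_query -> run_all_estimators -> diagnostics ->
    assemble_report. ``estimators`` restricts the effect table to a
    subset of the five methods (fixed order is preserved).
    """
    data = validate_query(query, table)
    query = data.query  # resolved exposure/reference levels
    results = run_all_estimators(data, query, estimators=estimators)
    ps = results.propensity
    return assemble_report(
        data=data,
        query=query,
        results=results,
        ps_table=ps_summary(ps, data, query),
        balance=balance_table(data, query, ps),
        overlap=overlap_data(ps, data, query),
    )
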