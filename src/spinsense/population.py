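"""Cohort-level aggregation of per-cell rotation calls.

Cells are grouped by experimental condition — non-capacitating or
capacitating medium, each at low or high viscosity — and the per-condition
counts and percentages of CCW, CW and non-rotating calls are tabulated, the
shape in which population results of this kind are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .detection import RotationCall

__all__ = [
    "CONDITIONS",
    "CohortRecord",
    "aggregate",
    "summed_observation_time",
]

CONDITIONS = ("noncap_low", "noncap_high", "cap_low", "cap_high")

_DIRECTION_COLUMNS = {"ccw": "n_ccw", "cw": "n_cw", "non-rotating": "n_nonrotating"}


@dataclass(frozen=True)
class CohortRecord:
    """One analysed cell: id, condition label and its rotation call."""

    cell_id: str
    condition: str
    call: RotationCall


def aggregate(records: list[CohortRecord]) -> pd.DataFrame:
    """Per-condition counts and percentages of rotation calls.

    Returns a DataFrame indexed by condition (plus a ``total`` row) with
    integer counts, full-precision percentages (``pct_*``) and a
    ``n_low_confidence`` audit column for non-rotating calls that were
    demoted for low confidence.  Percentages are conventionally displayed
    rounded to the nearest integer; full precision is retained here.
    """
    if not records:
        raise ValueError("no records to aggregate")
    bad = [r.cell_id for r in records if r.condition not in CONDITIONS]
    if bad:
        raise ValueError(
            f"unknown condition for cell(s) {', '.join(bad)}; valid: {', '.join(CONDITIONS)}"
        )
    rows = []
    for cond in CONDITIONS:
        sub = [r for r in records if r.condition == cond]
        row = {"condition": cond, "n_total": len(sub), "n_ccw": 0, "n_cw": 0,
               "n_nonrotating": 0, "n_low_confidence": 0}
        for r in sub:
            row[_DIRECTION_COLUMNS[r.call.direction]] += 1
            if r.call.low_confidence:
                row["n_low_confidence"] += 1
        rows.append(row)
    df = pd.DataFrame(rows).set_index("condition")
    total = df.sum(axis=0)
    total.name = "total"
    df = pd.concat([df, total.to_frame().T])
    for d in ("ccw", "cw", "nonrotating"):
        df[f"pct_{d}"] = 100.0 * df[f"n_{d}"] / df["n_total"].where(df["n_total"] > 0)
    return df


def summed_observation_time(n_cells: int, per_cell_duration_s: float) -> int:
    """Total analysed time in whole minutes for ``n_cells`` records."""
    if n_cells <= 0 or per_cell_duration_s <= 0:
        raise ValueError("n_cells and per_cell_duration_s must be positive")
    return int(round(n_cells * per_cell_duration_s / 60.0))
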