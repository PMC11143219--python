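"""Bone-turnover classification from K_i by fixed clearance cutoffs.

Net plasma clearance below 0.038 mL/min/mL indicates low turnover, above
0.055 mL/min/mL high turnover, and the closed interval between the two
cutoffs normal turnover.  Boundary values are assigned to "normal"
(strict inequalities for low/high).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = ["TurnoverCutoffs", "DEFAULT_CUTOFFS", "CATEGORIES", "classify_turnover", "classify_cohort"]

CATEGORIES = ("low", "normal", "high")


@dataclass(frozen=True)
class TurnoverCutoffs:
    """Clearance thresholds (mL/min/mL) separating turnover categories."""

    low_below: float = 0.038
    high_above: float = 0.055

    def __post_init__(self) -> None:
        if not 0 < self.low_below < self.high_above:
            raise ValueError("require 0 < low_below < high_above")


DEFAULT_CUTOFFS = TurnoverCutoffs()


def classify_turnover(ki: float, cutoffs: TurnoverCutoffs = DEFAULT_CUTOFFS) -> str:
    """Map one K_i value to 'low', 'normal' or 'high'."""
    if not math.isfinite(ki) or ki < 0:
        raise ValueError(f"K_i must be finite and non-negative, got {ki}")
    if ki < cutoffs.low_below:
        return "low"
    if ki > cutoffs.high_above:
        return "high"
    return "normal"


def classify_cohort(
    ki_table: pd.DataFrame,
    cutoffs: TurnoverCutoffs = DEFAULT_CUTOFFS,
    negative_action: str = "error",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify every (scan, region[, duration]) K_i in a table.

    ``ki_table`` needs columns ``scan_id``, ``region``, ``Ki`` and may carry
    extra grouping columns (e.g. ``duration_min``), which are preserved.
    A noisy fit can produce a (non-physical) negative clearance estimate;
    with ``negative_action='low'`` such values are assigned to the low
    category (they lie below the low cutoff), instead of raising.
    Returns ``(per_scan, counts)``: the input with a ``category`` column,
    and category counts per region (and any extra grouping columns), with
    all three categories present (zero-filled).
    """
    required = {"scan_id", "region", "Ki"}
    missing = required - set(ki_table.columns)
    if missing:
        raise ValueError(f"ki_table missing columns {sorted(missing)}")
    if negative_action not in ("error", "low"):
        raise ValueError(f"unknown negative_action {negative_action!r}")
    per_scan = ki_table.copy()
    per_scan["category"] = [
        "low" if (negative_action == "low" and math.isfinite(k) and k < 0)
        else classify_turnover(k, cutoffs)
        for k in per_scan["Ki"]
    ]
    group_cols = ["region"] + [c for c in ("duration_min",) if c in per_scan.columns]
    counts = (
        per_scan.groupby(group_cols)["category"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=list(CATEGORIES), fill_value=0)
        .reset_index()
    )
    counts.columns.name = None
    return per_scan, counts
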