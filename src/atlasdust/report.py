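"""Stage-level accounting of unidentified voxels.

A correction pipeline is judged by how many voxels still carry the
catch-all suspicious label after each stage. This module counts labels,
computes percent reductions between stages, and summarizes distributions
across datasets with five-number summaries (quartiles by linear
interpolation between order statistics, numpy's default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .volumes import LabelVolume

__all__ = [
    "StageCount",
    "FiveNumberSummary",
    "count_labels",
    "percent_reduction",
    "five_number_summary",
    "stage_counts",
    "stage_report",
]


@dataclass(frozen=True)
class StageCount:
    """Label census of one pipeline stage."""

    stage_name: str
    undefined_count: int
    per_label_counts: dict[int, int]


@dataclass(frozen=True)
class FiveNumberSummary:
    minimum: float
    first_quartile: float
    median: float
    third_quartile: float
    maximum: float


def count_labels(v: LabelVolume) -> dict[int, int]:
    """Exact voxel count per label ID; counts sum to the grid size."""
    ids, counts = np.unique(v.voxels, return_counts=True)
    return {int(i): int(c) for i, c in zip(ids, counts)}


def percent_reduction(before: int, after: int) -> float:
    """100 x (before - after) / before."""
    if before <= 0:
        raise ValueError("'before' count must be positive")
    if after < 0:
        raise ValueError("'after' count must be non-negative")
    return 100.0 * (before - after) / before


def five_number_summary(values: Sequence[float]) -> FiveNumberSummary:
    """Min, quartiles (linear interpolation), median, max."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one value")
    q = np.percentile(arr, [0, 25, 50, 75, 100], method="linear")
    return FiveNumberSummary(*map(float, q))


def stage_counts(
    stages: Sequence[tuple[str, LabelVolume]], suspicious_label: int = 999
) -> list[StageCount]:
    """Per-stage label censuses with the suspicious-label count pulled out."""
    out = []
    for name, vol in stages:
        counts = count_labels(vol)
        out.append(StageCount(
            stage_name=name,
            undefined_count=counts.get(suspicious_label, 0),
            per_label_counts=counts,
        ))
    return out


def stage_report(
    stages: Sequence[tuple[str, LabelVolume]], suspicious_label: int = 999
) -> dict:
    """JSON-ready cross-stage report: counts and reductions vs. baseline.

    ``reduction_from_base_percent`` is reported per stage relative to the
    first stage; ``reduction_step_percent`` relative to the previous stage.
    Reductions are None when the reference count is zero.
    """
    counts = stage_counts(stages, suspicious_label)
    base = counts[0].undefined_count
    rows = []
    prev = base
    for sc in counts:
        rows.append({
            "stage": sc.stage_name,
            "undefined_count": sc.undefined_count,
            "reduction_from_base_percent": (
                percent_reduction(base, sc.undefined_count) if base > 0 else None
            ),
            "reduction_step_percent": (
                percent_reduction(prev, sc.undefined_count) if prev > 0 else None
            ),
        })
        prev = sc.undefined_count
    return {
        "suspicious_label": suspicious_label,
        "stages": rows,
        "per_label_counts": {
            sc.stage_name: {str(k): v for k, v in sorted(sc.per_label_counts.items())}
            for sc in counts
        },
    }
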