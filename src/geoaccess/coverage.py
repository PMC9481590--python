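"""Zonal accessibility-coverage statistics.

For every (dataset, administrative unit, travel-time threshold) the covered
population is the total count of points whose travel time is at or below the
threshold.  The denominator is the unit's population excluding people on
barriers and outside the region — unreachable-but-on-land population stays in
the denominator, which is what makes low-coverage units honest rather than
empty.  Population on barriers is tallied separately.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .population import STATUS_BARRIER, STATUS_OK, STATUS_OUT_OF_REGION, STATUS_UNREACHABLE

__all__ = ["coverage_stats", "barrier_report", "LEVEL0_ID"]

log = logging.getLogger(__name__)

#: admin_id used for the always-emitted whole-region (level 0) rows.
LEVEL0_ID = "all"

COVERAGE_COLUMNS = [
    "dataset", "admin_level", "admin_id", "threshold_min",
    "pop_covered", "pop_total", "coverage_pct", "pop_on_barrier", "pop_unreachable",
]


def _unit_stats(group: pd.DataFrame, thresholds: Sequence[float]) -> list[dict]:
    counts = group["count"].to_numpy(float)
    status = group["status"].to_numpy()
    tt = group["travel_time_min"].to_numpy(float)
    in_region = status != STATUS_OUT_OF_REGION
    on_barrier = status == STATUS_BARRIER
    pop_barrier = float(counts[on_barrier].sum())
    pop_unreach = float(counts[status == STATUS_UNREACHABLE].sum())
    pop_total = float(counts[in_region & ~on_barrier].sum())
    ok = status == STATUS_OK
    rows = []
    for thr in thresholds:
        covered = float(counts[ok & (tt <= thr)].sum())
        rows.append(
            {
                "threshold_min": thr,
                "pop_covered": covered,
                "pop_total": pop_total,
                "coverage_pct": 100.0 * covered / pop_total if pop_total > 0 else np.nan,
                "pop_on_barrier": pop_barrier,
                "pop_unreachable": pop_unreach,
            }
        )
    return rows


def coverage_stats(
    points: pd.DataFrame,
    thresholds_min: Sequence[float],
    levels: tuple[int, ...] = (0, 1, 2),
) -> pd.DataFrame:
    """Coverage table per (dataset, admin level, unit, threshold).

    ``points`` must be classified (columns count, status, travel_time_min,
    dataset, and adminL_id for each requested positive level).  A level-0
    whole-region row is always emitted.  ``coverage_pct`` is kept at full
    precision; report rounding happens only at serialization.  Units with no
    non-barrier population get NaN coverage rather than a fabricated 0%.
    """
    if list(thresholds_min) != sorted(thresholds_min) or len(set(thresholds_min)) != len(
        list(thresholds_min)
    ):
        raise ValueError("thresholds must be strictly increasing")
    if points.empty:
        log.warning("coverage_stats called with an empty point set")
        return pd.DataFrame(columns=COVERAGE_COLUMNS)

    records: list[dict] = []

    def emit(level: int, unit_id: str, group: pd.DataFrame, dataset: str) -> None:
        for row in _unit_stats(group, thresholds_min):
            records.append(
                {"dataset": dataset, "admin_level": level, "admin_id": unit_id, **row}
            )

    for dataset, dgroup in points.groupby("dataset", sort=True):
        emit(0, LEVEL0_ID, dgroup, dataset)
        for level in sorted(lv for lv in levels if lv > 0):
            col = f"admin{level}_id"
            if col not in dgroup.columns:
                raise ValueError(f"points lack {col}; classify_points with level {level} first")
            for unit_id, ugroup in dgroup[dgroup[col] != ""].groupby(col, sort=True):
                emit(level, str(unit_id), ugroup, dataset)

    table = pd.DataFrame.from_records(records)[COVERAGE_COLUMNS]
    return table.sort_values(
        ["dataset", "admin_level", "admin_id", "threshold_min"]
    ).reset_index(drop=True)


def barrier_report(points: pd.DataFrame) -> pd.DataFrame:
    """Per-dataset absolute and relative population on barrier cells.

    The percentage is barrier population over all in-region population
    (barrier plus non-barrier).
    """
    if points.empty:
        return pd.DataFrame(columns=["dataset", "pop_on_barrier", "pct_on_barrier"])
    rows = []
    for dataset, group in points.groupby("dataset", sort=True):
        in_region = group["status"] != STATUS_OUT_OF_REGION
        counts = group.loc[in_region, "count"].to_numpy(float)
        on_barrier = (group.loc[in_region, "status"] == STATUS_BARRIER).to_numpy()
        total = float(counts.sum())
        barrier = float(counts[on_barrier].sum())
        rows.append(
            {
                "dataset": dataset,
                "pop_on_barrier": barrier,
                "pct_on_barrier": 100.0 * barrier / total if total > 0 else 0.0,
            }
        )
    return pd.DataFrame(rows)
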