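"""Cross-dataset difference statistics.

"Difference" throughout is the absolute difference in coverage percentage
points between two datasets for the same unit and threshold — a ratio-based
definition would explode in low-coverage units and does not match the 0–70+
percentage-point magnitudes these comparisons are meant to surface.
"""

from __future__ import annotations

import logging
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .coverage import LEVEL0_ID

__all__ = ["pairwise_diff", "average_unit_diff", "size_association"]

log = logging.getLogger(__name__)


def _coverage_by_dataset(
    table: pd.DataFrame, threshold: float, level: int, unit: str
) -> pd.Series:
    sel = table[
        (table["threshold_min"] == threshold)
        & (table["admin_level"] == level)
        & (table["admin_id"] == unit)
    ]
    return sel.set_index("dataset")["coverage_pct"].sort_index()


def pairwise_diff(
    table: pd.DataFrame,
    threshold: float,
    level: int = 0,
    unit: str = LEVEL0_ID,
    datasets: list[str] | None = None,
) -> pd.DataFrame:
    """Symmetric matrix of |coverage_pct_A - coverage_pct_B| in percentage points."""
    cov = _coverage_by_dataset(table, threshold, level, unit)
    datasets = sorted(datasets) if datasets else list(cov.index)
    missing = [d for d in datasets if d not in cov.index]
    if missing:
        raise ValueError(
            f"no coverage row for dataset(s) {missing} at unit {unit!r}, "
            f"level {level}, threshold {threshold}"
        )
    vals = cov.loc[datasets].to_numpy(float)
    mat = np.abs(vals[:, None] - vals[None, :])
    return pd.DataFrame(mat, index=datasets, columns=datasets)


def average_unit_diff(
    table: pd.DataFrame,
    threshold: float,
    level: int,
    areas_km2: Mapping[str, float],
    n_quantiles: int = 4,
) -> pd.DataFrame:
    """Per-unit mean pairwise absolute coverage difference, with context columns.

    For each unit at the given level: the mean over all unordered dataset
    pairs of |Δ coverage_pct|, the unit's area (km², computed on the run's
    equal-area metric plane), the unit's total population averaged across
    datasets, and a population quantile label (quartiles by default).
    """
    sel = table[(table["threshold_min"] == threshold) & (table["admin_level"] == level)]
    datasets = sorted(sel["dataset"].unique())
    if len(datasets) < 2:
        raise ValueError("average_unit_diff needs at least two datasets")
    rows = []
    for unit_id, group in sel.groupby("admin_id", sort=True):
        cov = group.set_index("dataset")["coverage_pct"]
        pairs = [
            abs(cov[a] - cov[b])
            for a, b in combinations(datasets, 2)
            if a in cov.index and b in cov.index
        ]
        if not pairs:
            continue
        rows.append(
            {
                "admin_id": unit_id,
                "admin_level": level,
                "mean_abs_diff_pp": float(np.nanmean(pairs)),
                "area_km2": float(areas_km2[unit_id]),
                "mean_pop": float(group["pop_total"].mean()),
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    try:
        out["pop_quantile"] = pd.qcut(
            out["mean_pop"], n_quantiles, labels=[f"Q{i + 1}" for i in range(n_quantiles)]
        ).astype(str)
    except ValueError:  # too few distinct values for the requested quantiles
        out["pop_quantile"] = "Q1"
    return out


def size_association(unit_diff: pd.DataFrame, min_units: int = 5) -> dict:
    """Association between unit area and mean coverage difference.

    Returns the Spearman rank correlation of area_km2 against
    mean_abs_diff_pp, its p-value, the per-population-quantile mean
    differences, and the correlation's sign.  Degenerate (constant) inputs
    yield NaN statistics rather than an error.
    """
    if len(unit_diff) < min_units:
        raise ValueError(f"size_association needs at least {min_units} units")
    area = unit_diff["area_km2"].to_numpy(float)
    diff = unit_diff["mean_abs_diff_pp"].to_numpy(float)
    if np.all(area == area[0]) or np.all(diff == diff[0]):
        rho, p = np.nan, np.nan
    else:
        rho, p = spearmanr(area, diff)
    group_means = (
        unit_diff.groupby("pop_quantile", sort=True)["mean_abs_diff_pp"].mean().to_dict()
        if "pop_quantile" in unit_diff.columns
        else {}
    )
    return {
        "spearman_rho": float(rho) if rho == rho else float("nan"),
        "p_value": float(p) if p == p else float("nan"),
        "n_units": int(len(unit_diff)),
        "sign": 0 if rho != rho else int(np.sign(rho)),
        "quantile_mean_diff_pp": {k: float(v) for k, v in group_means.items()},
    }
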