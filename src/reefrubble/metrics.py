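"""Reef- and region-scale susceptibility metrics.

Susceptibility of a reef is the percentage of its transects whose potential
rubble cover strictly exceeds a threshold; the count of exceeding transects
times the 500-m transect spacing gives the linear distance of susceptible
reef slope. Region-scale summaries count reefs containing at least one
exceeding ("problematic") transect per threshold.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

DEFAULT_THRESHOLDS = tuple(range(10, 100, 10))
CRITICAL_THRESHOLDS = (30, 40, 50)
TRANSECT_SPACING_M = 500.0


def results_table(transect_results) -> pd.DataFrame:
    """Tidy per-transect table from a list of TransectResult."""
    return pd.DataFrame(
        {
            "transect_id": [r.transect_id for r in transect_results],
            "reef_id": [r.reef_id for r in transect_results],
            "cover_pct_total": [r.cover_pct_total for r in transect_results],
            "cover_pct_shallow": [r.cover_pct_shallow for r in transect_results],
            "cover_pct_deep": [r.cover_pct_deep for r in transect_results],
        }
    )


def linear_distance(count_exceeding: int, spacing_m: float = TRANSECT_SPACING_M) -> float:
    """Linear extent (km) represented by ``count_exceeding`` transects."""
    if count_exceeding < 0:
        raise ValueError("count must be non-negative")
    return count_exceeding * spacing_m / 1000.0


def reef_susceptibility(
    transects: pd.DataFrame,
    thresholds: tuple[int, ...] = DEFAULT_THRESHOLDS,
    spacing_m: float = TRANSECT_SPACING_M,
) -> pd.DataFrame:
    """Per-reef exceedance percentages and linear distances.

    ``transects`` needs columns reef_id and cover_pct_total. A transect
    counts toward threshold t iff its cover is strictly greater than t.
    Returns a long table (reef_id, threshold, n_transects, n_exceeding,
    pct_exceeding, linear_distance_km). Reefs with zero transects cannot
    appear; unassigned transects (reef_id None/NaN) are excluded with a
    warning.
    """
    df = transects.copy()
    unassigned = df["reef_id"].isna()
    if unassigned.any():
        warnings.warn(f"{unassigned.sum()} transects without a reef excluded")
        df = df[~unassigned]
    if df.empty:
        raise ValueError("no reef-assigned transects to aggregate")
    rows = []
    for reef_id, grp in df.groupby("reef_id", sort=True):
        covers = grp["cover_pct_total"].to_numpy()
        for t in thresholds:
            n_exc = int((covers > t).sum())
            rows.append(
                {
                    "reef_id": reef_id,
                    "threshold": t,
                    "n_transects": len(covers),
                    "n_exceeding": n_exc,
                    "pct_exceeding": 100.0 * n_exc / len(covers),
                    "linear_distance_km": linear_distance(n_exc, spacing_m),
                }
            )
    return pd.DataFrame(rows)


def summarize_region(
    reef_table: pd.DataFrame,
    transects: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Region-wide summary per threshold.

    Counts reefs with at least one transect exceeding each threshold, the
    percentage of reefs that is, and the total linear distance summed over
    all reefs. Attrs carry the count and percentage of reefs with zero
    potential rubble cover anywhere (the "excluded" reefs) when the
    per-transect table is supplied.
    """
    n_reefs = reef_table["reef_id"].nunique()
    out = (
        reef_table.groupby("threshold")
        .agg(
            n_reefs_problematic=("n_exceeding", lambda s: int((s > 0).sum())),
            total_linear_km=("linear_distance_km", "sum"),
        )
        .reset_index()
    )
    out["pct_reefs_problematic"] = 100.0 * out["n_reefs_problematic"] / n_reefs
    out.attrs["n_reefs"] = n_reefs
    if transects is not None:
        zero = (
            transects.dropna(subset=["reef_id"])
            .groupby("reef_id")["cover_pct_total"]
            .max()
            .eq(0.0)
        )
        out.attrs["n_reefs_zero_rubble"] = int(zero.sum())
        out.attrs["pct_reefs_zero_rubble"] = 100.0 * zero.sum() / n_reefs
    return out


def pct_of_reefs(count: int, total: int, ndigits: int = 1) -> float:
    """Percentage a reef count represents, rounded as reported (one decimal)."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, ndigits)


def rank_top_decile(
    reef_table: pd.DataFrame,
    threshold: int,
) -> pd.DataFrame:
    """Top 10% of reefs ranked by exceedance percentage at one threshold.

    Descending by pct_exceeding — the greater the percentage, the higher
    the rank; ties broken by reef_id for determinism. Returns
    ceil(0.1 * n) rows with a 1-based ``rank`` column. Fewer than 10 reefs
    returns the whole ranked list with a warning.
    """
    sub = reef_table[reef_table["threshold"] == threshold].copy()
    if sub.empty:
        raise ValueError(f"no reefs at threshold {threshold}")
    sub = sub.sort_values(
        ["pct_exceeding", "reef_id"], ascending=[False, True]
    ).reset_index(drop=True)
    sub["rank"] = np.arange(1, len(sub) + 1)
    n = len(sub)
    if n < 10:
        warnings.warn(f"only {n} reefs; returning the full ranking")
        return sub
    return sub.head(math.ceil(0.1 * n))


def full_ranking(reef_table: pd.DataFrame, threshold: int) -> pd.DataFrame:
    """Complete descending ranking of all reefs at one threshold."""
    sub = reef_table[reef_table["threshold"] == threshold].copy()
    sub = sub.sort_values(
        ["pct_exceeding", "reef_id"], ascending=[False, True]
    ).reset_index(drop=True)
    sub["rank"] = np.arange(1, len(sub) + 1)
    return sub
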