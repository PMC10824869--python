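"""One-at-a-time (OAT) sensitivity of the accumulation algorithm.

Each of the four parameters is perturbed by +/-20% with the others held at
the base case, the whole transect-to-reef pipeline is rerun, and two output
variables are tracked per threshold: the count of reefs containing
problematic transects, and the ranking of the base case's top-10% most
susceptible reefs. Parameters are then ranked by the mean percentage
change in reef count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import PARAM_NAMES, RubbleParams, evaluate_transect
from .metrics import (
    CRITICAL_THRESHOLDS,
    full_ranking,
    rank_top_decile,
    reef_susceptibility,
    results_table,
    summarize_region,
)

SCENARIO_FACTORS = {"-20%": 0.8, "base": 1.0, "+20%": 1.2}


@dataclass
class OATResult:
    """Per-parameter OAT outputs.

    counts: long table (parameter, scenario, threshold, n_reefs).
    rank_changes: long table (parameter, scenario, threshold, reef_id,
    rank_base, rank_scenario, abs_change).
    """

    counts: pd.DataFrame
    rank_changes: pd.DataFrame
    base_counts: pd.DataFrame


def _pipeline_counts(profiles, params, thresholds, spacing_m):
    results = [evaluate_transect(p, params) for p in profiles]
    reef = reef_susceptibility(results_table(results), thresholds, spacing_m)
    region = summarize_region(reef)
    return reef, region


def run_oat(
    profiles,
    base_params: RubbleParams = RubbleParams(),
    thresholds: tuple[int, ...] = CRITICAL_THRESHOLDS,
    spacing_m: float = 500.0,
) -> OATResult:
    """Rerun the pipeline at 0.8x and 1.2x of each parameter.

    Scenarios whose scaled parameter violates the parameter invariants are
    skipped with a warning. The base scenario is computed once and shared.
    """
    base_reef, base_region = _pipeline_counts(profiles, base_params, thresholds, spacing_m)
    base_rankings = {t: rank_top_decile(base_reef, t) for t in thresholds}
    count_rows, rank_rows = [], []
    for t in thresholds:
        n_base = int(
            base_region.loc[base_region["threshold"] == t, "n_reefs_problematic"].iloc[0]
        )
        count_rows.append(
            {"parameter": "all", "scenario": "base", "threshold": t, "n_reefs": n_base}
        )
    for name in PARAM_NAMES:
        for scenario, factor in SCENARIO_FACTORS.items():
            if scenario == "base":
                continue
            try:
                params = base_params.scaled(name, factor)
            except ValueError as err:
                warnings.warn(f"skipping {name} {scenario}: {err}")
                continue
            reef, region = _pipeline_counts(profiles, params, thresholds, spacing_m)
            for t in thresholds:
                n = int(region.loc[region["threshold"] == t, "n_reefs_problematic"].iloc[0])
                count_rows.append(
                    {"parameter": name, "scenario": scenario, "threshold": t, "n_reefs": n}
                )
                scen_ranking = full_ranking(reef, t)
                lookup = dict(zip(scen_ranking["reef_id"], scen_ranking["rank"]))
                absent_rank = len(scen_ranking) + 1
                for _, row in base_rankings[t].iterrows():
                    r_new = lookup.get(row["reef_id"], absent_rank)
                    rank_rows.append(
                        {
                            "parameter": name,
                            "scenario": scenario,
                            "threshold": t,
                            "reef_id": row["reef_id"],
                            "rank_base": int(row["rank"]),
                            "rank_scenario": int(r_new),
                            "abs_change": abs(int(row["rank"]) - int(r_new)),
                        }
                    )
    base_counts = pd.DataFrame(
        [r for r in count_rows if r["scenario"] == "base"]
    )
    counts = pd.DataFrame([r for r in count_rows if r["scenario"] != "base"])
    return OATResult(
        counts=counts, rank_changes=pd.DataFrame(rank_rows), base_counts=base_counts
    )


def count_sensitivity(
    result: OATResult,
    parameter: str,
    include_zero_base: bool = False,
) -> float:
    """Mean absolute % change in problematic-reef count for one parameter.

    Per threshold and perturbation: 100 * |n_scenario - n_base| / n_base,
    averaged over both perturbations and thresholds. Thresholds with a
    zero base count are excluded by default (NaN if none remain); with
    ``include_zero_base`` they contribute 0% change instead.
    """
    base = dict(zip(result.base_counts["threshold"], result.base_counts["n_reefs"]))
    sub = result.counts[result.counts["parameter"] == parameter]
    if sub.empty:
        raise ValueError(f"no scenarios for parameter {parameter!r}")
    changes = []
    for _, row in sub.iterrows():
        n_base = base[row["threshold"]]
        if n_base == 0:
            if include_zero_base:
                changes.append(0.0)
            continue
        changes.append(100.0 * abs(row["n_reefs"] - n_base) / n_base)
    return float(np.mean(changes)) if changes else float("nan")


def ranking_sensitivity(result: OATResult, parameter: str) -> tuple[float, float]:
    """Mean |rank change| of the base top-10% reefs and its standard error.

    Averaged per threshold over both perturbations, then across
    thresholds; the SE is over the per-threshold means.
    """
    sub = result.rank_changes[result.rank_changes["parameter"] == parameter]
    if sub.empty:
        raise ValueError(f"no ranking data for parameter {parameter!r}")
    per_threshold = sub.groupby("threshold")["abs_change"].mean()
    mean = float(per_threshold.mean())
    se = (
        float(per_threshold.std(ddof=1) / np.sqrt(len(per_threshold)))
        if len(per_threshold) > 1
        else 0.0
    )
    return mean, se


def rank_parameters(result: OATResult, include_zero_base: bool = False) -> pd.DataFrame:
    """Parameters ordered by descending count sensitivity.

    Ties broken by ranking sensitivity (descending), then by name.
    """
    rows = []
    for name in PARAM_NAMES:
        cs = count_sensitivity(result, name, include_zero_base)
        rs, se = ranking_sensitivity(result, name)
        rows.append(
            {
                "parameter": name,
                "count_sensitivity_pct": cs,
                "mean_rank_change": rs,
                "rank_change_se": se,
            }
        )
    df = pd.DataFrame(rows)
    df = df.sort_values(
        ["count_sensitivity_pct", "mean_rank_change", "parameter"],
        ascending=[False, False, True],
    ).reset_index(drop=True)
    df["sensitivity_rank"] = np.arange(1, len(df) + 1)
    return df
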