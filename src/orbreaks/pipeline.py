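"""End-to-end orchestration: history fit -> bounds -> feasibility -> summaries.

The full analysis mirrors a staffing question: given last years' case
records, on what share of future cases could a supervising anesthesiologist
give a 15-minute morning break (starting 9:00-10:30) or a 30-minute lunch
break (starting 11:15-12:45), covering one, two, or three adjacent rooms?
Throughout-workday and widened-window (11:00-13:00) variants quantify how
much the clock window itself matters.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .duration import fit_all_stats, lower_prediction_bound, coverage_check
from .feasibility import BreakPolicy, classify_schedule
from .summaries import (FLAG_COLUMNS, facility_covariate, stratum_lower_limits,
                        summarize)

DEFAULT_POLICIES: dict[str, BreakPolicy] = {
    "lunch": BreakPolicy("lunch", 30, 15, dt.time(11, 15), dt.time(12, 45)),
    "lunch_anytime": BreakPolicy("lunch_anytime", 30, 15),
    "lunch_wide": BreakPolicy("lunch_wide", 30, 15, dt.time(11, 0), dt.time(13, 0)),
    "morning": BreakPolicy("morning", 15, 15, dt.time(9, 0), dt.time(10, 30)),
    "morning_anytime": BreakPolicy("morning_anytime", 15, 15),
}


def attach_bounds(historical: pd.DataFrame, future: pd.DataFrame,
                  risk: float = 0.05) -> pd.DataFrame:
    """Future table plus per-case prediction bounds fitted from history.

    Adds ``case_id`` (stable row ids), ``hist_n`` (historical cases used for
    the code, capped), ``bound_hours`` and ``bound_usable``.  Codes absent
    from history or with fewer than two cases yield unusable bounds.
    """
    stats = fit_all_stats(historical)
    bounds = {code: lower_prediction_bound(st, risk=risk)
              for code, st in stats.items()}
    fut = future.reset_index(drop=True).copy()
    fut["case_id"] = [f"C{i:06d}" for i in range(len(fut))]
    fut["hist_n"] = [stats[c].n if c in stats else 0 for c in fut["code"]]
    fut["bound_hours"] = [bounds[c].bound_hours if c in bounds and bounds[c].usable
                          else np.nan for c in fut["code"]]
    fut["bound_usable"] = [c in bounds and bounds[c].usable for c in fut["code"]]
    return fut


def _weekday(date_str: str) -> str:
    return dt.date.fromisoformat(date_str).strftime("%A")


def covariate_points(per_policy: dict[str, pd.DataFrame],
                     future_b: pd.DataFrame,
                     policies: dict[str, BreakPolicy]) -> pd.DataFrame:
    """One (facility, window) point per policy for the covariate analysis.

    ``x_pct`` is the percent of denominator cases whose *actual* surgical
    time is at least break duration + lead-in; ``y_pct`` the single-room
    feasibility percent on the same denominator.
    """
    actual_min = ((future_b["surgery_end"] - future_b["surgery_start"])
                  .dt.total_seconds() / 60.0)
    actual_by_id = dict(zip(future_b["case_id"], actual_min))
    rows = []
    for name, results in per_policy.items():
        pol = policies[name]
        denom = results.loc[results["in_denominator"]]
        for facility, grp in denom.groupby("facility", sort=True):
            n = len(grp)
            if n == 0:
                continue
            threshold = pol.duration_min + pol.lead_in_min
            long_enough = sum(actual_by_id[cid] >= threshold for cid in grp["case_id"])
            rows.append({"facility": facility, "window": name,
                         "duration_min": pol.duration_min, "n": n,
                         "x_pct": 100.0 * long_enough / n,
                         "y_pct": 100.0 * grp["single"].mean()})
    return pd.DataFrame(rows)


@dataclass
class StudyAnalysis:
    """All analysis products for one (historical, future) table pair."""

    future_bounded: pd.DataFrame
    per_policy: dict[str, pd.DataFrame]
    summary: pd.DataFrame
    strata: pd.DataFrame
    covariate_pts: pd.DataFrame
    correlations: pd.DataFrame
    coverage: tuple[float, tuple[float, float]] | None
    exclusions: dict[str, dict[str, int]] = field(default_factory=dict)


def analyze_study(historical: pd.DataFrame, future: pd.DataFrame,
                  policies: dict[str, BreakPolicy] | None = None,
                  stratum_facility: str | None = "pediatric",
                  risk: float = 0.05) -> StudyAnalysis:
    """Run the complete pipeline on a pair of case tables.

    Returns per-case flags per policy, Table-style facility summaries, the
    Šidák service-by-weekday lower limits for the middle facility (single
    room, 30-minute break, any time of day), the facility covariate
    correlations, and the prediction-bound coverage check.
    """
    if policies is None:
        policies = DEFAULT_POLICIES
    fut = attach_bounds(historical, future, risk=risk)

    per_policy: dict[str, pd.DataFrame] = {}
    exclusions: dict[str, dict[str, int]] = {}
    summary_frames = []
    for name, pol in policies.items():
        res = classify_schedule(fut, pol)
        if not res.empty:
            res["weekday"] = res["date"].map(_weekday)
        per_policy[name] = res
        if res.empty:
            exclusions[name] = {}
            continue
        exclusions[name] = (res.loc[res["excluded_reason"] != "", "excluded_reason"]
                            .value_counts().to_dict())
        summ = summarize(res, by=["facility"])
        if not summ.empty:
            summ.insert(1, "window", name)
            summary_frames.append(summ)
    summary = (pd.concat(summary_frames, ignore_index=True)
               if summary_frames else pd.DataFrame())

    strata = pd.DataFrame()
    if stratum_facility is not None and "lunch_anytime" in per_policy:
        res = per_policy["lunch_anytime"]
        if not res.empty:
            sub = res.loc[res["facility"] == stratum_facility]
            if not sub.empty:
                strata = stratum_lower_limits(sub)

    pts = covariate_points(per_policy, fut, policies)
    correlations = facility_covariate(pts) if not pts.empty else pd.DataFrame()

    usable = fut.loc[fut["bound_usable"]]
    coverage = None
    if not usable.empty:
        actual_h = ((usable["surgery_end"] - usable["surgery_start"])
                    .dt.total_seconds() / 3600.0)
        coverage = coverage_check(usable["bound_hours"].to_numpy(),
                                  actual_h.to_numpy())
    return StudyAnalysis(future_bounded=fut, per_policy=per_policy,
                         summary=summary, strata=strata, covariate_pts=pts,
                         correlations=correlations, coverage=coverage,
                         exclusions=exclusions)


__all__ = ["DEFAULT_POLICIES", "attach_bounds", "covariate_points",
           "analyze_study", "StudyAnalysis", "FLAG_COLUMNS"]
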