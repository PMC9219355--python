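"""Per-procedure log-normal duration statistics and lower prediction bounds.

Surgical times are modeled per procedure code as two-parameter log-normal.
From the historical cases of a code (capped at the 99 most recent) the
sample mean ``m`` and SD ``s`` of log surgical time (natural log, hours)
give the one-sided lower prediction bound for a single future case::

    bound = exp(m - t(1 - risk, n - 1) * s * sqrt(1 + 1/n))

where ``t(p, df)`` is the Student-t quantile.  The next case of the same
procedure exceeds this bound with probability ``1 - risk`` (exactly, under
log-normal truth), so the bound is the earliest time the case can be relied
upon to still be running.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .summaries import clopper_pearson

#: at most this many most-recent historical cases contribute per procedure
HISTORY_CAP = 99


@dataclass(frozen=True)
class ProcedureStats:
    """History summary for one procedure code.

    ``n`` is the count of cases used (<= HISTORY_CAP); ``m``/``s`` are the
    sample mean and SD of log surgical time in log-hours.  ``s`` (and the
    prediction bound) are defined only when ``n >= 2``.
    """

    code: str
    n: int
    m: float = math.nan
    s: float = math.nan

    @property
    def sufficient(self) -> bool:
        return self.n >= 2 and not math.isnan(self.s)


@dataclass(frozen=True)
class PredictionBound:
    code: str
    risk: float
    bound_hours: float
    usable: bool


def _log_hours(cases: pd.DataFrame) -> np.ndarray:
    dur = (cases["surgery_end"] - cases["surgery_start"]).dt.total_seconds() / 3600.0
    return np.log(dur.to_numpy())


def _stats_from_logs(code: str, logs: np.ndarray, cap: int) -> ProcedureStats:
    logs = logs[-cap:]
    n = len(logs)
    if n == 0:
        return ProcedureStats(code=code, n=0)
    m = float(np.mean(logs))
    s = float(np.std(logs, ddof=1)) if n >= 2 else math.nan
    return ProcedureStats(code=code, n=n, m=m, s=s)


def fit_procedure_stats(historical: pd.DataFrame, code: str,
                        cap: int = HISTORY_CAP) -> ProcedureStats:
    """Fit log-scale stats for one code from its most recent ``cap`` cases.

    Recency is by ``surgery_start``; among equal timestamps, later rows of
    the input table are treated as more recent (stable sort).  A code absent
    from history yields ``n=0`` (insufficient), not an exception.
    """
    sub = historical.loc[historical["code"] == code]
    sub = sub.sort_values("surgery_start", kind="stable")
    return _stats_from_logs(code, _log_hours(sub), cap)


def fit_all_stats(historical: pd.DataFrame,
                  cap: int = HISTORY_CAP) -> dict[str, ProcedureStats]:
    """Vectorized :func:`fit_procedure_stats` over every code in history."""
    if historical.empty:
        return {}
    df = historical.sort_values("surgery_start", kind="stable")
    df = df.assign(_log_h=_log_hours(df))
    recent = df.groupby("code", sort=False).tail(cap)
    agg = recent.groupby("code", sort=False)["_log_h"].agg(["count", "mean", "std"])
    return {
        code: ProcedureStats(code=code, n=int(row["count"]), m=float(row["mean"]),
                             s=float(row["std"]) if row["count"] >= 2 else math.nan)
        for code, row in agg.iterrows()
    }


def lower_prediction_bound(stats: ProcedureStats, risk: float = 0.05) -> PredictionBound:
    """One-sided lower prediction bound (hours) for a single future case.

    With fewer than two usable historical cases the result is flagged
    unusable and the case must be excluded downstream.
    """
    if not 0.0 < risk < 1.0:
        raise ValueError(f"risk must be in (0, 1), got {risk}")
    if not stats.sufficient:
        return PredictionBound(code=stats.code, risk=risk, bound_hours=math.nan,
                               usable=False)
    tq = float(sps.t.ppf(1.0 - risk, stats.n - 1))
    bound = math.exp(stats.m - tq * stats.s * math.sqrt(1.0 + 1.0 / stats.n))
    return PredictionBound(code=stats.code, risk=risk, bound_hours=bound, usable=True)


def coverage_check(bound_hours: np.ndarray, actual_hours: np.ndarray,
                   confidence: float = 0.99) -> tuple[float, tuple[float, float]]:
    """Observed lower-tail incidence of the bounds on realized times.

    Returns the fraction of cases whose actual surgical time fell strictly
    below their prediction bound, with a two-sided Clopper-Pearson interval.
    Under a correctly specified model the incidence equals the nominal risk.
    """
    bound_hours = np.asarray(bound_hours, dtype=float)
    actual_hours = np.asarray(actual_hours, dtype=float)
    if bound_hours.shape != actual_hours.shape:
        raise ValueError("bound and actual arrays must have identical shape")
    n = bound_hours.size
    if n == 0:
        raise ValueError("incidence undefined for an empty future table")
    if np.isnan(bound_hours).any():
        raise ValueError("every future case must have a usable bound")
    k = int(np.sum(actual_hours < bound_hours))
    return k / n, clopper_pearson(k, n, confidence=confidence)


def calibration_study(seed: int, n_reps: int = 100_000, n_history: int = 99,
                      mu: float = math.log(2.0), sigma: float = 0.5,
                      risk: float = 0.05, chunk: int = 50_000) -> float:
    """Monte-Carlo miss rate of the prediction bound under log-normal truth.

    Each replicate draws ``n_history`` log-times from Normal(mu, sigma), fits
    ``m``/``s``, forms the lower prediction bound, draws one future time from
    the same distribution, and records whether it fell below the bound.
    Returns the fraction of misses; exact calibration means it equals
    ``risk`` up to binomial noise.
    """
    if n_reps < 1 or n_history < 2:
        raise ValueError("need n_reps >= 1 and n_history >= 2")
    rng = np.random.default_rng(seed)
    tq = float(sps.t.ppf(1.0 - risk, n_history - 1))
    infl = math.sqrt(1.0 + 1.0 / n_history)
    misses = 0
    done = 0
    while done < n_reps:
        b = min(chunk, n_reps - done)
        hist = rng.normal(mu, sigma, size=(b, n_history))
        m = hist.mean(axis=1)
        s = hist.std(axis=1, ddof=1)
        log_bound = m - tq * s * infl
        future = rng.normal(mu, sigma, size=b)
        misses += int(np.sum(future < log_bound))
        done += b
    return misses / n_reps
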