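"""Aggregation: exact binomial intervals, multiplicity control, covariates.

Feasibility flags are summarized per stratum as ``k/n`` percentages with 99%
two-sided Clopper-Pearson intervals (exact Beta-quantile form).  The
service-by-weekday sensitivity analysis uses one-sided lower limits at a
Šidák-adjusted confidence so the family-wise error rate over all strata is
5%.  A facility-level covariate analysis relates single-room feasibility to
the share of cases at least as long as the break plus the lead-in.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

FLAG_COLUMNS = ["single", "two_best", "two_least", "three"]


def clopper_pearson(k: int, n: int, confidence: float = 0.99,
                    sides: str = "two") -> tuple[float, float]:
    """Exact (conservative) binomial confidence bounds as fractions.

    Two-sided bounds are the usual Beta quantiles; ``k=0`` gives lower 0 and
    ``k=n`` gives upper 1.  ``sides="one"`` returns a lower confidence limit
    at level ``confidence`` (upper bound reported as 1).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must be in (0, 1)")
    alpha = 1.0 - confidence
    if sides == "two":
        lower = 0.0 if k == 0 else float(sps.beta.ppf(alpha / 2, k, n - k + 1))
        upper = 1.0 if k == n else float(sps.beta.ppf(1 - alpha / 2, k + 1, n - k))
        return lower, upper
    if sides == "one":
        lower = 0.0 if k == 0 else float(sps.beta.ppf(alpha, k, n - k + 1))
        return lower, 1.0
    raise ValueError(f"sides must be 'one' or 'two', got {sides!r}")


def sidak_level(m: int, fwer: float = 0.05) -> float:
    """Per-comparison confidence for ``m`` independent comparisons.

    Returns ``1 - alpha`` with ``alpha = 1 - (1 - fwer)**(1/m)``; at
    ``m=1`` this is simply ``1 - fwer``.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0.0 < fwer < 1.0:
        raise ValueError("fwer must be in (0, 1)")
    alpha = 1.0 - (1.0 - fwer) ** (1.0 / m)
    return 1.0 - alpha


def summarize(results: pd.DataFrame, by: list[str] | None = None,
              confidence: float = 0.99) -> pd.DataFrame:
    """Table-style rows: per stratum, k/n, percentage and CP bounds per flag.

    ``results`` holds one row per case with boolean ``single``, ``two_best``,
    ``two_least``, ``three`` columns; rows with ``in_denominator == False``
    (if the column is present) are ignored.  Percentages are on the 0-100
    scale at full precision; display rounding happens at report time.
    """
    if by is None:
        by = ["facility"]
    df = results
    if "in_denominator" in df.columns:
        df = df.loc[df["in_denominator"]]
    rows = []
    for key, grp in df.groupby(by, sort=True, observed=True):
        if not isinstance(key, tuple):
            key = (key,)
        n = len(grp)
        row: dict = dict(zip(by, key))
        row["n"] = n
        for col in FLAG_COLUMNS:
            if n == 0:
                row[f"{col}_k"] = 0
                row[f"{col}_pct"] = np.nan
                row[f"{col}_lo"] = np.nan
                row[f"{col}_hi"] = np.nan
                continue
            k = int(grp[col].sum())
            lo, hi = clopper_pearson(k, n, confidence=confidence)
            row[f"{col}_k"] = k
            row[f"{col}_pct"] = 100.0 * k / n
            row[f"{col}_lo"] = 100.0 * lo
            row[f"{col}_hi"] = 100.0 * hi
        rows.append(row)
    return pd.DataFrame(rows)


def stratum_lower_limits(results: pd.DataFrame, fwer: float = 0.05,
                         min_cases: int = 5) -> pd.DataFrame:
    """Service-by-weekday one-sided lower limits at a Šidák-adjusted level.

    ``results`` holds single-room, any-time-of-day feasibility flags
    (``single``) for one facility's future cases plus ``service`` and
    ``weekday`` columns.  Strata with fewer than ``min_cases`` cases are
    dropped; the realized stratum count sets the adjustment.  The returned
    ``lower_limit`` is in percent.
    """
    df = results
    if "in_denominator" in df.columns:
        df = df.loc[df["in_denominator"]]
    sizes = df.groupby(["service", "weekday"], sort=True, observed=True).size()
    kept = sizes[sizes >= min_cases]
    m = len(kept)
    rows = []
    if m == 0:
        return pd.DataFrame(columns=["service", "weekday", "n", "k", "confidence", "lower_limit"])
    conf = sidak_level(m, fwer=fwer)
    for (service, weekday), n in kept.items():
        grp = df.loc[(df["service"] == service) & (df["weekday"] == weekday)]
        k = int(grp["single"].sum())
        lo, _ = clopper_pearson(k, int(n), confidence=conf, sides="one")
        rows.append({"service": service, "weekday": weekday, "n": int(n), "k": k,
                     "confidence": conf, "lower_limit": 100.0 * lo})
    return pd.DataFrame(rows)


def facility_covariate(points: pd.DataFrame) -> pd.DataFrame:
    """Correlate single-room feasibility with long-enough-case percentage.

    ``points`` has one row per (facility, analysis window) with columns
    ``duration_min``, ``x_pct`` (percent of denominator cases whose actual
    surgical time is at least break duration + lead-in) and ``y_pct``
    (single-room feasibility percent).  Returns Pearson and Spearman
    coefficients per break duration; with fewer than 3 points the
    coefficients are reported as NaN.
    """
    rows = []
    for dur, grp in points.groupby("duration_min", sort=True):
        x = grp["x_pct"].to_numpy(dtype=float)
        y = grp["y_pct"].to_numpy(dtype=float)
        if len(grp) >= 3 and np.ptp(x) > 0 and np.ptp(y) > 0:
            pearson = float(sps.pearsonr(x, y).statistic)
            spearman = float(sps.spearmanr(x, y).statistic)
        else:
            pearson = spearman = float("nan")
        rows.append({"duration_min": dur, "n_points": len(grp),
                     "pearson": pearson, "spearman": spearman})
    return pd.DataFrame(rows)


def scatter_plot(points: pd.DataFrame, path: str) -> None:
    """Optional scatter of feasibility vs long-case percentage (needs matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for dur, grp in points.groupby("duration_min", sort=True):
        ax.scatter(grp["x_pct"], grp["y_pct"], label=f"{dur}-min break")
    lim = [0, 100]
    ax.plot(lim, lim, ls=":", c="grey", lw=1)
    ax.set_xlabel("% cases with surgical time >= break + lead-in")
    ax.set_ylabel("% single-room feasibility")
    ax.set_xlim(lim)
    ax.set_ylim(lim)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
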