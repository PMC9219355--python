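# Methods

## Duration model and prediction bound

Per procedure code, surgical times (incision to dressing, in hours) are
treated as two-parameter log-normal.  Natural logs are used throughout.
From the code's historical cases the sample size `n`, log-mean `m`, and
log-SD `s` (ddof = 1) are computed over at most the **99 most recent**
cases; recency is by surgery start, and among equal timestamps later input
rows are treated as more recent (stable sort).  The capped window keeps the
bound responsive to drift in practice patterns while bounding the leverage
of very old cases.

The 5% lower prediction bound for a single future case is

    B = exp( m − t(1 − risk, n − 1) · s · sqrt(1 + 1/n) ),   risk = 0.05.

This is the classical normal-theory prediction bound for one future
observation, applied on the log scale and exponentiated.  It is *not* a
tolerance bound or a confidence bound on a quantile: those control coverage
of the distribution rather than of a single future draw, give systematically
different (more conservative) limits, and were deliberately rejected.  Under
correctly specified log-normal truth the bound is exactly calibrated for any
`n ≥ 2` — the future time falls below `B` with probability exactly `risk` —
which the Monte-Carlo suite verifies within 3 binomial standard errors.

Codes with `n < 2` have no defined `s`; their cases are excluded from every
feasibility denominator and counted per run with reasons (`no_history`,
`insufficient_history`).  Exclusion is the conservative choice: no fallback
bound is invented for sparse history.

## Suitable interval

A case starting at `S` with actual end `E` and bound `B` is available for a
break during `[S + L, min(S + B, E)]`, with lead-in `L = 15` minutes
reserved for induction completion, positioning, and initial documentation.
The interval is empty when the bound does not outlast the lead-in.  A
documented alternative reading, in which the predicted end is `S + B − L`,
is available via `BreakPolicy(deduct_lead_from_bound=True)`; the default
reading (predicted end `S + B`) matches the convention that availability
runs from 15 minutes after surgery start to the end of the procedure.

## Multi-room calculus

Within one facility-date, the rooms with any case that day are ordered by
room number with cyclic adjacency (first and last are neighbors; with two
rooms both neighbors coincide; a single room is its own neighbor, its other
cases never overlapping the index case).  For each neighbor room, the
constraint on the index case is the *single maximum-length intersection* of
the index suitable interval with one neighbor case's suitable interval — a
break is contiguous, so disjoint pieces are never unioned.  Ties in length
are broken toward the earliest-starting intersection (deterministic; ties
between the two *pairings* need no rule since best = least then).  A
neighbor room with no intersecting case imposes no constraint: the
anesthesiologist effectively has one ongoing case.  Neighbor cases without a
usable bound likewise impose no constraint, but their rooms still occupy a
slot in the cyclic order.  Two-room flags are the better (best chance) and
worse (least chance) of the two pairings; the three-room flag intersects
both neighbors' chosen constraints.

A break of duration `D` must *start* inside the policy's clock window but
may end after it; with window `[w0, w1]`, feasibility is
`max(interval.start, w0) ≤ w1` and `max(interval.start, w0) + D ≤
interval.end`.  Unrestricted ("throughout the workday") policies require
only `interval length ≥ D`.  Feasibility is monotone in the interval and in
the window and antitone in `D`, which yields the nested flags and the
monotonicity properties the suite asserts.

## Denominators

The throughout-workday denominator is every future case with a usable
prediction bound (including cases whose suitable interval is empty — they
are simply infeasible).  Windowed denominators include a case only when a
break starting in-window could possibly overlap its suitable interval:
the interval is non-empty, starts no later than the window end, and ends no
earlier than the window start.  This conditioning rule is an inference — it
is the design decision with the least external support in this package, and
it is why windowed and throughout-day rows have different sample sizes and
why an unrestricted window is only guaranteed to dominate a windowed one at
*fixed* denominator (the suite asserts dominance case-wise on the common
denominator).

## Summaries

Percentages are reported with 99% two-sided Clopper-Pearson intervals
computed from Beta quantiles: lower `Beta(α/2; k, n−k+1)`, upper
`Beta(1−α/2; k+1, n−k)`, with the exact closed forms at `k = 0` and
`k = n`.  The service-by-weekday sensitivity analysis keeps strata with at
least five cases, scores single-room feasibility of a 30-minute break at any
time of day, and reports one-sided lower Clopper-Pearson limits at
confidence `1 − α*` with the Šidák adjustment `α* = 1 − (1 − 0.05)^(1/m)`
for the *realized* stratum count `m` (50 strata give 99.9%).  Display
rounding is one decimal, half away from zero; stored CSVs keep full
precision so rounding never feeds back into computation.

The facility covariate analysis relates, per (facility, window) point, the
percentage of denominator cases whose *actual* surgical time is at least
`D + L` minutes (x) to the single-room feasibility percentage (y), reporting
Pearson and Spearman coefficients per break duration.  `y ≤ x` always:
feasibility requires the retrospective length condition *plus* a
sufficiently long prediction bound, so the bound can only shrink the set.

## Synthetic-schedule generator

The generator emulates the study conditions the analysis assumes, not any
particular institution.  Three archetypes with procedure-catalog medians
centered at 0.75, 1.5, and 2.75 hours (ambulatory, pediatric, adult
inpatient; 8/12/16 rooms) produce strictly increasing weighted-median
durations and hence the qualitative facility ordering of feasibility.
Per-procedure log-medians are drawn once per catalog (SD 0.5 log-hours,
clipped at ±1) with log-SDs uniform on 0.25–0.55; frequencies are Zipf-like
(exponent 1.1) with the last four codes per catalog down-weighted ×10⁻³ so
that both >99-case codes and codes with almost no history occur.  Workdays
run 07:45–17:00 on weekdays with a 30-minute turnover; the first case in a
room starts at 07:45 and cases are appended while the next start precedes
17:00, so rooms rarely end far before the scheduled day end.  Defaults of
750 historical and 250 future weekdays give roughly 110k historical and 36k
future cases — the same order of magnitude as a large three-suite practice —
but every pipeline stage accepts far smaller runs, and the test suite uses
40 + 15 days (ordering checks use 120 + 120 days, which already yields more
than 5,000 future cases per facility).

Durations are drawn as `exp(mu + sigma·Z)` hours and rounded to whole
minutes (minimum 1), because the case-table interchange format carries
minute-resolution timestamps.  The rounding introduces a small log-scale
discretization (≈1% relative at a 45-minute case) that normality tests at
realistic sample sizes do not detect, and it makes minute-grid brute-force
enumeration exactly equivalent to the interval arithmetic — which the oracle
suite exploits.

What the generator does **not** emulate: turnover-time variability,
add-ons/cancellations, time-of-day effects on room use, surgeon-level
clustering, non-stationary case mix between periods.  Passing tests
therefore demonstrate correctness of the calculus and calibration of the
bound under the stated model, not the numerical feasibility percentages of
any real facility — those depend on the facility's own case-duration mix,
which is why the package reports methodology-level checks (calibration,
oracle equivalence, nestedness, ordering) rather than targeting specific
institutional percentages.

## Numerical and degenerate-input choices

* Student-t and Beta quantiles come from scipy; tests cross-check them
  against values frozen from an independent implementation and against
  closed forms.
* `s = 0` (identical historical durations) gives `B = exp(m)` exactly.
* Empty future tables make the coverage check an explicit error; empty
  strata produce `n = 0` rows with blank statistics and a report warning.
* Correlations are undefined (NaN) below 3 points or at zero variance;
  Spearman uses average ranks for ties.
* All timestamps are timezone-naive local clock times; adjacency and
  overlap never cross a facility-date boundary.
* Determinism: every random draw flows from a single integer seed through
  `numpy.random.default_rng`; identical seeds give byte-identical CSVs.
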