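"""Seeded synthetic surgical schedules for three facility archetypes.

The feasibility analysis needs two case tables — a multi-year historical
period used to fit per-procedure duration statistics and a subsequent
"future" period on which feasibility is scored.  Institutional case records
are not public, so this module generates tables with the statistical
structure the analysis assumes:

* per-procedure two-parameter log-normal surgical times (``exp(mu + sigma*Z)``
  hours, ``Z`` standard normal);
* three facility archetypes ordered short -> long median duration
  (ambulatory surgery center, pediatric hospital, adult inpatient suite);
* sequential non-overlapping cases per room within a weekday workday,
  separated by a fixed turnover;
* a shared procedure catalog between the historical and future periods
  (stationary distributions, disjoint date ranges);
* heavy-tailed procedure frequencies so that both >99-case codes (history
  cap exercised) and near-absent codes (sparse-history path) occur.

Archetype parameters (room counts, workday, catalog medians) are stand-ins
chosen to be realistic for a university group practice; they are not
calibrated to any particular institution.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

CSV_COLUMNS = ["facility", "room", "code", "service", "date", "surgery_start", "surgery_end"]

#: default first workday of the historical period (a Monday)
DEFAULT_START_DATE = dt.date(2016, 10, 3)


@dataclass(frozen=True)
class ProcedureSpec:
    """One procedure code with its log-normal duration parameters.

    ``mu`` and ``sigma`` are the mean and SD of log surgical time in
    log-hours; ``weight`` is the relative sampling frequency of the code.
    """

    code: str
    mu: float
    sigma: float
    weight: float

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if self.weight <= 0:
            raise ValueError(f"weight must be > 0, got {self.weight}")

    @property
    def median_hours(self) -> float:
        return float(np.exp(self.mu))


@dataclass(frozen=True)
class FacilityArchetype:
    """A surgical suite: rooms, workday, turnover, and a procedure catalog.

    Each procedure is deterministically assigned a clinical service label
    (``service_labels[i % len(service_labels)]`` for the i-th catalog entry).
    """

    name: str
    n_rooms: int
    procedures: tuple[ProcedureSpec, ...]
    service_labels: tuple[str, ...]
    workday_start: dt.time = dt.time(7, 45)
    workday_end: dt.time = dt.time(17, 0)
    turnover_minutes: int = 30

    def __post_init__(self) -> None:
        if self.n_rooms < 1:
            raise ValueError("n_rooms must be >= 1")
        if self.workday_start >= self.workday_end:
            raise ValueError("workday_start must precede workday_end")
        if self.turnover_minutes < 0:
            raise ValueError("turnover_minutes must be >= 0")
        codes = [p.code for p in self.procedures]
        if len(codes) != len(set(codes)):
            raise ValueError("procedure codes must be unique within a catalog")

    def service_of(self, index: int) -> str:
        return self.service_labels[index % len(self.service_labels)]

    def weighted_median_hours(self) -> float:
        """Frequency-weighted median of per-procedure median durations."""
        med = np.array([p.median_hours for p in self.procedures])
        w = np.array([p.weight for p in self.procedures], dtype=float)
        order = np.argsort(med)
        cw = np.cumsum(w[order]) / w.sum()
        return float(med[order][np.searchsorted(cw, 0.5)])


_ARCHETYPE_PARAMS = [
    # name, rooms, codes, center log-hours, services
    ("ambulatory", 8, 24, np.log(0.75),
     ("general", "orthopedics", "ent", "ophthalmology", "urology")),
    ("pediatric", 12, 26, np.log(1.5),
     ("peds_general", "peds_orthopedics", "peds_ent", "peds_cardiac", "peds_urology")),
    ("adult_inpatient", 16, 30, np.log(2.75),
     ("general", "orthopedics", "neurosurgery", "cardiothoracic", "vascular", "transplant")),
]

#: log-hour spread of procedure medians within a catalog (clipped at +-1)
_CATALOG_SPREAD = 0.5
#: number of deliberately rare codes per catalog (sparse-history path)
_N_RARE = 4


def _make_catalog(rng: np.random.Generator, prefix: str, n_codes: int,
                  center: float) -> tuple[ProcedureSpec, ...]:
    mu = center + np.clip(rng.normal(0.0, _CATALOG_SPREAD, n_codes), -1.0, 1.0)
    sigma = rng.uniform(0.25, 0.55, n_codes)
    # Zipf-like frequencies; the tail codes are made genuinely rare so that
    # codes with <5 (or zero) historical cases occur in a multi-year run.
    weight = (np.arange(1, n_codes + 1)) ** -1.1
    weight[-_N_RARE:] *= 1e-3
    return tuple(
        ProcedureSpec(code=f"{prefix}{i + 1:03d}", mu=float(mu[i]),
                      sigma=float(sigma[i]), weight=float(weight[i]))
        for i in range(n_codes)
    )


def make_archetypes(seed: int) -> tuple[FacilityArchetype, FacilityArchetype, FacilityArchetype]:
    """Three facility archetypes with strictly increasing median duration.

    Ordering ambulatory < pediatric < adult_inpatient holds by construction
    (catalog centers 0.75, 1.5, 2.75 h with clipped spread) and is asserted.
    """
    rng = np.random.default_rng(seed)
    archetypes = []
    for name, n_rooms, n_codes, center, services in _ARCHETYPE_PARAMS:
        prefix = name[:3].upper()
        catalog = _make_catalog(rng, prefix, n_codes, center)
        archetypes.append(FacilityArchetype(
            name=name, n_rooms=n_rooms, procedures=catalog, service_labels=services))
    medians = [a.weighted_median_hours() for a in archetypes]
    if not (medians[0] < medians[1] < medians[2]):
        raise AssertionError(f"archetype median ordering violated: {medians}")
    return tuple(archetypes)


def weekday_sequence(start: dt.date, n_days: int) -> list[dt.date]:
    """First ``n_days`` weekdays on or after ``start``."""
    out: list[dt.date] = []
    d = start
    while len(out) < n_days:
        if d.weekday() < 5:
            out.append(d)
        d += dt.timedelta(days=1)
    return out


def generate_schedule(archetype: FacilityArchetype, n_days: int, seed: int,
                      start_date: dt.date = DEFAULT_START_DATE) -> pd.DataFrame:
    """Simulate ``n_days`` weekdays of sequential cases in every room.

    Per room-date the first case starts at ``workday_start``; each subsequent
    case starts at the previous end plus the turnover; cases are appended
    while the next start is before ``workday_end`` (so a case may run past
    the end of the workday but never starts after it).  Durations are drawn
    log-normal per procedure and rounded to whole minutes (minimum 1).
    """
    if n_days < 0:
        raise ValueError(f"n_days must be >= 0, got {n_days}")
    rng = np.random.default_rng(seed)
    mus = np.array([p.mu for p in archetype.procedures])
    sigmas = np.array([p.sigma for p in archetype.procedures])
    codes = [p.code for p in archetype.procedures]
    services = [archetype.service_of(i) for i in range(len(codes))]
    w = np.array([p.weight for p in archetype.procedures], dtype=float)
    cumw = np.cumsum(w) / w.sum()

    turnover = dt.timedelta(minutes=archetype.turnover_minutes)
    rows: list[tuple] = []
    for date in weekday_sequence(start_date, n_days):
        day_end = dt.datetime.combine(date, archetype.workday_end)
        for room in range(1, archetype.n_rooms + 1):
            t = dt.datetime.combine(date, archetype.workday_start)
            while t < day_end:
                i = int(np.searchsorted(cumw, rng.random(), side="left"))
                z = rng.standard_normal()
                minutes = max(1, int(round(float(np.exp(mus[i] + sigmas[i] * z)) * 60.0)))
                end = t + dt.timedelta(minutes=minutes)
                rows.append((archetype.name, room, codes[i], services[i],
                             date.isoformat(), t, end))
                t = end + turnover
    df = pd.DataFrame(rows, columns=CSV_COLUMNS)
    df["surgery_start"] = pd.to_datetime(df["surgery_start"])
    df["surgery_end"] = pd.to_datetime(df["surgery_end"])
    return df


def generate_study(seed: int, hist_days: int = 750, future_days: int = 250,
                   start_date: dt.date = DEFAULT_START_DATE,
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Historical and future case tables from the same stationary catalogs.

    Defaults emulate a three-weekday-year historical period followed by a
    one-year future period across all three archetypes.  Date ranges are
    disjoint, with the historical range strictly before the future range.
    """
    if hist_days < 0 or future_days < 0:
        raise ValueError("day counts must be >= 0")
    root = np.random.default_rng(seed)
    arch_seed = int(root.integers(2**31))
    archetypes = make_archetypes(arch_seed)
    future_start = weekday_sequence(start_date, hist_days + 1)[-1]
    hist_frames, future_frames = [], []
    for arch in archetypes:
        hseed = int(root.integers(2**31))
        fseed = int(root.integers(2**31))
        hist_frames.append(generate_schedule(arch, hist_days, hseed, start_date))
        future_frames.append(generate_schedule(arch, future_days, fseed, future_start))
    hist = pd.concat(hist_frames, ignore_index=True)
    future = pd.concat(future_frames, ignore_index=True)
    return hist, future
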