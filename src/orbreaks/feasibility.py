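"""Break-feasibility calculus over suitable intervals and adjacent rooms.

A case's *suitable interval* runs from 15 minutes after surgery start (the
lead-in for stabilization, positioning, and documentation) to the earlier of
(a) surgery start plus the 5% lower prediction bound of its duration and
(b) the actual end of the case.  Within that interval the supervising
anesthesiologist can rely on the case still being in maintenance.

Supervision of multiple rooms uses cyclic adjacency of the sequentially
numbered rooms in use that day: room r's neighbors are the previous and next
rooms in sorted cyclic order.  For two rooms, the break must fit inside the
maximum-length overlap of the index case's suitable interval with a neighbor
case's suitable interval (an idle neighbor room adds no constraint); the
better of the two pairings is the "best chance", the worse the "least
chance".  For three rooms both neighbors constrain simultaneously.

A break of D minutes must *start* inside the policy's clock window (e.g.,
11:15-12:45 for lunch) but may end after it; an unrestricted policy allows a
start at any time of day.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import pandas as pd


@dataclass(frozen=True)
class BreakPolicy:
    """Break length, lead-in, start window, and prediction-bound risk.

    ``window_start``/``window_end`` are clock times bounding the break START;
    both ``None`` means the break may start any time ("throughout the
    workday").  ``deduct_lead_from_bound`` selects the alternative reading in
    which the predicted end of the suitable interval is surgery start plus
    the bound *minus* the lead-in (off by default; see docs/methods.md).
    """

    name: str
    duration_min: int
    lead_in_min: int = 15
    window_start: dt.time | None = None
    window_end: dt.time | None = None
    risk: float = 0.05
    deduct_lead_from_bound: bool = False

    def __post_init__(self) -> None:
        if self.duration_min <= 0:
            raise ValueError("duration_min must be > 0")
        if self.lead_in_min < 0:
            raise ValueError("lead_in_min must be >= 0")
        if (self.window_start is None) != (self.window_end is None):
            raise ValueError("window_start and window_end must both be set or both None")
        if self.window_start is not None and self.window_start > self.window_end:
            raise ValueError("window_start must not exceed window_end")
        if not 0.0 < self.risk < 1.0:
            raise ValueError("risk must be in (0, 1)")

    @property
    def unrestricted(self) -> bool:
        return self.window_start is None


@dataclass(frozen=True)
class SuitableInterval:
    """Half-open-in-spirit time span; empty iff ``end <= start``."""

    start: dt.datetime
    end: dt.datetime

    @property
    def empty(self) -> bool:
        return self.end <= self.start

    @property
    def length(self) -> dt.timedelta:
        return max(self.end - self.start, dt.timedelta(0))

    def intersect(self, other: "SuitableInterval") -> "SuitableInterval":
        s = max(self.start, other.start)
        return SuitableInterval(s, max(s, min(self.end, other.end)))


@dataclass(frozen=True)
class FeasibilityResult:
    """Nested per-case flags: three => two_least => two_best => single."""

    case_id: str
    single: bool
    two_best: bool
    two_least: bool
    three: bool


def suitable_interval(surgery_start: dt.datetime, surgery_end: dt.datetime,
                      bound_hours: float, policy: BreakPolicy) -> SuitableInterval:
    """Span of a case during which a break could be taken.

    Starts at surgery start + lead-in; ends at surgery start + prediction
    bound, unless the case finished sooner, in which event at the actual
    end.  Returns an empty interval when the bound does not even outlast
    the lead-in.
    """
    if not bound_hours == bound_hours:  # NaN guard: caller must have filtered
        raise ValueError("suitable_interval requires a usable prediction bound")
    start = surgery_start + dt.timedelta(minutes=policy.lead_in_min)
    predicted = surgery_start + dt.timedelta(hours=bound_hours)
    if policy.deduct_lead_from_bound:
        predicted -= dt.timedelta(minutes=policy.lead_in_min)
    end = min(predicted, surgery_end)
    return SuitableInterval(start, max(start, end))


def adjacent_rooms(room: int, rooms_present: list[int]) -> tuple[int, int]:
    """Previous and next room in sorted cyclic order of the rooms in use."""
    rooms = sorted(rooms_present)
    if room not in rooms:
        raise ValueError(f"room {room} not among rooms present {rooms}")
    i = rooms.index(room)
    k = len(rooms)
    return rooms[(i - 1) % k], rooms[(i + 1) % k]


def overlap_with_room(index_interval: SuitableInterval,
                      neighbor_intervals: list[SuitableInterval]) -> SuitableInterval:
    """Maximum-length overlap of the index interval with one neighbor room.

    If the neighbor room has no case whose suitable interval intersects the
    index interval, the room imposes no constraint and the full index
    interval is returned (the anesthesiologist effectively has one ongoing
    case).  Otherwise the single longest intersection is returned; among
    equal-length intersections the earliest-starting one wins.
    """
    best: SuitableInterval | None = None
    for nb in neighbor_intervals:
        if nb.empty:
            continue
        inter = index_interval.intersect(nb)
        if inter.empty:
            continue
        if best is None or (inter.length, -inter.start.timestamp()) > (
                best.length, -best.start.timestamp()):
            best = inter
    return index_interval if best is None else best


def _window_bounds(policy: BreakPolicy, date: dt.date) -> tuple[dt.datetime, dt.datetime]:
    return (dt.datetime.combine(date, policy.window_start),
            dt.datetime.combine(date, policy.window_end))


def break_feasible(interval: SuitableInterval, policy: BreakPolicy) -> bool:
    """Can a break of ``duration_min`` start in-window and fit the interval?

    The earliest permissible start is the later of the interval start and the
    window start; the break must begin no later than the window end and end
    within the interval (it may end after the window).
    """
    if interval.empty:
        return False
    dur = dt.timedelta(minutes=policy.duration_min)
    if policy.unrestricted:
        return interval.length >= dur
    ws, we = _window_bounds(policy, interval.start.date())
    s = max(interval.start, ws)
    return s <= we and s + dur <= interval.end


def window_denominator(interval: SuitableInterval, policy: BreakPolicy) -> bool:
    """Does the case belong in the denominator of a windowed analysis?

    Unrestricted policies count every case with a usable bound.  Windowed
    policies count a case only when a break starting inside the clock window
    could possibly overlap its suitable interval: the interval is non-empty,
    starts no later than the window end, and ends no earlier than the window
    start.
    """
    if policy.unrestricted:
        return True
    if interval.empty:
        return False
    ws, we = _window_bounds(policy, interval.start.date())
    return interval.start <= we and interval.end >= ws


def classify_case(case_id: str, room: int, rooms_present: list[int],
                  intervals_by_room: dict[int, list[tuple[str, SuitableInterval]]],
                  policy: BreakPolicy) -> FeasibilityResult:
    """Flags for one index case given the day's suitable intervals per room.

    ``intervals_by_room`` maps each room in use to ``(case_id, interval)``
    pairs for its cases with usable bounds; the index case is excluded from
    its own neighbor lists (relevant only when a room is its own cyclic
    neighbor).  Rooms whose cases all lack usable bounds contribute no
    constraint but still occupy a slot in the cyclic order.
    """
    own = [iv for cid, iv in intervals_by_room.get(room, []) if cid == case_id]
    if not own:
        raise ValueError(f"case {case_id} not found in room {room}")
    index_iv = own[0]
    if index_iv.empty:
        return FeasibilityResult(case_id, False, False, False, False)

    single = break_feasible(index_iv, policy)
    prev_room, next_room = adjacent_rooms(room, rooms_present)
    overlaps = []
    for nb_room in (prev_room, next_room):
        nb_ivs = [iv for cid, iv in intervals_by_room.get(nb_room, [])
                  if cid != case_id]
        overlaps.append(overlap_with_room(index_iv, nb_ivs))
    flags = [break_feasible(ov, policy) for ov in overlaps]
    two_best = flags[0] or flags[1]
    two_least = flags[0] and flags[1]
    three = break_feasible(overlaps[0].intersect(overlaps[1]), policy)
    return FeasibilityResult(case_id, single, two_best, two_least, three)


def classify_schedule(cases: pd.DataFrame, policy: BreakPolicy) -> pd.DataFrame:
    """Per-case feasibility flags and denominator membership for one policy.

    ``cases`` must carry ``case_id``, ``facility``, ``date``, ``room``,
    ``surgery_start``, ``surgery_end``, ``bound_hours`` and ``bound_usable``
    columns (see :func:`orbreaks.pipeline.attach_bounds`).  Cases without a
    usable bound are returned with an ``excluded_reason`` and no flags;
    windowed policies additionally exclude cases outside the denominator
    rule of :func:`window_denominator`.  Adjacency and overlap are computed
    within one facility-date only.
    """
    records = []
    for (facility, date), day in cases.groupby(["facility", "date"], sort=True):
        rooms_present = sorted(day["room"].unique())
        intervals_by_room: dict[int, list[tuple[str, SuitableInterval]]] = {}
        per_case_iv: dict[str, SuitableInterval | None] = {}
        for row in day.itertuples(index=False):
            if not row.bound_usable:
                per_case_iv[row.case_id] = None
                continue
            iv = suitable_interval(row.surgery_start.to_pydatetime(),
                                   row.surgery_end.to_pydatetime(),
                                   row.bound_hours, policy)
            per_case_iv[row.case_id] = iv
            intervals_by_room.setdefault(int(row.room), []).append((row.case_id, iv))
        for row in day.itertuples(index=False):
            rec = {"case_id": row.case_id, "facility": facility, "date": date,
                   "room": int(row.room), "service": row.service,
                   "single": False, "two_best": False, "two_least": False,
                   "three": False, "in_denominator": False, "excluded_reason": ""}
            iv = per_case_iv[row.case_id]
            if iv is None:
                rec["excluded_reason"] = ("no_history" if row.hist_n == 0
                                          else "insufficient_history")
                records.append(rec)
                continue
            rec["interval_start"] = iv.start
            rec["interval_end"] = iv.end
            rec["interval_min"] = iv.length.total_seconds() / 60.0
            if not window_denominator(iv, policy):
                rec["excluded_reason"] = "outside_window"
                records.append(rec)
                continue
            res = classify_case(row.case_id, int(row.room), rooms_present,
                                intervals_by_room, policy)
            rec.update(single=res.single, two_best=res.two_best,
                       two_least=res.two_least, three=res.three,
                       in_denominator=True)
            records.append(rec)
    out = pd.DataFrame(records)
    return out
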