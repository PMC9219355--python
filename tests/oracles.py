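"""Independent brute-force oracles used by the test suite.

The minute-grid classifier re-derives per-case break feasibility by
enumerating every candidate break-start minute instead of using interval
arithmetic, mirroring the same scheduling rules: 15-minute lead-in,
prediction-bound/actual-end truncation, cyclic room adjacency, maximum
overlap per neighbor room (earliest start on length ties), and in-window
break starts.  All schedules it is applied to have minute-aligned case
starts, for which grid enumeration is exhaustive.
"""

import datetime as dt

import numpy as np
import pandas as pd

ONE_MIN = dt.timedelta(minutes=1)


def _interval(case, policy):
    if case["bound_hours"] is None or case["bound_hours"] != case["bound_hours"]:
        return None
    s = case["start"] + dt.timedelta(minutes=policy.lead_in_min)
    predicted = case["start"] + dt.timedelta(hours=case["bound_hours"])
    if policy.deduct_lead_from_bound:
        predicted -= dt.timedelta(minutes=policy.lead_in_min)
    e = min(predicted, case["end"])
    return (s, e) if e > s else "empty"


def _grid_feasible(iv, policy, day):
    """Exhaustive search of minute-aligned break starts inside ``iv``."""
    if iv is None or iv == "empty":
        return False
    s0, e0 = iv
    dur = dt.timedelta(minutes=policy.duration_min)
    if policy.unrestricted:
        lo, hi = s0, e0
    else:
        lo = max(s0, dt.datetime.combine(day, policy.window_start))
        hi = dt.datetime.combine(day, policy.window_end)
    t = lo.replace(second=0, microsecond=0)
    if t < lo:
        t += ONE_MIN
    while t <= hi:
        if t >= s0 and t + dur <= e0:
            return True
        t += ONE_MIN
    return False


def _max_overlap(index_iv, neighbor_ivs):
    s0, e0 = index_iv
    best = None
    for nb in neighbor_ivs:
        if nb is None or nb == "empty":
            continue
        s, e = max(s0, nb[0]), min(e0, nb[1])
        if e <= s:
            continue
        if best is None or (e - s, -best_start_key(s)) > (best[1] - best[0],
                                                          -best_start_key(best[0])):
            best = (s, e)
    return index_iv if best is None else best


def best_start_key(t: dt.datetime) -> float:
    return t.timestamp()


def brute_force_day(cases, policy):
    """Flags for every case of one facility-day.

    ``cases``: list of dicts with keys case_id, room, start, end,
    bound_hours (None for unusable).  Returns {case_id: (single, two_best,
    two_least, three) or None when the case has no usable bound}.
    """
    rooms_present = sorted({c["room"] for c in cases})
    ivs = {c["case_id"]: _interval(c, policy) for c in cases}
    out = {}
    for c in cases:
        iv = ivs[c["case_id"]]
        if iv is None:
            out[c["case_id"]] = None
            continue
        day = c["start"].date()
        if iv == "empty":
            out[c["case_id"]] = (False, False, False, False)
            continue
        single = _grid_feasible(iv, policy, day)
        i = rooms_present.index(c["room"])
        k = len(rooms_present)
        neighbors = (rooms_present[(i - 1) % k], rooms_present[(i + 1) % k])
        chosen = []
        for nb_room in neighbors:
            nb_ivs = [ivs[d["case_id"]] for d in cases
                      if d["room"] == nb_room and d["case_id"] != c["case_id"]]
            nb_ivs = [v for v in nb_ivs if v not in (None, "empty")]
            chosen.append(_max_overlap(iv, nb_ivs))
        flags = [_grid_feasible(ch, policy, day) for ch in chosen]
        s = max(chosen[0][0], chosen[1][0])
        e = min(chosen[0][1], chosen[1][1])
        three = e > s and _grid_feasible((s, e), policy, day)
        out[c["case_id"]] = (single, flags[0] or flags[1],
                             flags[0] and flags[1], three)
    return out


def random_day_schedule(rng: np.random.Generator, day=dt.date(2020, 3, 2)):
    """Random small facility-day: <=4 rooms, <=3 cases per room."""
    n_rooms = int(rng.integers(1, 5))
    rooms = sorted(rng.choice(np.arange(1, 9), size=n_rooms, replace=False).tolist())
    cases = []
    cid = 0
    for room in rooms:
        t = dt.datetime.combine(day, dt.time(7, 0)) + dt.timedelta(
            minutes=int(rng.integers(0, 120)))
        for _ in range(int(rng.integers(0, 4))):
            dur = int(rng.integers(10, 300))
            end = t + dt.timedelta(minutes=dur)
            if rng.random() < 0.1:
                bound = None  # unusable prediction bound
            else:
                bound = dur / 60.0 * float(rng.uniform(0.3, 1.3))
            cases.append({"case_id": f"K{cid:03d}", "room": int(room),
                          "start": t, "end": end, "bound_hours": bound})
            cid += 1
            t = end + dt.timedelta(minutes=int(rng.integers(15, 60)))
    return cases


def day_to_frame(cases, facility="f"):
    rows = []
    for c in cases:
        rows.append({"case_id": c["case_id"], "facility": facility,
                     "date": c["start"].date().isoformat(), "room": c["room"],
                     "code": "X", "service": "svc",
                     "surgery_start": pd.Timestamp(c["start"]),
                     "surgery_end": pd.Timestamp(c["end"]),
                     "hist_n": 0 if c["bound_hours"] is None else 99,
                     "bound_hours": (np.nan if c["bound_hours"] is None
                                     else c["bound_hours"]),
                     "bound_usable": c["bound_hours"] is not None})
    return pd.DataFrame(rows)
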