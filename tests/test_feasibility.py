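import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import orbreaks as ob
from orbreaks.feasibility import BreakPolicy, SuitableInterval

from oracles import brute_force_day, day_to_frame, random_day_schedule

D = dt.date(2020, 3, 2)


def T(h, m=0):
    return dt.datetime.combine(D, dt.time(h, m))


LUNCH = BreakPolicy("lunch", 30, 15, dt.time(11, 15), dt.time(12, 45))
ANYTIME = BreakPolicy("anytime", 30, 15)


class TestSuitableInterval:
    def test_truncated_by_prediction_bound(self):
        iv = ob.suitable_interval(T(8), T(10, 30), 2.0, LUNCH)
        assert (iv.start, iv.end) == (T(8, 15), T(10, 0))

    def test_truncated_by_actual_end(self):
        iv = ob.suitable_interval(T(8), T(9, 30), 2.0, LUNCH)
        assert (iv.start, iv.end) == (T(8, 15), T(9, 30))

    def test_bound_shorter_than_lead_in_is_empty(self):
        iv = ob.suitable_interval(T(8), T(9), 0.2, LUNCH)
        assert iv.empty

    def test_alternative_reading_deducts_lead_in(self):
        pol = BreakPolicy("alt", 30, 15, deduct_lead_from_bound=True)
        iv = ob.suitable_interval(T(8), T(10, 30), 2.0, pol)
        assert (iv.start, iv.end) == (T(8, 15), T(9, 45))

    def test_unusable_bound_is_an_error(self):
        with pytest.raises(ValueError):
            ob.suitable_interval(T(8), T(9), float("nan"), LUNCH)


class TestAdjacentRooms:
    def test_wraps_cyclically(self):
        assert ob.adjacent_rooms(1, list(range(1, 11))) == (10, 2)
        assert ob.adjacent_rooms(10, list(range(1, 11))) == (9, 1)

    def test_middle_room(self):
        assert ob.adjacent_rooms(2, [1, 2, 3]) == (1, 3)

    def test_two_rooms_degenerate(self):
        assert ob.adjacent_rooms(1, [1, 2]) == (2, 2)

    def test_absent_room_rejected(self):
        with pytest.raises(ValueError):
            ob.adjacent_rooms(4, [1, 2, 3])


class TestOverlapWithRoom:
    def test_single_intersection(self):
        got = ob.overlap_with_room(SuitableInterval(T(8, 15), T(12)),
                                   [SuitableInterval(T(9), T(11))])
        assert (got.start, got.end) == (T(9), T(11))

    def test_idle_neighbor_imposes_no_constraint(self):
        idx = SuitableInterval(T(8, 15), T(12))
        assert ob.overlap_with_room(idx, []) is idx
        # non-intersecting neighbor is the same as an idle room
        assert ob.overlap_with_room(
            idx, [SuitableInterval(T(13), T(14))]) is idx

    def test_longest_intersection_wins(self):
        idx = SuitableInterval(T(8, 15), T(12))
        got = ob.overlap_with_room(idx, [SuitableInterval(T(8, 30), T(9)),
                                         SuitableInterval(T(10), T(11, 30))])
        assert (got.start, got.end) == (T(10), T(11, 30))

    def test_length_tie_prefers_earliest(self):
        idx = SuitableInterval(T(8), T(13))
        got = ob.overlap_with_room(idx, [SuitableInterval(T(10), T(11)),
                                         SuitableInterval(T(9), T(10))])
        assert (got.start, got.end) == (T(9), T(10))


class TestBreakFeasible:
    def test_window_clips_start(self):
        assert ob.break_feasible(SuitableInterval(T(8, 15), T(12)), LUNCH)

    def test_empty_interval_infeasible(self):
        assert not ob.break_feasible(SuitableInterval(T(9), T(9)), LUNCH)

    def test_break_may_end_after_window(self):
        assert ob.break_feasible(SuitableInterval(T(12, 40), T(13, 30)), LUNCH)
        assert not ob.break_feasible(SuitableInterval(T(12, 50), T(14)), LUNCH)

    def test_unrestricted_needs_only_length(self):
        assert ob.break_feasible(SuitableInterval(T(15), T(15, 30)), ANYTIME)
        assert not ob.break_feasible(SuitableInterval(T(15), T(15, 29)), ANYTIME)

    @given(start_min=st.integers(0, 600), length=st.integers(0, 400),
           widen=st.integers(0, 90), dur=st.integers(5, 60),
           extra=st.integers(1, 60))
    def test_window_and_duration_monotonicity(self, start_min, length, widen,
                                              dur, extra):
        """Widening the window or shortening the break never hurts."""
        iv = SuitableInterval(T(7) + dt.timedelta(minutes=start_min),
                              T(7) + dt.timedelta(minutes=start_min + length))
        narrow = BreakPolicy("n", dur, 15, dt.time(11, 15), dt.time(12, 45))
        wide_start = (T(11, 15) - dt.timedelta(minutes=widen)).time()
        wide_end = (T(12, 45) + dt.timedelta(minutes=widen)).time()
        wide = BreakPolicy("w", dur, 15, wide_start, wide_end)
        longer = BreakPolicy("l", dur + extra, 15, dt.time(11, 15),
                             dt.time(12, 45))
        if ob.break_feasible(iv, narrow):
            assert ob.break_feasible(iv, wide)
        if ob.break_feasible(iv, longer):
            assert ob.break_feasible(iv, narrow)
        # unrestricted dominates any window at the same duration
        if ob.break_feasible(iv, narrow):
            assert ob.break_feasible(
                iv, BreakPolicy("u", dur, 15))


class TestPolicyValidation:
    def test_rejects_bad_policies(self):
        with pytest.raises(ValueError):
            BreakPolicy("x", 0)
        with pytest.raises(ValueError):
            BreakPolicy("x", 30, 15, dt.time(13), dt.time(12))
        with pytest.raises(ValueError):
            BreakPolicy("x", 30, 15, dt.time(11), None)


class TestClassifyCase:
    def _frame(self, cases):
        return day_to_frame(cases)

    def test_idle_neighbors_make_all_flags_equal_single(self):
        cases = [{"case_id": "K0", "room": 2, "start": T(8), "end": T(12, 30),
                  "bound_hours": 4.0}]  # iv [08:15, 12:00] reaches the window
        res = ob.classify_schedule(self._frame(cases), LUNCH)
        row = res.iloc[0]
        assert bool(row.single) and bool(row.two_best) and bool(row.two_least) \
            and bool(row.three)

    def test_best_versus_least_chance(self):
        # index 10:00-13:00 usable; neighbors give 90- and 20-minute overlaps
        cases = [
            {"case_id": "K0", "room": 2, "start": T(10), "end": T(14),
             "bound_hours": 3.0},                       # iv [10:15, 13:00]
            {"case_id": "K1", "room": 1, "start": T(11), "end": T(14),
             "bound_hours": 1.75},                      # iv [11:15, 12:45]
            {"case_id": "K2", "room": 3, "start": T(12, 15), "end": T(14),
             "bound_hours": 35 / 60},                   # iv [12:30, 12:50]
        ]
        # pairings: room 1 overlap [11:15, 12:45] (90 min, feasible);
        # room 3 overlap [12:30, 12:50] (20 min, a 30-min break cannot fit)
        res = ob.classify_schedule(self._frame(cases), LUNCH).set_index("case_id")
        row = res.loc["K0"]
        assert bool(row.single) and bool(row.two_best)
        assert not bool(row.two_least) and not bool(row.three)

    def test_unusable_bound_cases_excluded_with_reason(self):
        cases = [{"case_id": "K0", "room": 1, "start": T(8), "end": T(12),
                  "bound_hours": 3.0},
                 {"case_id": "K1", "room": 2, "start": T(8), "end": T(12),
                  "bound_hours": None}]
        res = ob.classify_schedule(self._frame(cases), ANYTIME).set_index("case_id")
        assert res.loc["K1", "excluded_reason"] == "no_history"
        assert not res.loc["K1", "in_denominator"]
        assert res.loc["K0", "in_denominator"]

    def test_outside_window_excluded_from_denominator(self):
        cases = [{"case_id": "K0", "room": 1, "start": T(14), "end": T(16),
                  "bound_hours": 2.0}]  # iv [14:15, 16:00], after lunch window
        res = ob.classify_schedule(self._frame(cases), LUNCH)
        assert res.iloc[0]["excluded_reason"] == "outside_window"

    @given(seed=st.integers(0, 10_000))
    def test_nestedness_on_random_days(self, seed):
        rng = np.random.default_rng(seed)
        cases = random_day_schedule(rng)
        if not cases:
            return
        for pol in (LUNCH, ANYTIME):
            res = ob.classify_schedule(day_to_frame(cases), pol)
            denom = res.loc[res["in_denominator"]]
            assert (denom["three"] <= denom["two_least"]).all()
            assert (denom["two_least"] <= denom["two_best"]).all()
            assert (denom["two_best"] <= denom["single"]).all()

    @given(seed=st.integers(0, 10_000))
    def test_flags_match_minute_grid_oracle(self, seed):
        rng = np.random.default_rng(seed)
        cases = random_day_schedule(rng)
        if not cases:
            return
        dur = int(rng.choice([15, 30, 45]))
        if rng.random() < 0.5:
            pol = BreakPolicy("p", dur, 15)
        else:
            h = int(rng.integers(8, 15))
            pol = BreakPolicy("p", dur, 15, dt.time(h, 0),
                              dt.time(h + 1, 30))
        res = ob.classify_schedule(day_to_frame(cases), pol).set_index("case_id")
        expected = brute_force_day(cases, pol)
        for cid, flags in expected.items():
            row = res.loc[cid]
            if flags is None:
                assert row["excluded_reason"] in ("no_history",
                                                  "insufficient_history")
                continue
            got = (bool(row.single), bool(row.two_best), bool(row.two_least),
                   bool(row.three))
            assert got == flags, f"{cid}: {got} != oracle {flags}"
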