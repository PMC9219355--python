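import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import orbreaks as ob

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")

STUDY_SEED = 1234


@pytest.fixture(scope="session")
def small_study():
    """Moderate synthetic study shared across tests (40 + 15 weekdays)."""
    return ob.generate_study(STUDY_SEED, hist_days=40, future_days=15)


@pytest.fixture(scope="session")
def small_analysis(small_study):
    hist, future = small_study
    return ob.analyze_study(hist, future)


def make_case_table(rows):
    """Case table from (facility, room, code, service, start, end) tuples."""
    recs = []
    for facility, room, code, service, start, end in rows:
        recs.append((facility, room, code, service, start.date().isoformat(),
                     pd.Timestamp(start), pd.Timestamp(end)))
    return pd.DataFrame(recs, columns=["facility", "room", "code", "service",
                                       "date", "surgery_start", "surgery_end"])


def constant_history(code, hours, n=2, facility="f", day=dt.date(2019, 1, 7)):
    """History of n identical-duration cases: s=0, so bound == duration."""
    rows = []
    for i in range(n):
        start = dt.datetime.combine(day + dt.timedelta(days=i), dt.time(8, 0))
        end = start + dt.timedelta(hours=hours)
        rows.append((facility, 1, code, "svc", start, end))
    return make_case_table(rows)
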