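"""Shared hypothesis strategies and random-cohort helpers for the tests."""

from __future__ import annotations

import datetime as dt

import numpy as np
from hypothesis import strategies as st

from opencohort import AnalysisPeriod, ObservationRecord

DATE_MIN = dt.date(2000, 1, 1)
DATE_MAX = dt.date(2030, 12, 31)

dates = st.dates(min_value=DATE_MIN, max_value=DATE_MAX)


@st.composite
def observation_records(draw, allow_outside_events: bool = True):
    """Arbitrary records; events may fall outside follow-up by default
    (the counting rules must process such records verbatim)."""
    d1 = draw(dates)
    d2 = draw(dates)
    start, end = min(d1, d2), max(d1, d2)
    if allow_outside_events:
        event = draw(st.one_of(st.none(), dates))
    else:
        event = draw(st.one_of(st.none(), st.dates(min_value=start, max_value=end)))
    return ObservationRecord(start_date=start, end_date=end, event_date=event)


@st.composite
def analysis_periods(draw):
    d1 = draw(dates)
    d2 = draw(dates)
    if d1 == d2:
        d2 = d2 + dt.timedelta(days=1)
    start, end = min(d1, d2), max(d1, d2)
    return AnalysisPeriod(period_start=start, period_end=end)


def random_cohort(rng: np.random.Generator, n: int,
                  origin: dt.date = dt.date(2004, 1, 1),
                  span_days: int = 4000) -> list[ObservationRecord]:
    """Adversarial random records: arbitrary intervals, events anywhere
    (before entry, after exit, missing), zero-length follow-up included."""
    records = []
    for i in range(n):
        a, b = sorted(rng.integers(0, span_days, size=2))
        if rng.random() < 0.6:
            event_off = int(rng.integers(-200, span_days + 200))
            event = origin + dt.timedelta(days=event_off)
        else:
            event = None
        records.append(
            ObservationRecord(
                start_date=origin + dt.timedelta(days=int(a)),
                end_date=origin + dt.timedelta(days=int(b)),
                event_date=event,
                record_id=f"r{i}",
            )
        )
    return records


def random_periods(rng: np.random.Generator, n: int,
                   origin: dt.date = dt.date(2004, 1, 1),
                   span_days: int = 4000,
                   max_len_days: int = 450) -> list[AnalysisPeriod]:
    periods = []
    for _ in range(n):
        start_off = int(rng.integers(0, span_days))
        length = int(rng.integers(1, max_len_days))
        start = origin + dt.timedelta(days=start_off)
        periods.append(
            AnalysisPeriod(period_start=start,
                           period_end=start + dt.timedelta(days=length))
        )
    return periods
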