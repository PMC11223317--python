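"""Period-incidence counting rules: event indicator and person-time.

Over a half-open period ``[period_start, period_end)``:

Numerator — a record contributes one event iff
``period_start <= event_date < period_end`` (strict at the period end),
``end_date >= period_start`` and ``start_date < period_end``.

Denominator — person-time at risk, censored at the earliest of the
follow-up end, the event, and the period end::

    start_observation = max(start_date, period_start)
    end_observation   = min(end_date, event_date, period_end)

provided the eligibility conditions hold (follow-up overlaps the period,
and the event — when present — falls on/after the period start and
strictly after follow-up start). A missing event date is non-binding
inside the minimum. Days are accumulated as exact integers and divided
by 365.25 once per record; the divisor is fixed, not configurable.

The numerator does not require ``event_date <= end_date``: a record with
an event dated after follow-up end but inside the period is counted in
the numerator while its person-time is censored at ``end_date``. Such
records are surfaced by :func:`opencohort.cohort.validate_cohort`.
"""

from __future__ import annotations

import logging
import math
from typing import Optional, Sequence

from .cohort import AnalysisPeriod, IncidenceEstimate, ObservationRecord
from .uncertainty import byar_interval, scale_interval

logger = logging.getLogger(__name__)

#: Fixed days-per-year divisor for person-time.
DAYS_PER_YEAR = 365.25


def incidence_numerator_indicator(
    record: ObservationRecord, period: AnalysisPeriod
) -> int:
    """1 iff the record's event is new within the period; 0 otherwise."""
    event = record.event_date
    if event is None:
        return 0
    return int(
        period.period_start <= event < period.period_end
        and record.end_date >= period.period_start
        and record.start_date < period.period_end
    )


def _at_risk(record: ObservationRecord, period: AnalysisPeriod) -> bool:
    event = record.event_date
    return (
        record.start_date < period.period_end
        and record.end_date >= period.period_start
        and (event is None or event >= period.period_start)
        and (event is None or event > record.start_date)
    )


def person_time_days(record: ObservationRecord, period: AnalysisPeriod) -> int:
    """At-risk days contributed by a record within the period (integer).

    0 when the eligibility conditions fail or the observation window is
    degenerate.
    """
    if not _at_risk(record, period):
        return 0
    start_observation = max(record.start_date, period.period_start)
    end_observation = min(record.end_date, period.period_end)
    if record.event_date is not None:
        end_observation = min(end_observation, record.event_date)
    return max((end_observation - start_observation).days, 0)


def person_time(record: ObservationRecord, period: AnalysisPeriod) -> float:
    """Person-years at risk contributed by a record within the period."""
    return person_time_days(record, period) / DAYS_PER_YEAR


def period_incidence(
    cohort: Sequence[ObservationRecord],
    period: AnalysisPeriod,
    multiplier: int = 100_000,
    ci_level: float = 0.95,
    stratifier: str = "overall",
    stratum: str = "overall",
) -> IncidenceEstimate:
    """Incidence rate of the cohort over the period, per ``multiplier``
    person-years, with a Byar confidence interval on the event count.

    Person-time is summed in integer days across records before the
    single division by 365.25, avoiding float accumulation drift. Zero
    person-years yields an explicitly-undefined estimate (NaN), never a
    division error.
    """
    numerator = sum(incidence_numerator_indicator(r, period) for r in cohort)
    total_days = sum(person_time_days(r, period) for r in cohort)
    person_years = total_days / DAYS_PER_YEAR
    if person_years > 0:
        ci = byar_interval(numerator, ci_level)
        lower, estimate, upper = scale_interval(ci, person_years, multiplier)
    else:
        logger.warning(
            "incidence over %s: zero person-time, estimate undefined", period.label
        )
        lower = estimate = upper = math.nan
    return IncidenceEstimate(
        metric="incidence",
        period_label=period.label or period.period_start.isoformat(),
        period_start=period.period_start,
        period_end=period.period_end,
        numerator=numerator,
        person_years=person_years,
        estimate=estimate,
        ci_lower=lower,
        ci_upper=upper,
        multiplier=multiplier,
        ci_level=ci_level,
        stratifier=stratifier,
        stratum=stratum,
    )
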