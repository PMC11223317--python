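"""Point-prevalence counting rules and the per-period estimate.

Numerator rule — a record counts at an anchor date P iff all three hold:

* ``start_date <= P``  (follow-up began on or before P)
* ``end_date   >= P``  (follow-up had not ended before P)
* ``event_date <= P``  (an event was recorded on or before P)

Denominator rule — the first two conditions only; the event date is
irrelevant. A missing event date satisfies no inequality, so it
short-circuits the numerator indicator to 0.
"""

from __future__ import annotations

import datetime
import logging
import math
from typing import Optional, Sequence

from .cohort import AnalysisPeriod, ObservationRecord, PrevalenceEstimate
from .uncertainty import byar_interval, scale_interval

logger = logging.getLogger(__name__)


def prevalence_numerator_indicator(
    record: ObservationRecord, period_start: datetime.date
) -> int:
    """1 iff the record is under follow-up at ``period_start`` with an
    event recorded on or before it; 0 otherwise (including missing event)."""
    if record.event_date is None:
        return 0
    return int(
        record.start_date <= period_start
        and record.end_date >= period_start
        and record.event_date <= period_start
    )


def prevalence_denominator_indicator(
    record: ObservationRecord, period_start: datetime.date
) -> int:
    """1 iff the record is under follow-up at ``period_start``."""
    return int(record.start_date <= period_start and record.end_date >= period_start)


def point_prevalence(
    cohort: Sequence[ObservationRecord],
    period_start: datetime.date,
    multiplier: int = 100_000,
    ci_level: float = 0.95,
    label: Optional[str] = None,
    period: Optional[AnalysisPeriod] = None,
    stratifier: str = "overall",
    stratum: str = "overall",
) -> PrevalenceEstimate:
    """Point prevalence of the cohort at ``period_start``.

    The Byar interval is computed on the numerator count and scaled by
    ``multiplier / denominator``. A zero denominator yields an
    explicitly-undefined estimate (NaN estimate and bounds), never a
    division error.
    """
    numerator = sum(prevalence_numerator_indicator(r, period_start) for r in cohort)
    denominator = sum(prevalence_denominator_indicator(r, period_start) for r in cohort)
    if denominator > 0:
        ci = byar_interval(numerator, ci_level)
        lower, estimate, upper = scale_interval(ci, denominator, multiplier)
    else:
        logger.warning(
            "point prevalence at %s: zero denominator, estimate undefined",
            period_start,
        )
        lower = estimate = upper = math.nan
    return PrevalenceEstimate(
        metric="point_prevalence",
        period_label=label if label is not None else period_start.isoformat(),
        period_start=period_start,
        period_end=period.period_end if period is not None else period_start,
        numerator=numerator,
        denominator=denominator,
        estimate=estimate,
        ci_lower=lower,
        ci_upper=upper,
        multiplier=multiplier,
        ci_level=ci_level,
        stratifier=stratifier,
        stratum=stratum,
    )
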