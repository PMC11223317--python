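"""Period grids, per-period orchestration, and subgroup stratification.

Builds gap-free half-open period grids (annual, quarterly or monthly)
over a study window and evaluates the requested metrics per period,
overall and within each level of each requested stratifier. Point
prevalence is anchored at each period's start date; incidence runs over
the half-open period. Period prevalence is an optional rearrangement of
the two rulesets: the numerator condition relaxes the point-prevalence
event anchor to "event before the period end while follow-up overlaps
the period", and the denominator counts persons whose follow-up overlaps
the period (the incidence-style overlap conditions, as a head count
rather than person-time).
"""

from __future__ import annotations

import datetime
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import yaml

from .cohort import (
    AnalysisPeriod,
    Estimate,
    ObservationRecord,
    PrevalenceEstimate,
    StratifierError,
    available_stratifiers,
)
from .prevalence import point_prevalence
from .incidence import period_incidence
from .uncertainty import byar_interval, scale_interval

logger = logging.getLogger(__name__)

FREQUENCIES = ("annual", "quarterly", "monthly")
METRICS = ("incidence", "point_prevalence", "period_prevalence")

#: Category assigned to records lacking a value for a requested stratifier.
MISSING_CATEGORY = "missing"


@dataclass
class AnalysisConfig:
    """Study window, period frequency, metrics and reporting options."""

    start_year: int
    end_year: int
    frequency: str = "annual"
    metrics: tuple[str, ...] = ("incidence", "point_prevalence")
    multiplier: int = 100_000
    ci_level: float = 0.95
    stratifiers: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.start_year > self.end_year:
            raise ValueError(
                f"start_year {self.start_year} must not exceed end_year {self.end_year}"
            )
        if self.frequency not in FREQUENCIES:
            raise ValueError(
                f"unknown frequency {self.frequency!r}; choose from {FREQUENCIES}"
            )
        self.metrics = tuple(self.metrics)
        if not self.metrics:
            raise ValueError("at least one metric is required")
        for metric in self.metrics:
            if metric not in METRICS:
                raise ValueError(
                    f"unknown metric {metric!r}; choose from {METRICS}"
                )
        if self.multiplier <= 0:
            raise ValueError("multiplier must be positive")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must be in (0, 1)")
        self.stratifiers = tuple(self.stratifiers)

    @classmethod
    def from_file(cls, path: Union[str, Path], **overrides) -> "AnalysisConfig":
        """Load a config from a YAML (or JSON) mapping, applying overrides."""
        with Path(path).open(encoding="utf-8") as handle:
            data = yaml.safe_load(handle) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a mapping")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def make_period_grid(config: AnalysisConfig) -> list[AnalysisPeriod]:
    """Abutting half-open periods tiling Jan 1 of start_year to Jan 1 of
    end_year + 1, labelled by year / year-quarter / year-month."""
    starts: list[tuple[datetime.date, str]] = []
    if config.frequency == "annual":
        for year in range(config.start_year, config.end_year + 1):
            starts.append((datetime.date(year, 1, 1), str(year)))
    elif config.frequency == "quarterly":
        for year in range(config.start_year, config.end_year + 1):
            for quarter, month in enumerate((1, 4, 7, 10), start=1):
                starts.append((datetime.date(year, month, 1), f"{year}Q{quarter}"))
    else:  # monthly
        for year in range(config.start_year, config.end_year + 1):
            for month in range(1, 13):
                starts.append((datetime.date(year, month, 1), f"{year}-{month:02d}"))
    boundaries = [start for start, _ in starts]
    boundaries.append(datetime.date(config.end_year + 1, 1, 1))
    return [
        AnalysisPeriod(period_start=boundaries[i], period_end=boundaries[i + 1],
                       label=starts[i][1])
        for i in range(len(starts))
    ]


def period_prevalence(
    cohort: Sequence[ObservationRecord],
    period: AnalysisPeriod,
    multiplier: int = 100_000,
    ci_level: float = 0.95,
    stratifier: str = "overall",
    stratum: str = "overall",
) -> PrevalenceEstimate:
    """Prevalence over a period, as persons ever-diagnosed among persons
    whose follow-up overlaps the period.

    Numerator: ``event_date < period_end`` with ``end_date >=
    period_start`` and ``start_date < period_end``. Denominator: the two
    overlap conditions alone, as a head count. CI handling matches point
    prevalence. This is an interpretation of a rearrangement of the two
    primary rulesets, not a primary metric.
    """
    numerator = 0
    denominator = 0
    for record in cohort:
        overlaps = (
            record.start_date < period.period_end
            and record.end_date >= period.period_start
        )
        if not overlaps:
            continue
        denominator += 1
        if record.event_date is not None and record.event_date < period.period_end:
            numerator += 1
    if denominator > 0:
        ci = byar_interval(numerator, ci_level)
        lower, estimate, upper = scale_interval(ci, denominator, multiplier)
    else:
        logger.warning(
            "period prevalence over %s: zero denominator, estimate undefined",
            period.label,
        )
        lower = estimate = upper = math.nan
    return PrevalenceEstimate(
        metric="period_prevalence",
        period_label=period.label or period.period_start.isoformat(),
        period_start=period.period_start,
        period_end=period.period_end,
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


def _stratum_value(record: ObservationRecord, name: str) -> str:
    value = record.strata.get(name, "")
    return value if value else MISSING_CATEGORY


def _compute_one(
    metric: str,
    cohort: Sequence[ObservationRecord],
    period: AnalysisPeriod,
    config: AnalysisConfig,
    stratifier: str,
    stratum: str,
) -> Estimate:
    if metric == "incidence":
        return period_incidence(
            cohort, period, config.multiplier, config.ci_level,
            stratifier=stratifier, stratum=stratum,
        )
    if metric == "point_prevalence":
        return point_prevalence(
            cohort, period.period_start, config.multiplier, config.ci_level,
            label=period.label, period=period,
            stratifier=stratifier, stratum=stratum,
        )
    return period_prevalence(
        cohort, period, config.multiplier, config.ci_level,
        stratifier=stratifier, stratum=stratum,
    )


def compute_time_series(
    cohort: Sequence[ObservationRecord], config: AnalysisConfig
) -> list[Estimate]:
    """One estimate per period x metric x (overall + each stratum level).

    Stratum levels are the sorted union of values observed anywhere in
    the cohort (missing values form an explicit "missing" level), so a
    level empty in some period is still emitted there — with an
    undefined estimate, not dropped. Output order and values are
    independent of record order.
    """
    available = available_stratifiers(cohort)
    level_sets: dict[str, list[str]] = {}
    for name in config.stratifiers:
        if name not in available:
            raise StratifierError(
                f"unknown stratifier {name!r}; available stratifiers: "
                f"{available or 'none'}"
            )
        level_sets[name] = sorted({_stratum_value(r, name) for r in cohort})

    subsets: dict[tuple[str, str], list[ObservationRecord]] = {}
    for name, levels in level_sets.items():
        for level in levels:
            subsets[(name, level)] = [
                r for r in cohort if _stratum_value(r, name) == level
            ]

    results: list[Estimate] = []
    grid = make_period_grid(config)
    for metric in config.metrics:
        for period in grid:
            results.append(
                _compute_one(metric, cohort, period, config, "overall", "overall")
            )
            for name, levels in level_sets.items():
                for level in levels:
                    results.append(
                        _compute_one(
                            metric, subsets[(name, level)], period, config, name, level
                        )
                    )
    return results
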