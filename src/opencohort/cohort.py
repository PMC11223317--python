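"""Domain types, validation and CSV I/O for open-cohort observation tables.

An observation row describes one person's follow-up interval (start/end
calendar dates), an optional first-event date, and any number of
categorical stratifier labels. All date arithmetic is done on calendar
dates at day granularity.
"""

from __future__ import annotations

import csv
import datetime
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

logger = logging.getLogger(__name__)

#: Input cell values parsed as a missing event date.
MISSING_TOKENS = frozenset({"", "NA"})

#: column_map keys with fixed meaning; everything else maps a stratifier
#: name to a column name.
RESERVED_ROLES = ("start_date", "end_date", "event_date", "record_id")

DEFAULT_DATE_FORMAT = "%Y-%m-%d"


class SchemaError(ValueError):
    """A mandatory column is absent from the input file."""


class StratifierError(ValueError):
    """A requested stratifier is not present on the cohort."""


@dataclass(frozen=True)
class ObservationRecord:
    """One person's follow-up interval with an optional first-event date.

    ``event_date`` may legitimately fall outside ``[start_date, end_date]``;
    such records are kept (and processed verbatim by the counting rules)
    but flagged by :func:`validate_cohort`.
    """

    start_date: datetime.date
    end_date: datetime.date
    event_date: Optional[datetime.date] = None
    strata: Mapping[str, str] = field(default_factory=dict)
    record_id: str = ""

    def __post_init__(self) -> None:
        if self.start_date > self.end_date:
            raise ValueError(
                f"start_date {self.start_date} is after end_date {self.end_date}"
                f" (record_id={self.record_id!r})"
            )


@dataclass(frozen=True)
class AnalysisPeriod:
    """A half-open calendar window ``[period_start, period_end)``."""

    period_start: datetime.date
    period_end: datetime.date
    label: str = ""

    def __post_init__(self) -> None:
        if self.period_start >= self.period_end:
            raise ValueError(
                f"period_start {self.period_start} must precede period_end "
                f"{self.period_end}"
            )

    @property
    def length_days(self) -> int:
        return (self.period_end - self.period_start).days


@dataclass(frozen=True)
class PrevalenceEstimate:
    """A per-period prevalence: count numerator over count denominator."""

    metric: str  # "point_prevalence" or "period_prevalence"
    period_label: str
    period_start: datetime.date
    period_end: datetime.date
    numerator: int
    denominator: int
    estimate: float  # per `multiplier` population; NaN when undefined
    ci_lower: float
    ci_upper: float
    multiplier: int = 100_000
    ci_level: float = 0.95
    stratifier: str = "overall"
    stratum: str = "overall"

    def __post_init__(self) -> None:
        if self.numerator > self.denominator:
            raise ValueError(
                f"numerator {self.numerator} exceeds denominator {self.denominator}"
            )

    @property
    def undefined(self) -> bool:
        return self.denominator == 0


@dataclass(frozen=True)
class IncidenceEstimate:
    """A per-period incidence rate: event count over person-years."""

    metric: str  # always "incidence"
    period_label: str
    period_start: datetime.date
    period_end: datetime.date
    numerator: int
    person_years: float
    estimate: float  # per `multiplier` person-years; NaN when undefined
    ci_lower: float
    ci_upper: float
    multiplier: int = 100_000
    ci_level: float = 0.95
    stratifier: str = "overall"
    stratum: str = "overall"

    def __post_init__(self) -> None:
        if self.numerator < 0 or self.person_years < 0:
            raise ValueError("numerator and person_years must be non-negative")

    @property
    def undefined(self) -> bool:
        return self.person_years == 0


Estimate = Union[PrevalenceEstimate, IncidenceEstimate]


@dataclass
class LoadReport:
    """Outcome of reading a cohort CSV: row counts and per-row messages."""

    n_rows: int = 0
    n_loaded: int = 0
    n_rejected: int = 0
    n_missing_event: int = 0
    messages: list[str] = field(default_factory=list)

    def add(self, message: str) -> None:
        self.messages.append(message)
        logger.warning(message)


@dataclass
class ValidationReport:
    """Counts of suspicious-but-loadable record shapes. Reporting only."""

    n_records: int = 0
    event_before_start: int = 0
    event_after_end: int = 0
    zero_length_followup: int = 0

    @property
    def n_warnings(self) -> int:
        return self.event_before_start + self.event_after_end + self.zero_length_followup


def _parse_date(text: str, date_format: str) -> datetime.date:
    return datetime.datetime.strptime(text.strip(), date_format).date()


def read_cohort(
    path: Union[str, Path],
    column_map: Optional[Mapping[str, str]] = None,
    date_format: str = DEFAULT_DATE_FORMAT,
    strict: bool = False,
) -> tuple[list[ObservationRecord], LoadReport]:
    """Read an observation table from CSV.

    Parameters
    ----------
    path:
        CSV file with a mandatory header row.
    column_map:
        Maps the roles ``start_date``, ``end_date``, ``event_date`` and
        ``record_id`` to column names; any other key names a stratifier
        and maps it to its column. Defaults to identity for the reserved
        roles. Columns not named in the map are ignored.
    date_format:
        ``strptime`` format for every date column (default ISO-8601).
    strict:
        When True, rows whose event date falls outside the follow-up
        interval are rejected instead of loaded-with-warning.

    Returns
    -------
    (records, report):
        Validated records plus a :class:`LoadReport`. Rows violating
        ``start_date <= end_date``, or with unparseable dates, are
        rejected and counted in the report.
    """
    path = Path(path)
    cmap = dict(column_map) if column_map else {}
    for role in ("start_date", "end_date", "event_date", "record_id"):
        cmap.setdefault(role, role)

    report = LoadReport()
    records: list[ObservationRecord] = []

    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: file is empty (no header row)")
        header = set(reader.fieldnames)
        for role in ("start_date", "end_date"):
            if cmap[role] not in header:
                raise SchemaError(
                    f"{path}: mandatory column {cmap[role]!r} (role {role!r}) "
                    f"not found; columns present: {sorted(header)}"
                )
        stratifier_cols = {
            name: col for name, col in cmap.items() if name not in RESERVED_ROLES
        }
        for name, col in stratifier_cols.items():
            if col not in header:
                raise SchemaError(
                    f"{path}: stratifier column {col!r} (stratifier {name!r}) not "
                    f"found; available columns: {sorted(header)}"
                )
        has_event = cmap["event_date"] in header
        has_id = cmap["record_id"] in header

        for row_number, row in enumerate(reader, start=2):  # 1 is the header
            report.n_rows += 1
            try:
                start = _parse_date(row[cmap["start_date"]], date_format)
                end = _parse_date(row[cmap["end_date"]], date_format)
                event: Optional[datetime.date] = None
                if has_event:
                    cell = (row[cmap["event_date"]] or "").strip()
                    if cell not in MISSING_TOKENS:
                        event = _parse_date(cell, date_format)
            except (ValueError, TypeError) as exc:
                report.n_rejected += 1
                report.add(f"row {row_number}: unparseable date ({exc})")
                continue
            if start > end:
                report.n_rejected += 1
                report.add(
                    f"row {row_number}: end_date {end} precedes start_date {start}; "
                    "row rejected"
                )
                continue
            if event is None:
                report.n_missing_event += 1
            elif strict and not (start <= event <= end):
                report.n_rejected += 1
                report.add(
                    f"row {row_number}: event_date {event} outside follow-up "
                    f"[{start}, {end}]; row rejected (strict mode)"
                )
                continue
            strata = {
                name: ((row.get(col) or "").strip() or "missing")
                for name, col in stratifier_cols.items()
            }
            record_id = (row.get(cmap["record_id"]) or "").strip() if has_id else ""
            records.append(
                ObservationRecord(
                    start_date=start,
                    end_date=end,
                    event_date=event,
                    strata=strata,
                    record_id=record_id or str(row_number),
                )
            )
            report.n_loaded += 1

    if report.n_rows == 0:
        report.add(f"{path}: no data rows (header only)")
    logger.info(
        "read_cohort(%s): %d rows, %d loaded, %d rejected, %d missing event",
        path, report.n_rows, report.n_loaded, report.n_rejected, report.n_missing_event,
    )
    return records, report


def validate_cohort(records: Iterable[ObservationRecord]) -> ValidationReport:
    """Count suspicious record shapes without mutating or dropping anything.

    Flags events dated before follow-up start or after follow-up end
    (both are processed verbatim by the counting rules) and zero-length
    follow-up intervals.
    """
    report = ValidationReport()
    for record in records:
        report.n_records += 1
        if record.event_date is not None:
            if record.event_date < record.start_date:
                report.event_before_start += 1
            if record.event_date > record.end_date:
                report.event_after_end += 1
        if record.start_date == record.end_date:
            report.zero_length_followup += 1
    return report


RESULT_COLUMNS = [
    "metric",
    "period_start",
    "period_end",
    "period_label",
    "stratifier",
    "stratum",
    "numerator",
    "denominator_count",
    "person_years",
    "estimate",
    "ci_lower",
    "ci_upper",
    "multiplier",
    "ci_level",
]


def results_frame(estimates: Iterable[Estimate]) -> pd.DataFrame:
    """Assemble estimates into the long-format result table."""
    rows = []
    for est in estimates:
        row = {
            "metric": est.metric,
            "period_start": est.period_start.isoformat(),
            "period_end": est.period_end.isoformat(),
            "period_label": est.period_label,
            "stratifier": est.stratifier,
            "stratum": est.stratum,
            "numerator": est.numerator,
            "denominator_count": math.nan,
            "person_years": math.nan,
            "estimate": est.estimate,
            "ci_lower": est.ci_lower,
            "ci_upper": est.ci_upper,
            "multiplier": est.multiplier,
            "ci_level": est.ci_level,
        }
        if isinstance(est, PrevalenceEstimate):
            row["denominator_count"] = est.denominator
        else:
            row["person_years"] = est.person_years
        rows.append(row)
    frame = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if len(frame):
        frame = frame.sort_values(
            ["metric", "stratifier", "stratum", "period_start"], kind="mergesort"
        ).reset_index(drop=True)
    return frame


def write_results(estimates: Iterable[Estimate], path: Union[str, Path]) -> None:
    """Write estimates as a long-format CSV (one row per period/stratum).

    ``person_years`` is left empty on prevalence rows and
    ``denominator_count`` on incidence rows. Rows are sorted by
    (metric, stratifier, stratum, period_start). Undefined estimates
    appear as empty cells.
    """
    frame = results_frame(estimates)
    frame.to_csv(path, index=False, lineterminator="\n")


def write_cohort(records: Iterable[ObservationRecord], path: Union[str, Path]) -> None:
    """Write records in the exact CSV dialect :func:`read_cohort` reads."""
    records = list(records)
    stratifiers: list[str] = []
    for record in records:
        for name in record.strata:
            if name not in stratifiers:
                stratifiers.append(name)
    columns = ["record_id", "start_date", "end_date", "event_date", *stratifiers]
    with Path(path).open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(columns)
        for record in records:
            writer.writerow(
                [
                    record.record_id,
                    record.start_date.isoformat(),
                    record.end_date.isoformat(),
                    record.event_date.isoformat() if record.event_date else "NA",
                    *[record.strata.get(name, "missing") for name in stratifiers],
                ]
            )


def available_stratifiers(records: Sequence[ObservationRecord]) -> list[str]:
    """Union of stratifier names present on any record, in first-seen order."""
    names: list[str] = []
    for record in records:
        for name in record.strata:
            if name not in names:
                names.append(name)
    return names
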