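import datetime as dt

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from opencohort import (
    AnalysisPeriod,
    IncidenceEstimate,
    ObservationRecord,
    PrevalenceEstimate,
    SchemaError,
    read_cohort,
    validate_cohort,
    write_cohort,
    write_results,
)
from opencohort.cohort import results_frame

from _strategies import observation_records


def _write(tmp_path, text, name="cohort.csv"):
    path = tmp_path / name
    path.write_text(text, encoding="utf-8")
    return path


class TestObservationRecord:
    def test_rejects_reversed_interval(self):
        with pytest.raises(ValueError, match="start_date"):
            ObservationRecord(dt.date(2006, 1, 1), dt.date(2005, 1, 1))

    def test_zero_length_interval_allowed(self):
        r = ObservationRecord(dt.date(2006, 1, 1), dt.date(2006, 1, 1))
        assert r.start_date == r.end_date

    def test_event_outside_interval_allowed(self):
        r = ObservationRecord(dt.date(2006, 1, 1), dt.date(2007, 1, 1),
                              dt.date(2001, 1, 1))
        assert r.event_date == dt.date(2001, 1, 1)


class TestAnalysisPeriod:
    def test_rejects_empty_period(self):
        with pytest.raises(ValueError):
            AnalysisPeriod(dt.date(2006, 1, 1), dt.date(2006, 1, 1))

    def test_length_days(self):
        p = AnalysisPeriod(dt.date(2006, 1, 1), dt.date(2007, 1, 1))
        assert p.length_days == 365


class TestReadCohort:
    def test_basic_parse_with_missing_event(self, tmp_path):
        path = _write(tmp_path, (
            "record_id,start_date,end_date,event_date\n"
            "a,2005-01-01,2010-01-01,2006-05-01\n"
            "b,2005-01-01,2010-01-01,\n"
            "c,2005-01-01,2010-01-01,NA\n"
        ))
        records, report = read_cohort(path)
        assert len(records) == 3
        assert report.n_rows == 3 and report.n_loaded == 3
        assert report.n_missing_event == 2
        assert records[0].event_date == dt.date(2006, 5, 1)
        assert records[1].event_date is None and records[2].event_date is None

    def test_reversed_interval_rejected_and_reported(self, tmp_path):
        path = _write(tmp_path, (
            "record_id,start_date,end_date,event_date\n"
            "a,2006-01-01,2005-01-01,\n"
            "b,2005-01-01,2010-01-01,\n"
        ))
        records, report = read_cohort(path)
        assert len(records) == 1
        assert report.n_rejected == 1
        assert any("row 2" in m for m in report.messages)

    def test_header_only_file(self, tmp_path):
        path = _write(tmp_path, "record_id,start_date,end_date,event_date\n")
        records, report = read_cohort(path)
        assert records == []
        assert report.n_rows == 0
        assert report.messages  # warning logged

    def test_missing_mandatory_column_names_it(self, tmp_path):
        path = _write(tmp_path, "record_id,start_date,event_date\na,2005-01-01,\n")
        with pytest.raises(SchemaError, match="end_date"):
            read_cohort(path)

    def test_unparseable_date_reported_with_row_number(self, tmp_path):
        path = _write(tmp_path, (
            "record_id,start_date,end_date,event_date\n"
            "a,2005-01-01,2010-01-01,\n"
            "b,not-a-date,2010-01-01,\n"
        ))
        records, report = read_cohort(path)
        assert len(records) == 1
        assert any("row 3" in m for m in report.messages)

    def test_column_map_renames_and_selects_stratifiers(self, tmp_path):
        path = _write(tmp_path, (
            "id,entry,exit,diagnosis,ethnicity,ignored\n"
            "a,2005-01-01,2010-01-01,2006-05-01,white,zzz\n"
        ))
        records, _ = read_cohort(path, column_map={
            "record_id": "id", "start_date": "entry", "end_date": "exit",
            "event_date": "diagnosis", "ethnicity": "ethnicity",
        })
        assert records[0].strata == {"ethnicity": "white"}
        assert "ignored" not in records[0].strata

    def test_custom_date_format(self, tmp_path):
        path = _write(tmp_path, (
            "record_id,start_date,end_date,event_date\n"
            "a,01/02/2005,01/02/2010,NA\n"
        ))
        records, _ = read_cohort(path, date_format="%d/%m/%Y")
        assert records[0].start_date == dt.date(2005, 2, 1)

    def test_empty_stratifier_cell_becomes_missing(self, tmp_path):
        path = _write(tmp_path, (
            "record_id,start_date,end_date,event_date,ethnicity\n"
            "a,2005-01-01,2010-01-01,NA,\n"
        ))
        records, _ = read_cohort(path, column_map={"ethnicity": "ethnicity"})
        assert records[0].strata["ethnicity"] == "missing"

    def test_strict_mode_drops_event_outside_followup(self, tmp_path):
        path = _write(tmp_path, (
            "record_id,start_date,end_date,event_date\n"
            "a,2005-01-01,2010-01-01,2004-01-01\n"
            "b,2005-01-01,2010-01-01,2006-01-01\n"
        ))
        records, report = read_cohort(path, strict=True)
        assert [r.record_id for r in records] == ["b"]
        assert report.n_rejected == 1
        records, report = read_cohort(path, strict=False)
        assert len(records) == 2 and report.n_rejected == 0


class TestValidateCohort:
    def test_event_before_start(self):
        r = ObservationRecord(dt.date(2005, 1, 1), dt.date(2010, 1, 1),
                              dt.date(2004, 1, 1))
        report = validate_cohort([r])
        assert report.event_before_start == 1
        assert report.event_after_end == 0

    def test_event_after_end(self):
        r = ObservationRecord(dt.date(2005, 1, 1), dt.date(2010, 1, 1),
                              dt.date(2011, 1, 1))
        assert validate_cohort([r]).event_after_end == 1

    def test_zero_length_followup(self):
        r = ObservationRecord(dt.date(2005, 1, 1), dt.date(2005, 1, 1))
        assert validate_cohort([r]).zero_length_followup == 1

    def test_clean_cohort_no_warnings(self, small_cohort):
        clean = [r for r in small_cohort if r.record_id != "d"]
        assert validate_cohort(clean).n_warnings == 0

    def test_does_not_mutate(self, small_cohort):
        before = list(small_cohort)
        validate_cohort(small_cohort)
        assert small_cohort == before


class TestWriteResults:
    @staticmethod
    def _prev(label="2006"):
        return PrevalenceEstimate(
            metric="point_prevalence", period_label=label,
            period_start=dt.date(int(label), 1, 1),
            period_end=dt.date(int(label) + 1, 1, 1),
            numerator=2, denominator=3, estimate=66666.67,
            ci_lower=7487.5, ci_upper=240695.6,
        )

    @staticmethod
    def _inc():
        return IncidenceEstimate(
            metric="incidence", period_label="2006",
            period_start=dt.date(2006, 1, 1), period_end=dt.date(2007, 1, 1),
            numerator=1, person_years=2.4942, estimate=40093.3,
            ci_lower=1015.1, ci_upper=223380.2,
        )

    def test_two_rows_plus_header(self, tmp_path):
        path = tmp_path / "out.csv"
        write_results([self._prev("2006"), self._prev("2007")], path)
        assert len(path.read_text().strip().splitlines()) == 3

    def test_empty_collection_header_only(self, tmp_path):
        path = tmp_path / "out.csv"
        write_results([], path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1
        assert lines[0].startswith("metric,period_start,period_end")

    def test_mixed_metrics_column_blanking(self, tmp_path):
        path = tmp_path / "out.csv"
        write_results([self._inc(), self._prev()], path)
        frame = pd.read_csv(path)
        inc = frame[frame.metric == "incidence"].iloc[0]
        prev = frame[frame.metric == "point_prevalence"].iloc[0]
        assert pd.isna(inc.denominator_count) and inc.person_years == 2.4942
        assert pd.isna(prev.person_years) and prev.denominator_count == 3

    def test_roundtrip_numeric_fields(self, tmp_path):
        path = tmp_path / "out.csv"
        estimates = [self._inc(), self._prev("2006"), self._prev("2007")]
        write_results(estimates, path)
        frame = pd.read_csv(path)
        expected = results_frame(estimates)
        for col in ("numerator", "estimate", "ci_lower", "ci_upper",
                    "multiplier", "ci_level"):
            assert list(frame[col]) == list(expected[col])

    def test_sorted_by_metric_stratifier_stratum_period(self, tmp_path):
        path = tmp_path / "out.csv"
        write_results([self._prev("2007"), self._inc(), self._prev("2006")], path)
        frame = pd.read_csv(path)
        keys = list(zip(frame.metric, frame.stratifier, frame.stratum,
                        frame.period_start))
        assert keys == sorted(keys)


class TestCohortRoundTrip:
    @given(records=st.lists(observation_records(), max_size=30))
    @settings(max_examples=25, deadline=None)
    def test_write_then_read_identity(self, tmp_path_factory, records):
        path = tmp_path_factory.mktemp("rt") / "cohort.csv"
        write_cohort(records, path)
        back, report = read_cohort(path)
        assert report.n_rejected == 0
        assert [(r.start_date, r.end_date, r.event_date) for r in back] == [
            (r.start_date, r.end_date, r.event_date) for r in records
        ]

    def test_strata_roundtrip(self, tmp_path):
        records = [
            ObservationRecord(dt.date(2005, 1, 1), dt.date(2010, 1, 1), None,
                              {"ethnicity": "white", "region": "north"}, "a"),
            ObservationRecord(dt.date(2006, 1, 1), dt.date(2011, 1, 1),
                              dt.date(2007, 1, 1),
                              {"ethnicity": "black", "region": "south"}, "b"),
        ]
        path = tmp_path / "cohort.csv"
        write_cohort(records, path)
        back, _ = read_cohort(
            path, column_map={"ethnicity": "ethnicity", "region": "region"}
        )
        assert [dict(r.strata) for r in back] == [dict(r.strata) for r in records]
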