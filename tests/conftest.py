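import datetime as dt
import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from opencohort import AnalysisPeriod, ObservationRecord


@pytest.fixture
def year_2006() -> AnalysisPeriod:
    return AnalysisPeriod(dt.date(2006, 1, 1), dt.date(2007, 1, 1), "2006")


@pytest.fixture
def small_cohort() -> list[ObservationRecord]:
    """Four hand-checked records: two prevalent at 2006-01-01, three under
    follow-up then; one event precedes its own follow-up start."""
    return [
        ObservationRecord(dt.date(2005, 6, 1), dt.date(2010, 6, 1),
                          dt.date(2005, 12, 1), record_id="a"),
        ObservationRecord(dt.date(2005, 1, 1), dt.date(2006, 1, 1),
                          dt.date(2006, 1, 1), record_id="b"),
        ObservationRecord(dt.date(2005, 1, 1), dt.date(2010, 1, 1),
                          None, record_id="c"),
        ObservationRecord(dt.date(2006, 6, 1), dt.date(2010, 1, 1),
                          dt.date(2005, 12, 1), record_id="d"),
    ]
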