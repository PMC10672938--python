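import pandas as pd
import pytest

from srsignal import make_paper_fixture, restrict_to_suspect
from srsignal.report_store import ReportDatabase


def db_from_rows(cases, drugs, events):
    """Build a small in-memory database from plain row tuples.

    cases: (case_id, sex); drugs: (case_id, generic_name, involvement, start);
    events: (case_id, pt_name, onset).  Dates may be None.
    """
    case_df = pd.DataFrame(cases, columns=["case_id", "sex"])
    case_df["report_quarter"] = ""
    drug_df = pd.DataFrame(drugs, columns=["case_id", "generic_name",
                                           "involvement", "admin_start_date"])
    drug_df["admin_start_date"] = pd.to_datetime(drug_df["admin_start_date"])
    event_df = pd.DataFrame(events, columns=["case_id", "pt_name", "onset_date"])
    event_df["onset_date"] = pd.to_datetime(event_df["onset_date"])
    event_df["outcome"] = ""
    return ReportDatabase(cases=case_df, drugs=drug_df, events=event_df).validate()


@pytest.fixture(scope="session")
def paper_fixture():
    """The deterministic miniature study database (db, term_map, config)."""
    return make_paper_fixture()


@pytest.fixture(scope="session")
def suspect_db(paper_fixture):
    db, term_map, config = paper_fixture
    return restrict_to_suspect(db), term_map, config
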