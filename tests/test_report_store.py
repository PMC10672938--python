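"""Loading, validation, suspect-drug restriction and HLT roll-up."""

import pandas as pd
import pytest

from srsignal.report_store import (
    Dialect,
    ReferentialIntegrityError,
    SchemaError,
    TermMap,
    flag_event_group,
    load_database,
    normalize_drug_name,
    restrict_to_suspect,
)

from conftest import db_from_rows


def write_toy_tables(tmp_path, demo=None, drug=None, reac=None):
    demo = demo if demo is not None else pd.DataFrame({
        "case_id": [f"c{i}" for i in range(1, 6)],
        "sex": ["female", "male", "F", "", "hermit"],
    })
    drug = drug if drug is not None else pd.DataFrame({
        "case_id": ["c1", "c1", "c2", "c3", "c4"],
        "generic_name": ["  Nivolumab ", "cisplatin", "nivolumab",
                         "nivolumab", "cisplatin"],
        "involvement": ["suspect", "concomitant", "Suspect Drug",
                        "suspect", "interaction"],
        "admin_start_date": ["2018-03-01", "", "2018-04-01", "2018-05", ""],
    })
    reac = reac if reac is not None else pd.DataFrame({
        "case_id": ["c1", "c2", "c2", "c5"],
        "pt_name": ["hypopituitarism", "nausea", "hypophysitis", "rash"],
        "onset_date": ["2018-06-01", "", "2018-07-01", ""],
    })
    paths = {}
    for name, df in (("demo", demo), ("drug", drug), ("reac", reac)):
        paths[name] = tmp_path / f"{name}.csv"
        df.to_csv(paths[name], index=False)
    return paths


class TestLoadDatabase:
    def test_row_counts_and_normalization(self, tmp_path):
        db = load_database(write_toy_tables(tmp_path))
        assert db.n_reports == 5
        assert list(db.cases["sex"]) == ["women", "men", "women", "unknown", "unknown"]
        # names trimmed and case-folded; involvement vocabulary normalized
        assert set(db.drugs["generic_name"]) == {"nivolumab", "cisplatin"}
        assert list(db.drugs["involvement"]) == [
            "suspect", "concomitant", "suspect", "suspect", "interaction"]

    def test_unrecognized_sex_becomes_unknown_with_warning(self, tmp_path, caplog):
        with caplog.at_level("WARNING"):
            db = load_database(write_toy_tables(tmp_path))
        assert db.cases.loc[db.cases["case_id"] == "c5", "sex"].item() == "unknown"
        assert any("unrecognized sex" in r.message for r in caplog.records)

    def test_partial_dates_are_missing(self, tmp_path):
        db = load_database(write_toy_tables(tmp_path))
        starts = db.drugs.set_index(db.drugs.index)["admin_start_date"]
        assert starts.notna().sum() == 2  # the year-month value c3 coerces to NaT

    def test_blank_case_ids_dropped(self, tmp_path):
        demo = pd.DataFrame({"case_id": ["c1", "", "c2"], "sex": ["m", "f", "f"]})
        drug = pd.DataFrame({"case_id": ["c1"], "generic_name": ["x"],
                             "involvement": ["suspect"]})
        reac = pd.DataFrame({"case_id": ["c2"], "pt_name": ["rash"]})
        db = load_database(write_toy_tables(tmp_path, demo, drug, reac))
        assert db.n_reports == 2

    def test_missing_table_is_fatal(self, tmp_path):
        paths = write_toy_tables(tmp_path)
        del paths["reac"]
        with pytest.raises(FileNotFoundError):
            load_database(paths)

    def test_missing_column_is_fatal_and_named(self, tmp_path):
        demo = pd.DataFrame({"case_id": ["c1"]})  # no sex column
        with pytest.raises(SchemaError, match="sex"):
            load_database(write_toy_tables(tmp_path, demo=demo))

    def test_orphan_mentions_violate_referential_integrity(self, tmp_path):
        drug = pd.DataFrame({"case_id": ["ghost"], "generic_name": ["x"],
                             "involvement": ["suspect"]})
        with pytest.raises(ReferentialIntegrityError, match="ghost"):
            load_database(write_toy_tables(tmp_path, drug=drug))

    def test_synonyms_collapse_to_generic_name(self, tmp_path):
        drug = pd.DataFrame({"case_id": ["c1"], "generic_name": ["Opdivo"],
                             "involvement": ["suspect"]})
        db = load_database(write_toy_tables(tmp_path, drug=drug),
                           drug_synonyms={"opdivo": "nivolumab"})
        assert set(db.drugs["generic_name"]) == {"nivolumab"}
        assert normalize_drug_name(" Opdivo ", db.drug_synonyms) == "nivolumab"

    def test_dialect_column_map(self, tmp_path):
        demo = pd.DataFrame({"id": ["c1"], "seibetsu": ["female"]})
        drug = pd.DataFrame({"id": ["c1"], "generic_name": ["x"],
                             "involvement": ["suspect"]})
        reac = pd.DataFrame({"id": ["c1"], "pt_name": ["rash"]})
        paths = write_toy_tables(tmp_path, demo, drug, reac)
        db = load_database(paths, Dialect(column_map={"id": "case_id",
                                                      "seibetsu": "sex"}))
        assert db.n_reports == 1 and db.cases["sex"].item() == "women"


class TestRestrictToSuspect:
    def test_filters_involvement_only(self, tmp_path):
        db = load_database(write_toy_tables(tmp_path))
        restricted = restrict_to_suspect(db)
        assert len(restricted.drugs) == 3
        assert set(restricted.drugs["involvement"]) == {"suspect"}
        # cases and events untouched: N++ is invariant
        assert restricted.n_reports == db.n_reports
        assert len(restricted.events) == len(db.events)

    def test_idempotent(self, tmp_path):
        db = restrict_to_suspect(load_database(write_toy_tables(tmp_path)))
        again = restrict_to_suspect(db)
        pd.testing.assert_frame_equal(again.drugs, db.drugs)

    def test_no_suspect_mentions_leaves_empty_drug_table(self):
        db = db_from_rows(
            cases=[("c1", "women")],
            drugs=[("c1", "x", "concomitant", None)],
            events=[("c1", "rash", None)],
        )
        restricted = restrict_to_suspect(db)
        assert len(restricted.drugs) == 0 and restricted.n_reports == 1


class TestFlagEventGroup:
    TM = TermMap({"hypopituitarism": "aph", "hypophysitis": "aph",
                  "diabetes insipidus": "ppd", "rash": "skin"})

    def test_case_with_two_matching_pts_flagged_once(self):
        db = db_from_rows(
            cases=[("c1", "women"), ("c2", "men")],
            drugs=[("c1", "x", "suspect", None)],
            events=[("c1", "hypopituitarism", None), ("c1", "hypophysitis", None),
                    ("c2", "rash", None)],
        )
        flag = flag_event_group(db, self.TM, "aph")
        assert flag.sum() == 1 and bool(flag["c1"]) and not bool(flag["c2"])

    def test_flag_depends_on_pt_set_not_multiset(self):
        events = [("c1", "hypopituitarism", None), ("c2", "rash", None)]
        db1 = db_from_rows([("c1", "women"), ("c2", "men")],
                           [("c1", "x", "suspect", None)], events)
        db2 = db_from_rows([("c1", "women"), ("c2", "men")],
                           [("c1", "x", "suspect", None)],
                           events + [("c1", "hypopituitarism", None)] * 3)
        flag1 = flag_event_group(db1, self.TM, "aph")
        flag2 = flag_event_group(db2, self.TM, "aph")
        assert flag1.equals(flag2)

    def test_hand_counted_fixture_sums_to_three(self):
        # 10 cases, exactly 3 of them with a PT rolling up to 'aph'
        cases = [(f"c{i}", "women") for i in range(10)]
        events = [("c0", "hypopituitarism", None), ("c1", "hypophysitis", None),
                  ("c2", "hypopituitarism", None), ("c3", "rash", None),
                  ("c4", "diabetes insipidus", None), ("c5", "rash", None)]
        db = db_from_rows(cases, [("c0", "x", "suspect", None)], events)
        assert flag_event_group(db, self.TM, "aph").sum() == 3

    def test_unknown_hlt_is_a_configuration_error(self):
        db = db_from_rows([("c1", "women")], [("c1", "x", "suspect", None)],
                          [("c1", "rash", None)])
        with pytest.raises(KeyError, match="no such hlt"):
            flag_event_group(db, self.TM, "no such hlt")


def test_term_map_rejects_ambiguous_pt(tmp_path):
    path = tmp_path / "tm.csv"
    pd.DataFrame({"pt_name": ["rash", "rash"], "hlt_name": ["a", "b"]}).to_csv(
        path, index=False)
    with pytest.raises(SchemaError, match="rash"):
        TermMap.from_csv(path)
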