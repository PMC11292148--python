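"""Data dictionary validation, cleaning ledger, share aggregation."""

import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fedhybrid.datacenter import (
    DataDictionary,
    DictionaryError,
    FieldSpec,
    aggregate_share,
    clean_records,
    validate_dictionary,
)

DICT_DOC = {
    "fields": [
        {"name": "patient_id", "type": "integer", "required": True},
        {"name": "age", "type": "integer", "required": True, "range": [0, 120]},
        {"name": "sex", "type": "categorical", "required": False, "range": ["M", "F"]},
        {"name": "sbp", "type": "real", "required": False, "range": [60, 260]},
        {"name": "visit", "type": "date-string", "required": False,
         "range": ["2000-01-01", "2030-12-31"]},
    ],
    "key_fields": ["patient_id"],
    "version": "1",
}


@pytest.fixture()
def dictionary():
    return validate_dictionary(DICT_DOC)


def defect_fixture():
    """10 rows: 1 missing required, 1 out of range, 2 duplicate keys -> 6 clean."""
    rows = [
        {"patient_id": 1, "age": 50, "sex": "M", "sbp": 120, "visit": "2020-01-01"},
        {"patient_id": 2, "age": 61, "sex": "F", "sbp": 135, "visit": "2020-02-01"},
        {"patient_id": 3, "age": None, "sex": "M", "sbp": 110, "visit": "2020-03-01"},  # missing
        {"patient_id": 4, "age": 45, "sex": "F", "sbp": 500, "visit": "2020-04-01"},    # range
        {"patient_id": 5, "age": 70, "sex": "M", "sbp": 140, "visit": "2020-05-01"},
        {"patient_id": 1, "age": 50, "sex": "M", "sbp": 120, "visit": "2020-01-01"},    # dup
        {"patient_id": 6, "age": 33, "sex": "F", "sbp": 115, "visit": "2020-06-01"},
        {"patient_id": 2, "age": 62, "sex": "F", "sbp": 130, "visit": "2020-07-01"},    # dup
        {"patient_id": 7, "age": 58, "sex": "M", "sbp": 150, "visit": "2020-08-01"},
        {"patient_id": 8, "age": 41, "sex": "F", "sbp": 125, "visit": "2020-09-01"},
    ]
    return pd.DataFrame(rows)


class TestDictionary:
    def test_minimal_valid(self):
        d = validate_dictionary({
            "fields": [{"name": "id", "type": "integer", "required": True}],
            "key_fields": ["id"],
        })
        assert d.key_fields == ["id"]

    def test_duplicate_field_named_in_error(self):
        doc = {"fields": [{"name": "a", "type": "real"}, {"name": "a", "type": "real"},
                          {"name": "id", "type": "integer", "required": True}],
               "key_fields": ["id"]}
        with pytest.raises(DictionaryError, match="'a'"):
            validate_dictionary(doc)

    @pytest.mark.parametrize("doc,fragment", [
        ({"fields": [{"name": "x", "type": "complex"}], "key_fields": ["x"]}, "unknown type"),
        ({"fields": [{"name": "x", "type": "real", "required": True}], "key_fields": []},
         "non-empty"),
        ({"fields": [{"name": "x", "type": "real"}], "key_fields": ["x"]}, "required"),
        ({"fields": [{"name": "x", "type": "real", "required": True}], "key_fields": ["y"]},
         "not declared"),
    ])
    def test_schema_errors(self, doc, fragment):
        with pytest.raises(DictionaryError, match=fragment):
            validate_dictionary(doc)

    def test_json_round_trip_idempotent(self, dictionary):
        again = DataDictionary.from_json(dictionary.to_json())
        assert again == dictionary


class TestCleaning:
    def test_defect_fixture_ledger(self, dictionary):
        clean, report = clean_records(defect_fixture(), dictionary)
        assert len(clean) == 6
        assert (report.dropped_missing, report.dropped_range, report.dropped_duplicate) \
            == (1, 1, 2)
        assert report.reconciles()
        reasons = dict(report.rejected)
        assert reasons == {2: "missing", 3: "range", 5: "duplicate", 7: "duplicate"}

    def test_empty_share(self, dictionary):
        clean, report = clean_records(pd.DataFrame(columns=["patient_id", "age"]), dictionary)
        assert len(clean) == 0 and report.records_in == 0 and report.reconciles()

    def test_clean_share_untouched(self, dictionary):
        share = defect_fixture().iloc[[0, 1, 4, 6, 8, 9]].reset_index(drop=True)
        clean, report = clean_records(share, dictionary)
        assert len(clean) == len(share)
        assert report.rejected == []

    def test_idempotent(self, dictionary):
        clean, _ = clean_records(defect_fixture(), dictionary)
        again, report = clean_records(clean, dictionary)
        assert report.records_out == report.records_in
        assert report.rejected == []

    def test_missing_required_column_rejects_share(self, dictionary):
        with pytest.raises(DictionaryError, match="age"):
            clean_records(pd.DataFrame({"patient_id": [1]}), dictionary)

    def test_uncoercible_counts_as_range(self, dictionary):
        share = pd.DataFrame([{"patient_id": 1, "age": "old"},
                              {"patient_id": 2, "age": "2020-13-45"}])
        share["visit"] = ["2020-01-01", "not-a-date"]
        _, report = clean_records(share, dictionary)
        assert report.dropped_range == 2

    def test_enhance_hook_applied(self, dictionary):
        share = pd.DataFrame([{"patient_id": 1, "age": 30}])
        clean, _ = clean_records(share, dictionary,
                                 enhance=lambda df: df.assign(decade=df.age.astype(int) // 10))
        assert list(clean["decade"]) == [3]

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(
        st.tuples(st.integers(0, 30), st.integers(-20, 140), st.booleans()),
        max_size=40,
    ))
    def test_ledger_balances_for_random_shares(self, rows):
        dictionary = validate_dictionary(DICT_DOC)
        share = pd.DataFrame(
            [{"patient_id": pid, "age": (None if drop_age else age)}
             for pid, age, drop_age in rows],
            columns=["patient_id", "age"],
        )
        clean, report = clean_records(share, dictionary)
        assert report.reconciles()
        assert report.records_out == len(clean)
        # surviving keys unique
        assert clean["patient_id"].astype(str).is_unique


class TestAggregation:
    def _share(self, ids):
        return pd.DataFrame([{"patient_id": i, "age": 40 + (i % 30)} for i in ids])

    def test_three_shares_accumulate(self, dictionary, tmp_path):
        core = tmp_path / "core.csv"
        sizes = [range(6), range(10, 14), range(20, 25)]  # 6 + 4 + 5 unique keys
        for ids in sizes:
            share, _ = clean_records(self._share(ids), dictionary)
            aggregate_share(core, share, dictionary, uploads_dir=tmp_path / "uploads")
        assert len(pd.read_csv(core)) == 15
        log = (tmp_path / "core.csv.provenance.jsonl").read_text().strip().splitlines()
        assert len(log) == 3
        assert len(list((tmp_path / "uploads").glob("upload_*.csv"))) == 3

    def test_resubmission_is_noop(self, dictionary, tmp_path):
        core = tmp_path / "core.csv"
        share, _ = clean_records(self._share(range(5)), dictionary)
        aggregate_share(core, share, dictionary, upload_label="a")
        before = core.read_bytes()
        entry = aggregate_share(core, share, dictionary, upload_label="b")
        assert core.read_bytes() == before
        assert entry["rows_appended"] == 0
        assert entry["rows_dropped_cross_share_duplicate"] == 5

    def test_bootstrap_stamps_version(self, dictionary, tmp_path):
        core = tmp_path / "fresh.csv"
        share, _ = clean_records(self._share([1]), dictionary)
        aggregate_share(core, share, dictionary, upload_label="x")
        meta = json.loads((tmp_path / "fresh.csv.meta.json").read_text())
        assert meta["version"] == dictionary.version

    def test_version_mismatch_rejected(self, dictionary, tmp_path):
        core = tmp_path / "core.csv"
        share, _ = clean_records(self._share([1]), dictionary)
        aggregate_share(core, share, dictionary, upload_label="x")
        other = DataDictionary(fields=dictionary.fields,
                               key_fields=dictionary.key_fields, version="2")
        with pytest.raises(DictionaryError, match="version"):
            aggregate_share(core, share, other, upload_label="y")

    def test_key_uniqueness_after_any_sequence(self, dictionary, tmp_path):
        rng = np.random.default_rng(7)
        core = tmp_path / "core.csv"
        for k in range(5):
            ids = rng.integers(0, 20, size=rng.integers(1, 10))
            share, _ = clean_records(self._share(ids), dictionary)
            aggregate_share(core, share, dictionary, upload_label=str(k))
        df = pd.read_csv(core, dtype=str)
        assert df["patient_id"].is_unique
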