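"""Chapter exclusion, three-level generalization, and transaction building."""

import pandas as pd
import pytest

from comorbnet.preprocessing import (DEFAULT_BLOCK_TABLE,
                                     MappingConfigurationError, TransactionDB,
                                     build_generalization_map,
                                     build_transactions, exclude_chapters,
                                     filter_patients, summarize_cohort)
from comorbnet.records import (DiagnosisRecord, RecordFormatError,
                               RecordValidationError, load_records,
                               write_records)


def rec(pid, code, visit="V1", sex="male", age=3, region="urban"):
    return DiagnosisRecord(pid, f"{pid}-{visit}", code, sex, age, region)


# ---------------------------------------------------------------- records IO

def test_load_records_roundtrip(tmp_path):
    records = [rec("P1", "F84.0"), rec("P1", "F70.900"), rec("P2", "G40.900")]
    path = tmp_path / "d.csv"
    write_records(records, path)
    assert load_records(path) == records


def test_missing_column_is_a_format_error(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("patient_id,icd10_code\nP1,F84.0\n")
    with pytest.raises(RecordFormatError):
        load_records(path)


def test_invalid_code_names_the_row(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("patient_id,visit_id,icd10_code,sex,age_years,region\n"
                    "P1,V1,F84.0,male,3,urban\n"
                    "P2,V1,12345,male,4,urban\n")
    with pytest.raises(RecordValidationError) as exc:
        load_records(path)
    assert exc.value.problems[0][0] == 3  # header is row 1


# ---------------------------------------------------------------- exclusion

@pytest.mark.parametrize("code,kept", [
    ("Z00.000", False), ("V01.x00", False), ("Y98.000", False), ("Z99.900", False),
    ("F84.0", True), ("U07.100", True), ("R94.001", True),
])
def test_supplementary_chapters_are_excluded(code, kept):
    out = exclude_chapters([rec("P1", code)])
    assert bool(out) is kept


def test_exclusion_preserves_order_of_survivors():
    records = [rec("P1", "F84.0"), rec("P1", "Z00.000"), rec("P1", "G40.900")]
    assert [r.icd10_code for r in exclude_chapters(records)] == ["F84.0", "G40.900"]


# ----------------------------------------------------------- generalization

def gmap_for(*codes, **kw):
    return build_generalization_map(set(codes), **kw)


@pytest.mark.parametrize("code,expected_level,expected_item", [
    ("F70.900", 2, "F70-F79"),   # block-level grouping
    ("F84.1", 1, "F84"),         # autism codes collapse to F84
    ("F84.0", 1, "F84"),
    ("F41.001", 0, "F41.001"),   # flagged NOS subcategory stays verbatim
    ("R94.001", 0, "R94.001"),   # abnormal-findings range stays verbatim
    ("F84.2", 0, "F84.2"),       # other pervasive disorders not merged
    ("F84.900", 0, "F84.900"),
    ("G47.900", 1, "G47"),       # plain three-character collapse
    ("R56", 0, "R56"),           # already a category
    ("J02.900", 2, "J00-J06"),
])
def test_generalization_level_assignment(code, expected_level, expected_item):
    gmap = gmap_for(code)
    assert gmap.level(code) == expected_level
    assert gmap.item(code) == expected_item


def test_generalization_is_idempotent_on_item_labels():
    gmap = gmap_for("F70.900", "G47.900", "F41.001")
    for code in ("F70.900", "G47.900", "F41.001"):
        label = gmap.item(code)
        assert gmap.item(label) == label


def test_levels_partition_is_total_and_disjoint():
    codes = {"F70.900", "F84.0", "F84.2", "F41.001", "R94.001", "G47.900",
             "J02.900", "E58.x00", "L20.800", "R56"}
    gmap = build_generalization_map(codes)
    for code in codes:
        level, label = gmap.entries[code]
        assert level in (0, 1, 2)
        if level == 0:
            assert label == code
        elif level == 1:
            assert len(label) == 3
        else:
            assert "-" in label and len(label) == 7


def test_overlapping_block_rows_are_rejected():
    blocks = (("F70-F79", "F70", "F79"), ("F75-F80", "F75", "F80"))
    with pytest.raises(MappingConfigurationError):
        gmap_for("F78.100", block_table=blocks)


def test_explicit_overrides_win():
    gmap = gmap_for("F70.900", overrides={"F70.900": (0, "F70.900")})
    assert gmap.item("F70.900") == "F70.900"


# ------------------------------------------------------------- transactions

def test_autism_variants_collapse_to_one_item():
    records = [rec("P1", "F84.0", visit="V1"), rec("P1", "F84.1", visit="V2")]
    gmap = gmap_for("F84.0", "F84.1")
    db = build_transactions(records, gmap)
    assert db.transactions["P1"] == frozenset({"F84"})


def test_generalize_then_set_collapse():
    records = [rec("P1", "F84.0"), rec("P1", "F70.900"), rec("P1", "F71.900")]
    gmap = gmap_for("F84.0", "F70.900", "F71.900")
    db = build_transactions(records, gmap)
    assert db.transactions["P1"] == frozenset({"F84", "F70-F79"})


def test_empty_records_give_empty_db():
    db = build_transactions([], gmap_for("F84.0"))
    assert db.n_patients == 0 and db.item_frequencies == {}


def test_filter_patients_thresholds_and_frequencies(worked_db):
    singleton = TransactionDB({**dict(worked_db.transactions),
                               "P4": frozenset({"F84"})})
    kept = filter_patients(singleton, min_items=2)
    assert set(kept.transactions) == {"P1", "P2", "P3"}
    before, after = singleton.item_frequencies, kept.item_frequencies
    assert all(after.get(i, 0) <= before[i] for i in before)


def test_anchor_frequency_equals_patient_count(small_cohort_db):
    assert small_cohort_db.item_frequencies["F84"] == small_cohort_db.n_patients


# ------------------------------------------------------------------ summary

def test_cohort_summary_counts_and_first_visit_rule():
    records = [
        rec("P1", "F84.0", visit="V1", age=3), rec("P1", "F80.000", visit="V2", age=7),
        rec("P2", "F84.0", sex="male", age=6), rec("P2", "G40.900", age=6),
        rec("P3", "F84.1", sex="male", age=11), rec("P3", "R56.000", age=11),
        rec("P4", "F84.0", sex="female", age=2, region="rural"),
        rec("P4", "F70.900", age=2, region="rural"),
    ]
    gmap = build_generalization_map({r.icd10_code for r in records})
    db = filter_patients(build_transactions(records, gmap))
    summary = summarize_cohort(records, db)
    male = summary.query("characteristic=='sex' and value=='male'").iloc[0]
    assert male["count"] == 3 and male["percent"] == 75.00
    early = summary.query("characteristic=='age_band' and value=='early childhood'").iloc[0]
    assert early["count"] == 2  # P1 counted at first visit (age 3), plus P4
    bins = summary.query("characteristic=='visit_bin'")
    assert bins["count"].sum() == 4


def test_visit_bin_assignment():
    records = [rec("P1", "F84.0", visit=f"V{i:02d}") for i in range(12)]
    records += [rec("P1", "F80.000", visit="V00")]
    gmap = build_generalization_map({r.icd10_code for r in records})
    db = build_transactions(records, gmap)
    summary = summarize_cohort(records, db)
    row = summary.query("characteristic=='visit_bin' and value=='10-19'").iloc[0]
    assert row["count"] == 1
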