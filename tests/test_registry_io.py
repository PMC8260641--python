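"""Dump loading: child aggregation, missing data, dialects, round trips."""

import csv
from datetime import date
from pathlib import Path

import pytest

from trialcoder.errors import ConfigurationError
from trialcoder.registry_io import (
    FieldName,
    LoadReport,
    SexesEligible,
    TrialRegistration,
    load_registry_dump,
    parse_date,
    parse_sexes_eligible,
    read_registrations_jsonl,
    word_count,
    write_dump_csv,
    write_registrations_jsonl,
)
from trialcoder.synthetic_data import GeneratorSpec, generate_registrations


def _write_table(path: Path, header, rows):
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        w.writerows(rows)


STUDY_HEADER = [
    "nct_id", "official_title", "brief_title", "study_type", "overall_status",
    "phase", "start_date", "study_first_submitted_date", "enrollment", "enrollment_type",
]


def _study_row(nct="NCT00000001", **kw):
    row = {
        "nct_id": nct, "official_title": "T", "brief_title": "T", "study_type": "Observational",
        "overall_status": "Recruiting", "phase": "", "start_date": "", "study_first_submitted_date": "2020-05-01",
        "enrollment": "", "enrollment_type": "",
    }
    row.update(kw)
    return [row[h] for h in STUDY_HEADER]


def test_conditions_aggregated_with_newline_separator(tmp_path):
    _write_table(tmp_path / "studies.csv", STUDY_HEADER, [_study_row()])
    _write_table(tmp_path / "conditions.csv", ["nct_id", "name"],
                 [["NCT00000001", "COVID-19"], ["NCT00000001", "Pneumonia"]])
    regs = load_registry_dump({"studies": tmp_path / "studies.csv", "conditions": tmp_path / "conditions.csv"})
    assert len(regs) == 1
    assert regs[0].texts[FieldName.CONDITIONS] == "COVID-19\nPneumonia"


def test_missing_child_tables_yield_empty_fields(tmp_path):
    _write_table(tmp_path / "studies.csv", STUDY_HEADER, [_study_row()])
    (reg,) = load_registry_dump({"studies": tmp_path / "studies.csv"})
    assert reg.texts[FieldName.ELIGIBILITY_CRITERIA] == ""
    assert reg.sexes_eligible == SexesEligible.MISSING
    assert reg.groups == [] and reg.interventions == []


def test_missing_studies_table_is_fatal(tmp_path):
    with pytest.raises(ConfigurationError):
        load_registry_dump({"studies": tmp_path / "nope.csv"})


def test_unparseable_row_skipped_and_counted(tmp_path):
    _write_table(tmp_path / "studies.csv", STUDY_HEADER,
                 [_study_row(), _study_row(nct="NCT00000002", study_type="Bogus")])
    report = LoadReport()
    regs = load_registry_dump({"studies": tmp_path / "studies.csv"}, report=report)
    assert len(regs) == 1 and report.rows_skipped == 1


def test_duplicate_nct_id_keeps_first(tmp_path):
    _write_table(tmp_path / "studies.csv", STUDY_HEADER,
                 [_study_row(overall_status="Recruiting"), _study_row(overall_status="Completed")])
    report = LoadReport()
    regs = load_registry_dump({"studies": tmp_path / "studies.csv"}, report=report)
    assert len(regs) == 1 and regs[0].status == "Recruiting"
    assert report.duplicate_nct_ids_dropped == 1


def test_totality_on_awkward_text(tmp_path):
    nasty = 'A "quoted" title,\nwith a newline – and unicode ✓'
    _write_table(tmp_path / "studies.csv", STUDY_HEADER, [_study_row(official_title=nasty)])
    (reg,) = load_registry_dump({"studies": tmp_path / "studies.csv"})
    assert reg.texts[FieldName.OFFICIAL_TITLE] == nasty


@pytest.mark.parametrize(
    "raw, expected",
    [
        ("All", SexesEligible.ALL),
        ("FEMALE", SexesEligible.FEMALE),
        ("male", SexesEligible.MALE),
        ("", SexesEligible.MISSING),
        ("Both", SexesEligible.MISSING),
        (None, SexesEligible.MISSING),
    ],
)
def test_parse_sexes_eligible(raw, expected):
    assert parse_sexes_eligible(raw) == expected


def test_parse_date_month_precision():
    assert parse_date("2020-03") == date(2020, 3, 1)
    assert parse_date("2020-03-15") == date(2020, 3, 15)
    assert parse_date("") is None


def test_word_count():
    reg = TrialRegistration(
        nct_id="NCT1", study_type="Observational", submitted_date=date(2020, 1, 1),
        texts={FieldName.BRIEF_SUMMARY: "A COVID-19 trial.", FieldName.DETAILED_DESCRIPTION: ""},
    )
    assert word_count(reg) == 3
    reg.texts[FieldName.BRIEF_SUMMARY] = ""
    assert word_count(reg) == 0


def test_generator_padding_gives_exact_word_count():
    from trialcoder.synthetic_data import _pad_to_word_count

    padded = _pad_to_word_count("This study evaluates care.", 245)
    assert len(padded.split()) == 245


def test_enrollment_missing_implies_missing_type():
    reg = TrialRegistration(
        nct_id="NCT1", study_type="Observational", submitted_date=date(2020, 1, 1),
        enrollment_count=None, enrollment_type="Anticipated",
    )
    assert reg.enrollment_type.value == "Missing"


def test_round_trip_both_dialects_equal_generator_truth(tmp_path):
    """Synthetic dump reloaded from either dialect is field-identical."""
    regs, _ = generate_registrations(GeneratorSpec(n_studies=50, seed=3, duplicate_rate=0.0))
    write_registrations_jsonl(regs, tmp_path / "regs.jsonl")
    paths = write_dump_csv(regs, tmp_path / "csv")
    from_jsonl = read_registrations_jsonl(tmp_path / "regs.jsonl")
    from_csv = load_registry_dump(paths, "aact_csv")
    assert from_jsonl == regs
    assert from_csv == regs
    # second round trip of the written form is also stable
    write_registrations_jsonl(from_csv, tmp_path / "regs2.jsonl")
    assert (tmp_path / "regs.jsonl").read_bytes() == (tmp_path / "regs2.jsonl").read_bytes()


def test_child_row_order_does_not_change_decisions(tmp_path):
    """Permuting child-table rows never changes downstream verdicts."""
    from trialcoder.cohort_selection import covid_relevance
    from trialcoder.sexgender_coding import assign_category

    _write_table(tmp_path / "studies.csv", STUDY_HEADER, [_study_row()])
    rows = [["NCT00000001", "Pneumonia"], ["NCT00000001", "COVID-19"], ["NCT00000001", "Sepsis"]]
    _write_table(tmp_path / "conditions.csv", ["nct_id", "name"], rows)
    (a,) = load_registry_dump({"studies": tmp_path / "studies.csv", "conditions": tmp_path / "conditions.csv"})
    _write_table(tmp_path / "conditions.csv", ["nct_id", "name"], rows[::-1])
    (b,) = load_registry_dump({"studies": tmp_path / "studies.csv", "conditions": tmp_path / "conditions.csv"})
    assert covid_relevance(a).rule == covid_relevance(b).rule
    assert assign_category(a).category == assign_category(b).category
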