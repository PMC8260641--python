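"""Cohort screening: placement rules, date window, statuses, deduplication."""

from datetime import date

import pytest

from trialcoder.cohort_selection import (
    CohortRule,
    covid_relevance,
    deduplicate,
    select_cohort,
    window_and_status_filter,
)
from trialcoder.fixtures import make_registration
from trialcoder.registry_io import FieldName, OutcomeRow


def test_title_match_dominates():
    reg = make_registration("NCT1", brief_title="COVID-19 Vaccine Study", conditions=("Pneumonia",))
    d = covid_relevance(reg)
    assert d.included and d.rule == CohortRule.TITLE_OR_CONDITION
    title_fields = {FieldName.BRIEF_TITLE, FieldName.OFFICIAL_TITLE}
    assert d.evidence and all(m.field in title_fields for m in d.evidence)


def test_single_secondary_outcome_mention_is_not_enough():
    reg = make_registration(
        "NCT2", conditions=("Pneumonia",),
        outcomes=(OutcomeRow("secondary", "Complications", "SARS-CoV-2 related complications."),),
    )
    d = covid_relevance(reg)
    assert not d.included and d.rule == CohortRule.NOT_MATCHED


def test_two_other_fields_rule():
    reg = make_registration(
        "NCT3", conditions=("Pneumonia",),
        brief_summary="Enrolling patients during the COVID pandemic.",
        outcomes=(OutcomeRow("secondary", "Complications", "COVID related complications."),),
    )
    d = covid_relevance(reg)
    assert d.included and d.rule == CohortRule.TWO_OTHER_FIELDS
    assert len({m.field for m in d.evidence}) >= 2


def test_primary_outcome_rule_beats_two_other_fields():
    reg = make_registration(
        "NCT4", conditions=("Pneumonia",),
        brief_summary="Enrolling during the COVID pandemic.",
        outcomes=(
            OutcomeRow("primary", "Time to COVID-19 clearance", ""),
            OutcomeRow("secondary", "x", "COVID complications."),
        ),
    )
    assert covid_relevance(reg).rule == CohortRule.PRIMARY_OUTCOME


@pytest.mark.parametrize(
    "start, submitted, kept",
    [
        (date(2019, 12, 15), date(2020, 2, 1), False),  # start date governs
        (None, date(2020, 5, 1), True),  # submission-date fallback
        (date(2020, 1, 1), date(2019, 12, 1), True),  # inclusive lower bound
        (date(2021, 1, 26), date(2021, 1, 2), True),  # inclusive upper bound
        (date(2021, 1, 27), date(2021, 1, 2), False),
    ],
)
def test_window_filter(start, submitted, kept):
    reg = make_registration("NCT5", submitted=submitted)
    reg.start_date = start
    kept_list, excluded = window_and_status_filter([reg])
    assert bool(kept_list) == kept
    if not kept:
        assert excluded[0].rule == CohortRule.OUT_OF_WINDOW


@pytest.mark.parametrize("status", ["Withdrawn", "withdrawn", "No longer available"])
def test_bad_status_excluded(status):
    reg = make_registration("NCT6", status=status)
    kept, excluded = window_and_status_filter([reg])
    assert not kept and excluded[0].rule == CohortRule.BAD_STATUS


def test_deduplicate_keeps_first_per_nct_id():
    a = make_registration("NCT7", brief_summary="first")
    b = make_registration("NCT7", brief_summary="second")
    c = make_registration("NCT8", brief_title="A Different Study")
    kept, log = deduplicate([a, b, c])
    assert [r.nct_id for r in kept] == ["NCT7", "NCT8"]
    assert kept[0].texts[FieldName.BRIEF_SUMMARY] == "first"
    assert log == [{"nct_id": "NCT7", "reason": "NctIdDuplicate", "kept": False}]


def test_title_duplicates_flagged_but_retained():
    a = make_registration("NCT9", brief_title="Same Title")
    b = make_registration("NCT10", brief_title="Same Title")
    kept, log = deduplicate([a, b])
    assert len(kept) == 2
    assert log == [{"nct_id": "NCT10", "reason": "TitleDuplicateCandidate", "kept": True}]


def test_planted_duplicates_removed(coded_small):
    truths = coded_small["truths"]
    regs = coded_small["registrations"]
    n_dup = sum(1 for t in truths if t.is_duplicate_row)
    kept, _ = deduplicate(regs)
    assert n_dup > 0 and len(kept) == len(regs) - n_dup


def test_filter_and_relevance_commute(coded_small):
    regs = [r for r in coded_small["registrations"]]
    filtered, _ = window_and_status_filter(regs)
    a = {r.nct_id for r in filtered if covid_relevance(r).included}
    relevant = [r for r in regs if covid_relevance(r).included]
    b = {r.nct_id for r in window_and_status_filter(relevant)[0]}
    assert a == b


def test_adding_a_covid_mention_is_monotone():
    """Adding a term occurrence never removes a study from the cohort."""
    reg = make_registration(
        "NCT11", conditions=("Pneumonia",),
        brief_summary="Enrolling patients during the COVID pandemic.",
        outcomes=(OutcomeRow("secondary", "Complications", "COVID related complications."),),
    )
    assert covid_relevance(reg).included
    reg.texts[FieldName.DETAILED_DESCRIPTION] += " COVID-19 exposure will be documented."
    assert covid_relevance(reg).included
    reg.texts[FieldName.BRIEF_TITLE] += " During COVID-19"
    d = covid_relevance(reg)
    assert d.included and d.rule == CohortRule.TITLE_OR_CONDITION


def test_synthetic_cohort_matches_planted_truth(coded_small):
    truths = coded_small["truths"]
    cohort_ids = {r.nct_id for r in coded_small["cohort"]}
    assert cohort_ids == {t.nct_id for t in truths if t.in_cohort}
    by_id = {d.nct_id: d for d in coded_small["decisions"] if d.included}
    for t in truths:
        if t.in_cohort:
            assert by_id[t.nct_id].rule.value == t.cohort_rule
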