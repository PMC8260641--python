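"""Sex/gender attention coding: hierarchy, auto rule, spurious contexts,
review channel, and the partition/monotonicity invariants."""

import pytest

from trialcoder import config
from trialcoder.fixtures import adversarial_fixtures, make_registration
from trialcoder.registry_io import FieldName, SexesEligible
from trialcoder.sexgender_coding import (
    Category,
    PIPELINE_RULE_IDS,
    Subtag,
    assign_category,
    auto_recruitment_only,
    detect_single_sex,
)
from trialcoder.textmatch import TermMatch


def test_single_sex_detection():
    assert detect_single_sex(make_registration("N1", sexes="Female")) == Category.FEMALE_ONLY
    assert detect_single_sex(make_registration("N2", sexes="Male")) == Category.MALE_ONLY
    assert detect_single_sex(make_registration("N3", sexes="All")) is None
    assert detect_single_sex(make_registration("N4", sexes="")) is None


def test_missing_sexes_field_flags_review():
    a = assign_category(make_registration("N5", sexes=""))
    assert a.category == Category.NO_MENTION and a.needs_review


def _m(field, start=0, end=3):
    return TermMatch("sex", field, start, end, "sex")


def test_auto_recruitment_only_requires_all_matches_in_criteria():
    assert auto_recruitment_only([_m(FieldName.ELIGIBILITY_CRITERIA)])
    assert not auto_recruitment_only(
        [_m(FieldName.ELIGIBILITY_CRITERIA), _m(FieldName.BRIEF_SUMMARY)]
    )
    assert not auto_recruitment_only([])


@pytest.mark.parametrize("fixture", adversarial_fixtures(), ids=lambda f: f.name)
def test_fixture_assignments(fixture):
    """Every curated edge case yields its expected category, subtag and flag."""
    a = assign_category(fixture.registration)
    assert a.category == fixture.category
    assert a.subtag == fixture.subtag
    assert a.needs_review == fixture.needs_review
    for rule_id in fixture.must_fire:
        assert rule_id in a.fired_rules


def test_every_bank_rule_fires_somewhere():
    """Coverage audit: the fixture set exercises every rule id."""
    fired = set()
    for f in adversarial_fixtures():
        fired.update(assign_category(f.registration).fired_rules)
    bank_ids = set(config.load_rule_bank().rule_ids)
    assert bank_ids <= fired
    assert set(PIPELINE_RULE_IDS) <= fired


def test_female_trap_yields_no_male_term_false_positive():
    reg = make_registration(
        "N6", brief_summary="Female and male participants will be recruited at all sites."
    )
    a = assign_category(reg)
    male_hits = [m for m in a.evidence if m.term == "male"]
    assert len(male_hits) == 1 and male_hits[0].surface_form.lower() == "male"


def test_auto_rule_subset_checkable_from_evidence(coded_small):
    """Every AutoEligibilityOnly study has all matches in the criteria field."""
    seen = 0
    for a in coded_small["assignments"]:
        if a.subtag == Subtag.AUTO_ELIGIBILITY_ONLY:
            seen += 1
            assert all(m.field == FieldName.ELIGIBILITY_CRITERIA for m in a.evidence)
    assert seen > 0


def test_partition_over_cohort(coded_small):
    """Category counts sum to the cohort size; one category per study."""
    assignments = coded_small["assignments"]
    assert len(assignments) == len(coded_small["cohort"])
    assert len({a.nct_id for a in assignments}) == len(assignments)
    counts = {}
    for a in assignments:
        counts[a.category] = counts.get(a.category, 0) + 1
    assert sum(counts.values()) == len(coded_small["cohort"])


ANALYSIS_SENTENCE = " Outcomes will be stratified by sex."


def test_hierarchy_monotonicity_on_fixtures():
    """Adding an analysis-cue sentence never moves a study to a lower category."""
    from trialcoder.sexgender_coding import CATEGORY_RANK

    for f in adversarial_fixtures():
        before = assign_category(f.registration)
        boosted = make_registration(
            f.registration.nct_id,
            brief_title=f.registration.texts[FieldName.BRIEF_TITLE],
            brief_summary=f.registration.texts[FieldName.BRIEF_SUMMARY],
            detailed_description=f.registration.texts[FieldName.DETAILED_DESCRIPTION]
            + ANALYSIS_SENTENCE,
            criteria=f.registration.texts[FieldName.ELIGIBILITY_CRITERIA],
            sexes=f.registration.sexes_eligible.value,
        )
        after = assign_category(boosted)
        assert CATEGORY_RANK[after.category] >= CATEGORY_RANK[before.category], f.name


def test_synthetic_recovery(coded_small):
    """Planted categories are recovered; adversarial misses carry the flag."""
    truths = {t.nct_id: t for t in coded_small["truths"] if not t.is_duplicate_row}
    clean_miss, adv_total, adv_miss = 0, 0, 0
    for a in coded_small["assignments"]:
        t = truths[a.nct_id]
        if t.adversarial:
            adv_total += 1
            if a.category.value != t.category:
                adv_miss += 1
                assert a.needs_review, (a.nct_id, t.template)
        elif a.category.value != t.category:
            clean_miss += 1
    assert clean_miss == 0
    assert adv_total > 0 and adv_miss / adv_total <= 0.10


def test_expected_review_flags_recovered(coded_small):
    """Registrations planted as ambiguous are flagged for human review."""
    truths = {t.nct_id: t for t in coded_small["truths"] if not t.is_duplicate_row}
    for a in coded_small["assignments"]:
        if truths[a.nct_id].needs_review:
            assert a.needs_review, a.nct_id
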