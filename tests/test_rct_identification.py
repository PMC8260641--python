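"""Pharmacological-RCT labelling: metadata rules, text fallbacks, precedence."""

from datetime import date

import pytest

from trialcoder.registry_io import (
    Allocation,
    GroupType,
    Intervention,
    InterventionType,
    StudyGroup,
    StudyType,
    TrialRegistration,
    assemble_texts,
)
from trialcoder.rct_identification import RctRule, StudyLabel, classify_study


def make_interventional(
    nct_id="NCT1",
    allocation=Allocation.RANDOMIZED,
    interventions=(Intervention(InterventionType.DRUG, "Participants receive remdesivir."),),
    groups=(),
    title="A Study of Remdesivir",
    study_type=StudyType.INTERVENTIONAL,
):
    groups = list(groups)
    interventions = list(interventions)
    texts = assemble_texts(
        official_title=title, brief_title=title, groups=groups, interventions=interventions
    )
    return TrialRegistration(
        nct_id=nct_id, study_type=study_type, allocation=allocation,
        submitted_date=date(2020, 5, 1), texts=texts, groups=groups, interventions=interventions,
    )


PLACEBO_GROUP = StudyGroup(GroupType.PLACEBO_COMPARATOR, "Placebo", "Matching placebo.")
EXPERIMENTAL_GROUP = StudyGroup(GroupType.EXPERIMENTAL, "Treatment", "Active drug.")


def test_group_type_control_rule():
    reg = make_interventional(groups=[EXPERIMENTAL_GROUP, PLACEBO_GROUP])
    c = classify_study(reg)
    assert c.label == StudyLabel.PHARMA_RCT and c.rct_rule == RctRule.GROUP_TYPE_CONTROL


def test_group_text_control_rule():
    reg = make_interventional(
        groups=[
            EXPERIMENTAL_GROUP,
            StudyGroup(GroupType.ACTIVE_COMPARATOR, "Arm B", "Receives matching placebo."),
        ]
    )
    c = classify_study(reg)
    assert c.label == StudyLabel.PHARMA_RCT and c.rct_rule == RctRule.GROUP_TEXT_CONTROL
    assert c.evidence


def test_group_type_precedes_group_text():
    """A study satisfying the group-type rule reports it even when text rules also fire."""
    reg = make_interventional(groups=[EXPERIMENTAL_GROUP, PLACEBO_GROUP],
                              title="A Randomized Placebo Controlled Trial of Remdesivir")
    assert classify_study(reg).rct_rule == RctRule.GROUP_TYPE_CONTROL


def test_title_text_rule_random_plus_control():
    reg = make_interventional(
        groups=[EXPERIMENTAL_GROUP],
        title="A Randomized, Placebo Controlled Trial of Remdesivir",
    )
    assert classify_study(reg).rct_rule == RctRule.TITLE_OR_INTERVENTION_TEXT


def test_rct_token_is_case_sensitive():
    yes = make_interventional(groups=[EXPERIMENTAL_GROUP], allocation=Allocation.MISSING,
                              title="An RCT of Remdesivir")
    assert classify_study(yes).rct_rule == RctRule.TITLE_OR_INTERVENTION_TEXT
    no = make_interventional(groups=[EXPERIMENTAL_GROUP], allocation=Allocation.MISSING,
                             title="Infarct size after treatment")
    assert classify_study(no).label == StudyLabel.OTHER_INTERVENTION


def test_random_without_control_is_not_enough():
    reg = make_interventional(groups=[EXPERIMENTAL_GROUP], title="A Randomized Dose Comparison Study")
    assert classify_study(reg).label == StudyLabel.OTHER_INTERVENTION


def test_behavioral_randomized_is_other_intervention():
    reg = make_interventional(
        interventions=[Intervention(InterventionType.BEHAVIORAL, "Telehealth counseling.")],
        groups=[EXPERIMENTAL_GROUP, PLACEBO_GROUP],
    )
    c = classify_study(reg)
    assert c.label == StudyLabel.OTHER_INTERVENTION and c.rct_rule is None


def test_non_randomized_drug_is_other_intervention():
    reg = make_interventional(allocation=Allocation.NON_RANDOMIZED,
                              groups=[EXPERIMENTAL_GROUP, PLACEBO_GROUP])
    assert classify_study(reg).label == StudyLabel.OTHER_INTERVENTION


@pytest.mark.parametrize(
    "study_type, label",
    [
        (StudyType.OBSERVATIONAL, StudyLabel.OBSERVATIONAL),
        (StudyType.PATIENT_REGISTRY, StudyLabel.PATIENT_REGISTRY),
        (StudyType.EXPANDED_ACCESS, StudyLabel.EXPANDED_ACCESS),
    ],
)
def test_passthrough_labels(study_type, label):
    reg = make_interventional(study_type=study_type)
    c = classify_study(reg)
    assert c.label == label and c.rct_rule is None


def test_labels_partition_cohort(coded_small):
    classes = coded_small["classes"]
    assert len(classes) == len(coded_small["cohort"])
    assert all((c.rct_rule is not None) == (c.label == StudyLabel.PHARMA_RCT) for c in classes)


def test_synthetic_labels_match_planted_truth(coded_small):
    truths = {t.nct_id: t for t in coded_small["truths"] if not t.is_duplicate_row}
    for c in coded_small["classes"]:
        t = truths[c.nct_id]
        assert c.label.value == t.label
        assert (c.rct_rule.value if c.rct_rule else "") == t.rct_rule
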