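"""Pharmacological-RCT labelling of cohort studies.

The registry has no pre-defined "pharmacological RCT" label, so one is
derived from structured design metadata with textual fallbacks: an
interventional study with randomized allocation and at least one drug or
biological/vaccine intervention is a PharmaRCT when a control arm is
identifiable —

``GroupTypeControl``
    a participant group typed placebo/sham comparator or no-intervention;
``GroupTextControl``
    failing that, a group title or description mentioning control*/placebo*
    (some obvious control arms are typed 'experimental' or 'active
    comparator');
``TitleOrInterventionText``
    failing that, the study titles or intervention descriptions contain the
    all-caps token "RCT", or random* together with control*/placebo*.

Remaining interventional studies are OtherIntervention; observational,
patient-registry and expanded-access records pass through from study type.
Missing allocation counts as randomized only when the text itself supplies
random* (or the RCT token): positive evidence of randomization is required.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

from .registry_io import (
    Allocation,
    FieldName,
    GroupType,
    InterventionType,
    StudyType,
    TrialRegistration,
)
from .textmatch import TermMatch, TermSpec, find_in_text, find_matches

CONTROL_GROUP_TYPES = frozenset(
    {GroupType.PLACEBO_COMPARATOR, GroupType.SHAM_COMPARATOR, GroupType.NO_INTERVENTION}
)
PHARMA_INTERVENTION_TYPES = frozenset({InterventionType.DRUG, InterventionType.BIOLOGICAL})

TERM_CONTROL = TermSpec("control*", wildcard=True)
TERM_PLACEBO = TermSpec("placebo*", wildcard=True)
TERM_RANDOM = TermSpec("random*", wildcard=True)
TERM_RCT = TermSpec("RCT", case_sensitive=True)  # all-caps token only

TITLE_INTERVENTION_FIELDS = (
    FieldName.OFFICIAL_TITLE,
    FieldName.BRIEF_TITLE,
    FieldName.INTERVENTION_DESCRIPTION,
)


class StudyLabel(str, Enum):
    PHARMA_RCT = "PharmaRCT"
    OTHER_INTERVENTION = "OtherIntervention"
    OBSERVATIONAL = "Observational"
    PATIENT_REGISTRY = "PatientRegistry"
    EXPANDED_ACCESS = "ExpandedAccess"


class RctRule(str, Enum):
    GROUP_TYPE_CONTROL = "GroupTypeControl"
    GROUP_TEXT_CONTROL = "GroupTextControl"
    TITLE_OR_INTERVENTION_TEXT = "TitleOrInterventionText"


@dataclass
class StudyClass:
    nct_id: str
    label: StudyLabel
    rct_rule: Optional[RctRule] = None
    evidence: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.rct_rule is not None) != (self.label == StudyLabel.PHARMA_RCT):
            raise ValueError(f"{self.nct_id}: rct_rule present iff label is PharmaRCT")


_PASSTHROUGH = {
    StudyType.OBSERVATIONAL: StudyLabel.OBSERVATIONAL,
    StudyType.PATIENT_REGISTRY: StudyLabel.PATIENT_REGISTRY,
    StudyType.EXPANDED_ACCESS: StudyLabel.EXPANDED_ACCESS,
}


def _group_text_matches(reg: TrialRegistration, terms: Sequence[TermSpec]) -> list[TermMatch]:
    return find_matches(reg.texts, (FieldName.GROUP_TITLE, FieldName.GROUP_DESCRIPTION), terms)


def classify_study(registration: TrialRegistration) -> StudyClass:
    """Label one cohort study; rule precedence is group type, group text, then title/intervention text."""
    passthrough = _PASSTHROUGH.get(registration.study_type)
    if passthrough is not None:
        return StudyClass(registration.nct_id, passthrough)

    pharmacological = any(
        iv.intervention_type in PHARMA_INTERVENTION_TYPES for iv in registration.interventions
    )
    title_text_matches = find_matches(
        registration.texts, TITLE_INTERVENTION_FIELDS, (TERM_RCT, TERM_RANDOM, TERM_CONTROL, TERM_PLACEBO)
    )
    has_rct_token = any(m.term == TERM_RCT.surface for m in title_text_matches)
    has_random = any(m.term == TERM_RANDOM.surface for m in title_text_matches)
    has_control_text = any(m.term in (TERM_CONTROL.surface, TERM_PLACEBO.surface) for m in title_text_matches)

    randomized = registration.allocation == Allocation.RANDOMIZED or (
        registration.allocation == Allocation.MISSING and (has_random or has_rct_token)
    )

    if pharmacological and randomized:
        if any(g.group_type in CONTROL_GROUP_TYPES for g in registration.groups):
            return StudyClass(registration.nct_id, StudyLabel.PHARMA_RCT, RctRule.GROUP_TYPE_CONTROL)
        group_hits = _group_text_matches(registration, (TERM_CONTROL, TERM_PLACEBO))
        if group_hits:
            return StudyClass(
                registration.nct_id, StudyLabel.PHARMA_RCT, RctRule.GROUP_TEXT_CONTROL, group_hits
            )
        if has_rct_token or (has_random and has_control_text):
            return StudyClass(
                registration.nct_id,
                StudyLabel.PHARMA_RCT,
                RctRule.TITLE_OR_INTERVENTION_TEXT,
                title_text_matches,
            )
    return StudyClass(registration.nct_id, StudyLabel.OTHER_INTERVENTION)


def classify_all(cohort: Sequence[TrialRegistration]) -> list[StudyClass]:
    return [classify_study(reg) for reg in cohort]
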