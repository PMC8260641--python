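"""Selection of the COVID-19 study cohort from a loaded registry dump.

A registration enters the cohort when a COVID-19 term occurs in its titles
or conditions, failing that in a primary outcome measure, failing that in at
least two other relevant fields (brief summary, detailed description, or a
non-primary outcome title/description). Records outside the 1 Jan 2020 –
26 Jan 2021 window — judged on the start date, falling back to the
first-submitted date — or listed as 'Withdrawn'/'No longer available', and
duplicate ids, are excluded with a logged reason.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from enum import Enum
from typing import Iterable, Optional, Sequence

from . import config
from .registry_io import FieldName, TrialRegistration
from .textmatch import TermMatch, TermSpec, find_matches

WINDOW_START = date(2020, 1, 1)
WINDOW_END = date(2021, 1, 26)  # the registry snapshot date; both ends inclusive

BAD_STATUSES = frozenset({"withdrawn", "no longer available"})

TITLE_CONDITION_FIELDS = frozenset(
    {FieldName.OFFICIAL_TITLE, FieldName.BRIEF_TITLE, FieldName.CONDITIONS}
)
PRIMARY_OUTCOME_FIELDS = frozenset(
    {FieldName.PRIMARY_OUTCOME_TITLE, FieldName.PRIMARY_OUTCOME_DESCRIPTION}
)


class CohortRule(str, Enum):
    TITLE_OR_CONDITION = "TitleOrCondition"
    PRIMARY_OUTCOME = "PrimaryOutcome"
    TWO_OTHER_FIELDS = "TwoOtherFields"
    NOT_MATCHED = "NotMatched"
    OUT_OF_WINDOW = "OutOfWindow"
    BAD_STATUS = "BadStatus"
    DUPLICATE = "Duplicate"


INCLUSION_RULES = frozenset(
    {CohortRule.TITLE_OR_CONDITION, CohortRule.PRIMARY_OUTCOME, CohortRule.TWO_OTHER_FIELDS}
)


@dataclass
class CohortDecision:
    nct_id: str
    included: bool
    rule: CohortRule
    evidence: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.included and self.rule not in INCLUSION_RULES:
            raise ValueError(f"{self.nct_id}: inclusion under non-inclusion rule {self.rule}")


def covid_relevance(
    registration: TrialRegistration,
    terms: Optional[Sequence[TermSpec]] = None,
    scope: Optional[Sequence[FieldName]] = None,
) -> CohortDecision:
    """Judge COVID-19 relevance of one registration by term placement.

    Rule precedence: titles/conditions, then primary outcomes, then at least
    two *distinct* other in-scope fields.
    """
    cfg = config.load_covid_config()
    terms = terms if terms is not None else cfg.terms
    scope = scope if scope is not None else cfg.scope
    matches = find_matches(registration.texts, scope, terms)

    title_cond = [m for m in matches if m.field in TITLE_CONDITION_FIELDS]
    if title_cond:
        return CohortDecision(registration.nct_id, True, CohortRule.TITLE_OR_CONDITION, title_cond)
    primary = [m for m in matches if m.field in PRIMARY_OUTCOME_FIELDS]
    if primary:
        return CohortDecision(registration.nct_id, True, CohortRule.PRIMARY_OUTCOME, primary)
    other = [m for m in matches if m.field not in TITLE_CONDITION_FIELDS | PRIMARY_OUTCOME_FIELDS]
    if len({m.field for m in other}) >= 2:
        return CohortDecision(registration.nct_id, True, CohortRule.TWO_OTHER_FIELDS, other)
    return CohortDecision(registration.nct_id, False, CohortRule.NOT_MATCHED, matches)


def in_window(registration: TrialRegistration, start: date = WINDOW_START, end: date = WINDOW_END) -> bool:
    return start <= registration.effective_date <= end


def has_bad_status(registration: TrialRegistration) -> bool:
    return registration.status.strip().lower() in BAD_STATUSES


def window_and_status_filter(
    registrations: Iterable[TrialRegistration],
    start: date = WINDOW_START,
    end: date = WINDOW_END,
) -> tuple[list[TrialRegistration], list[CohortDecision]]:
    """Keep in-window records without an excluded status; log the rest."""
    kept: list[TrialRegistration] = []
    excluded: list[CohortDecision] = []
    for reg in registrations:
        if not in_window(reg, start, end):
            excluded.append(CohortDecision(reg.nct_id, False, CohortRule.OUT_OF_WINDOW))
        elif has_bad_status(reg):
            excluded.append(CohortDecision(reg.nct_id, False, CohortRule.BAD_STATUS))
        else:
            kept.append(reg)
    return kept, excluded


def _normalized_title_pair(reg: TrialRegistration) -> tuple[str, str]:
    return (
        " ".join(reg.texts[FieldName.OFFICIAL_TITLE].lower().split()),
        " ".join(reg.texts[FieldName.BRIEF_TITLE].lower().split()),
    )


def deduplicate(
    registrations: Iterable[TrialRegistration],
) -> tuple[list[TrialRegistration], list[dict]]:
    """Drop repeated nct_ids (keep first); flag same-title pairs without dropping.

    The registry id is the only duplicate criterion acted on; registrations
    sharing a normalised title pair with an earlier record are only flagged
    as candidate duplicates for human review.
    """
    kept: list[TrialRegistration] = []
    dedup_log: list[dict] = []
    seen_ids: set = set()
    seen_titles: set = set()
    for reg in registrations:
        if reg.nct_id in seen_ids:
            dedup_log.append({"nct_id": reg.nct_id, "reason": "NctIdDuplicate", "kept": False})
            continue
        seen_ids.add(reg.nct_id)
        titles = _normalized_title_pair(reg)
        if any(titles) and titles in seen_titles:
            dedup_log.append({"nct_id": reg.nct_id, "reason": "TitleDuplicateCandidate", "kept": True})
        seen_titles.add(titles)
        kept.append(reg)
    return kept, dedup_log


def select_cohort(
    registrations: Sequence[TrialRegistration],
    terms: Optional[Sequence[TermSpec]] = None,
    start: date = WINDOW_START,
    end: date = WINDOW_END,
) -> tuple[list[TrialRegistration], list[CohortDecision], list[dict]]:
    """Full cohort screen: dedup, date window, status, then term relevance.

    Returns the cohort, one decision per input record (duplicates included),
    and the candidate-duplicate log.
    """
    unique, dedup_log = deduplicate(registrations)
    dropped_ids = [e["nct_id"] for e in dedup_log if not e["kept"]]
    decisions: list[CohortDecision] = [
        CohortDecision(nct_id, False, CohortRule.DUPLICATE) for nct_id in dropped_ids
    ]
    cohort: list[TrialRegistration] = []
    for reg in unique:
        if not in_window(reg, start, end):
            decisions.append(CohortDecision(reg.nct_id, False, CohortRule.OUT_OF_WINDOW))
            continue
        if has_bad_status(reg):
            decisions.append(CohortDecision(reg.nct_id, False, CohortRule.BAD_STATUS))
            continue
        decision = covid_relevance(reg, terms)
        decisions.append(decision)
        if decision.included:
            cohort.append(reg)
    return cohort, decisions, dedup_log
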