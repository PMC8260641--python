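"""Hierarchical, mutually exclusive coding of sex/gender attention.

Every cohort study receives exactly one category, in decreasing order of
attention:

``FemaleOnly`` / ``MaleOnly``
    single-sex designs, read off the structured eligible-sexes field;
``Analysis``
    an explicit plan to use sex/gender analytically (stratification,
    subgroup analyses, covariate adjustment, disaggregation, or a stated
    hypothesis involving sex/gender);
``OtherMention``
    sex-matching / representative-sample intent, or an explicit intent to
    record or report participant sex/gender;
``RecruitmentOnly``
    sex/gender appears only in recruitment statements covering both sexes —
    most commonly automatically, because the only term occurrences sit in
    the eligibility inclusion-criteria list;
``NoMention``
    no relevant occurrence, including *spurious* mentions (contraception
    requirements, pregnancy tests, donor or parent sex, literature
    background) that carry no design meaning.

Coding is evidence-first: each term occurrence is judged inside its context
window (the containing sentence, clamped to ±120 characters), negative
(spurious) rules run before positive ones, and a ``needs_review`` flag marks
every registration where the rule bank could not reach a confident verdict,
mirroring a human-coder escalation channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

from . import config
from .config import Rule, RuleBank, TermConfig
from .registry_io import FieldName, SexesEligible, TrialRegistration
from .textmatch import TermMatch, find_in_text, find_matches

SENTENCE_BOUNDARIES = ".!?;\n"
WINDOW_RADIUS = 120  # fallback/clamp when sentence bounds are unclear

RULE_SINGLE_SEX_FEMALE = "single_sex.female"
RULE_SINGLE_SEX_MALE = "single_sex.male"
RULE_AUTO_ELIGIBILITY_ONLY = "auto.eligibility_only"
PIPELINE_RULE_IDS = (RULE_SINGLE_SEX_FEMALE, RULE_SINGLE_SEX_MALE, RULE_AUTO_ELIGIBILITY_ONLY)


class Category(str, Enum):
    FEMALE_ONLY = "FemaleOnly"
    MALE_ONLY = "MaleOnly"
    ANALYSIS = "Analysis"
    OTHER_MENTION = "OtherMention"
    RECRUITMENT_ONLY = "RecruitmentOnly"
    NO_MENTION = "NoMention"


class Subtag(str, Enum):
    MATCHED_OR_REPRESENTATIVE = "MatchedOrRepresentative"
    RECORD_OR_REPORT = "RecordOrReport"
    AUTO_ELIGIBILITY_ONLY = "AutoEligibilityOnly"
    SPURIOUS_MENTION = "SpuriousMention"


# precedence: a higher value is a higher level of attention
CATEGORY_RANK = {
    Category.NO_MENTION: 0,
    Category.RECRUITMENT_ONLY: 1,
    Category.OTHER_MENTION: 2,
    Category.ANALYSIS: 3,
    Category.MALE_ONLY: 4,
    Category.FEMALE_ONLY: 4,
}

_VALID_SUBTAGS = {
    Category.OTHER_MENTION: {Subtag.MATCHED_OR_REPRESENTATIVE, Subtag.RECORD_OR_REPORT},
    Category.RECRUITMENT_ONLY: {Subtag.AUTO_ELIGIBILITY_ONLY},
    Category.NO_MENTION: {Subtag.SPURIOUS_MENTION},
}


@dataclass
class SexGenderAssignment:
    nct_id: str
    category: Category
    subtag: Optional[Subtag] = None
    evidence: list = field(default_factory=list)
    fired_rules: list = field(default_factory=list)
    needs_review: bool = False

    def __post_init__(self) -> None:
        if self.subtag is not None and self.subtag not in _VALID_SUBTAGS.get(self.category, set()):
            raise ValueError(f"{self.nct_id}: subtag {self.subtag} invalid for category {self.category}")


def detect_single_sex(registration: TrialRegistration) -> Optional[Category]:
    """Single-sex design from the structured eligible-sexes field, if any."""
    if registration.sexes_eligible == SexesEligible.FEMALE:
        return Category.FEMALE_ONLY
    if registration.sexes_eligible == SexesEligible.MALE:
        return Category.MALE_ONLY
    return None


def auto_recruitment_only(matches: Sequence[TermMatch]) -> bool:
    """True iff at least one match exists and all sit in the eligibility criteria list."""
    return bool(matches) and all(m.field == FieldName.ELIGIBILITY_CRITERIA for m in matches)


def context_window(text: str, start: int, end: int) -> tuple[int, int]:
    """Bounds of the sentence containing [start, end), clamped to ±120 chars."""
    left = max((text.rfind(b, 0, start) for b in SENTENCE_BOUNDARIES), default=-1)
    left = max(left + 1, start - WINDOW_RADIUS)
    rights = [i for b in SENTENCE_BOUNDARIES if (i := text.find(b, end)) != -1]
    right = min(rights) + 1 if rights else len(text)
    right = min(right, end + WINDOW_RADIUS)
    return left, right


@dataclass
class WindowEval:
    """Rule-bank verdicts for one term occurrence's context window."""

    match: TermMatch
    window_text: str
    spurious_ids: list = field(default_factory=list)
    analysis_ids: list = field(default_factory=list)
    other_rules: list = field(default_factory=list)  # fired Rule objects of kind other_mention
    recruitment_ids: list = field(default_factory=list)
    both_sexes_phrase: bool = False
    lit_analysis: bool = False  # analysis-style cue inside a spurious/background window

    @property
    def is_spurious(self) -> bool:
        return bool(self.spurious_ids)


def _rule_fires(rule: Rule, window_text: str) -> bool:
    return bool(find_in_text(window_text, rule.cues))


def classify_contexts(
    registration: TrialRegistration,
    matches: Sequence[TermMatch],
    bank: Optional[RuleBank] = None,
) -> list[WindowEval]:
    """Evaluate the rule bank on the context window of every term occurrence.

    Spurious rules are evaluated first: a window holding a spurious cue is
    discounted entirely and contributes no positive evidence. An analysis
    cue co-occurring with a literature/background cue is remembered so the
    registration can be flagged for human review.
    """
    bank = bank if bank is not None else config.load_rule_bank()
    evals: list[WindowEval] = []
    for m in matches:
        text = registration.texts[m.field]
        lo, hi = context_window(text, m.start, m.end)
        ev = WindowEval(match=m, window_text=text[lo:hi])
        for rule in bank.of_kind("spurious"):
            if _rule_fires(rule, ev.window_text):
                ev.spurious_ids.append(rule.rule_id)
        for rule in bank.of_kind("analysis"):
            if _rule_fires(rule, ev.window_text):
                if ev.is_spurious:
                    ev.lit_analysis = True
                else:
                    ev.analysis_ids.append(rule.rule_id)
        if not ev.is_spurious:
            for rule in bank.of_kind("other_mention"):
                if _rule_fires(rule, ev.window_text):
                    ev.other_rules.append(rule)
            for rule in bank.of_kind("recruitment"):
                if _rule_fires(rule, ev.window_text):
                    ev.recruitment_ids.append(rule.rule_id)
                    if rule.rule_id.endswith("both_sexes_phrase"):
                        ev.both_sexes_phrase = True
        evals.append(ev)
    return evals


def _ordered_unique(ids: Iterable[str]) -> list[str]:
    seen: set = set()
    out: list[str] = []
    for i in ids:
        if i not in seen:
            seen.add(i)
            out.append(i)
    return out


def assign_category(
    registration: TrialRegistration,
    terms: Optional[TermConfig] = None,
    bank: Optional[RuleBank] = None,
) -> SexGenderAssignment:
    """Assign the single, mutually exclusive sex/gender attention category.

    Precedence: single-sex design ≻ Analysis ≻ OtherMention ≻
    RecruitmentOnly ≻ NoMention. The recruitment category is reached either
    automatically (all non-spurious occurrences inside the eligibility
    criteria list) or through an explicit recruitment statement covering
    both sexes. Occurrences whose every context is spurious yield NoMention
    with the SpuriousMention subtag.
    """
    cfg = terms if terms is not None else config.load_sexgender_config()
    bank = bank if bank is not None else config.load_rule_bank()
    needs_review = registration.sexes_eligible == SexesEligible.MISSING

    matches = find_matches(registration.texts, cfg.scope, cfg.terms)

    single = detect_single_sex(registration)
    if single is not None:
        rule_id = RULE_SINGLE_SEX_FEMALE if single == Category.FEMALE_ONLY else RULE_SINGLE_SEX_MALE
        return SexGenderAssignment(
            registration.nct_id, single, None, list(matches), [rule_id], needs_review
        )

    if not matches:
        return SexGenderAssignment(
            registration.nct_id, Category.NO_MENTION, None, [], [], needs_review
        )

    evals = classify_contexts(registration, matches, bank)
    live = [ev for ev in evals if not ev.is_spurious]
    lit_analysis = any(ev.lit_analysis for ev in evals)
    fired = _ordered_unique(
        rid
        for ev in evals
        for rid in (
            ev.spurious_ids + ev.analysis_ids + [r.rule_id for r in ev.other_rules] + ev.recruitment_ids
        )
    )

    if not live:
        return SexGenderAssignment(
            registration.nct_id,
            Category.NO_MENTION,
            Subtag.SPURIOUS_MENTION,
            list(matches),
            fired,
            needs_review or lit_analysis,
        )

    if any(ev.analysis_ids for ev in live):
        return SexGenderAssignment(
            registration.nct_id, Category.ANALYSIS, None, list(matches), fired, needs_review
        )

    other_fired = [r for ev in live for r in ev.other_rules]
    if other_fired:
        subtag = (
            Subtag.MATCHED_OR_REPRESENTATIVE
            if any(r.subtag == Subtag.MATCHED_OR_REPRESENTATIVE.value for r in other_fired)
            else Subtag.RECORD_OR_REPORT
        )
        return SexGenderAssignment(
            registration.nct_id,
            Category.OTHER_MENTION,
            subtag,
            list(matches),
            fired,
            needs_review or lit_analysis,
        )

    live_matches = [ev.match for ev in live]
    if auto_recruitment_only(live_matches):
        return SexGenderAssignment(
            registration.nct_id,
            Category.RECRUITMENT_ONLY,
            Subtag.AUTO_ELIGIBILITY_ONLY,
            list(matches),
            fired + [RULE_AUTO_ELIGIBILITY_ONLY],
            needs_review or lit_analysis,
        )

    if _explicit_both_sex_recruitment(live, cfg):
        return SexGenderAssignment(
            registration.nct_id,
            Category.RECRUITMENT_ONLY,
            None,
            list(matches),
            fired,
            needs_review or lit_analysis,
        )

    # a live mention the rule bank could not code: send to human review
    return SexGenderAssignment(
        registration.nct_id, Category.NO_MENTION, None, list(matches), fired, True
    )


def _explicit_both_sex_recruitment(live: Sequence[WindowEval], cfg: TermConfig) -> bool:
    """A recruitment-cue context exists and its sex terms cover both sexes.

    Coverage within the registration's recruitment contexts: a female-class
    and a male-class term together, a neutral term (sex/gender), or an
    explicit both-sexes phrase. The both-sexes phrase itself only supplies
    coverage — candidacy needs a genuine recruitment cue (enrol*, recruit*,
    eligib*, inclusion, aged).
    """
    recruiting = [
        ev
        for ev in live
        if any(not rid.endswith("both_sexes_phrase") for rid in ev.recruitment_ids)
    ]
    if not recruiting:
        return False
    if any(ev.both_sexes_phrase for ev in recruiting):
        return True
    classes = {cfg.sex_classes.get(ev.match.term) for ev in recruiting}
    return "neutral" in classes or {"female", "male"} <= classes


def assign_all(
    cohort: Sequence[TrialRegistration],
    terms: Optional[TermConfig] = None,
    bank: Optional[RuleBank] = None,
) -> list[SexGenderAssignment]:
    cfg = terms if terms is not None else config.load_sexgender_config()
    bank = bank if bank is not None else config.load_rule_bank()
    return [assign_category(reg, cfg, bank) for reg in cohort]
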