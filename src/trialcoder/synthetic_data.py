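"""Synthetic registry dumps with known ground truth for every pipeline stage.

Registrations are assembled from compositional sentence templates (a class
template + a COVID-placement template + a sex/gender category template +
neutral filler), so each planted cohort rule, attention category and study
label is satisfiable by the pipeline's documented rules and recoverable
exactly. Defaults mirror the headline structure of the real COVID-19
registration sample: the category split (FemaleOnly 2.3 / MaleOnly 0.5 /
Analysis 4.0 / OtherMention 5.4 / RecruitmentOnly 21.2 / NoMention 66.7, in
percent), the study-type split (observational 1659 : other interventional
1314 : pharmacological RCT 1161 : patient registry 260 : expanded access 26,
rescaled), COVID terms overwhelmingly in titles/conditions, 56% of
submissions in the first half of 2020, and per-group enrollment and
word-count medians.

A configurable fraction of records is *adversarial*: the planted category is
expressed through a trap template (contraception clauses, literature
summaries, donor-sex mentions, "female"-contains-"male" phrasing, and one
deliberately uncodable phrasing) so the coder's spurious-mention rules and
review channel are exercised. Output is fully deterministic under the seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, fields as dc_fields
from datetime import date, timedelta
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .cohort_selection import (
    BAD_STATUSES,
    WINDOW_END,
    WINDOW_START,
    CohortRule,
)
from .errors import ConfigurationError
from .rct_identification import RctRule, StudyLabel
from .registry_io import (
    Allocation,
    EnrollmentType,
    GroupType,
    Intervention,
    InterventionType,
    OutcomeRow,
    Phase,
    SexesEligible,
    StudyGroup,
    StudyType,
    TrialRegistration,
    assemble_texts,
    write_dump_csv,
    write_registrations_jsonl,
)
from .sexgender_coding import Category, Subtag

# ---------------------------------------------------------------------------
# Default mixes (shares of the emulated registration sample)
# ---------------------------------------------------------------------------

_N_REFERENCE = 4420  # size of the emulated sample

DEFAULT_CATEGORY_MIX = {
    Category.FEMALE_ONLY.value: 100 / _N_REFERENCE,
    Category.MALE_ONLY.value: 24 / _N_REFERENCE,
    Category.ANALYSIS.value: 178 / _N_REFERENCE,
    Category.OTHER_MENTION.value: 237 / _N_REFERENCE,
    Category.RECRUITMENT_ONLY.value: 935 / _N_REFERENCE,
    Category.NO_MENTION.value: 2946 / _N_REFERENCE,
}

DEFAULT_TYPE_MIX = {
    StudyLabel.OBSERVATIONAL.value: 1659 / _N_REFERENCE,
    StudyLabel.OTHER_INTERVENTION.value: 1314 / _N_REFERENCE,
    StudyLabel.PHARMA_RCT.value: 1161 / _N_REFERENCE,
    StudyLabel.PATIENT_REGISTRY.value: 260 / _N_REFERENCE,
    StudyLabel.EXPANDED_ACCESS.value: 26 / _N_REFERENCE,
}

# title/condition placement dominates (~98% of COVID records), a small tail
# reaches the cohort via outcome-based rules, plus 5% non-COVID noise
DEFAULT_COVID_RULE_MIX = {
    CohortRule.TITLE_OR_CONDITION.value: 0.93,
    CohortRule.PRIMARY_OUTCOME.value: 0.01,
    CohortRule.TWO_OTHER_FIELDS.value: 0.01,
    "NonCovid": 0.05,
}

# log-normal enrollment medians: category targets override class targets
DEFAULT_ENROLLMENT_MEDIANS = {
    f"category:{Category.ANALYSIS.value}": 700,
    f"category:{Category.NO_MENTION.value}": 176,
    f"label:{StudyLabel.OBSERVATIONAL.value}": 287,
    f"label:{StudyLabel.PATIENT_REGISTRY.value}": 400,
    f"label:{StudyLabel.PHARMA_RCT.value}": 160,
    f"label:{StudyLabel.OTHER_INTERVENTION.value}": 100,
}

DEFAULT_WORDCOUNT_MEDIANS = {
    StudyLabel.OBSERVATIONAL.value: 245,
    StudyLabel.PATIENT_REGISTRY.value: 245,
    StudyLabel.OTHER_INTERVENTION.value: 260,
    StudyLabel.PHARMA_RCT.value: 214,
    StudyLabel.EXPANDED_ACCESS.value: 120,
}

# monthly submission weights, Nov 2019 .. Feb 2021; within the screening
# window the first half of 2020 carries 56% of the mass, peaking late spring
DEFAULT_DATE_WEIGHTS = {
    "2019-11": 0.010, "2019-12": 0.010,
    "2020-01": 0.038, "2020-02": 0.048, "2020-03": 0.096, "2020-04": 0.125,
    "2020-05": 0.125, "2020-06": 0.106, "2020-07": 0.077, "2020-08": 0.067,
    "2020-09": 0.067, "2020-10": 0.058, "2020-11": 0.058, "2020-12": 0.048,
    "2021-01": 0.047, "2021-02": 0.020,
}


@dataclass
class GeneratorSpec:
    """Controls for one synthetic dump; the seed fully determines the output."""

    n_studies: int = 1000
    seed: int = 0
    category_mix: dict = field(default_factory=lambda: dict(DEFAULT_CATEGORY_MIX))
    type_mix: dict = field(default_factory=lambda: dict(DEFAULT_TYPE_MIX))
    covid_rule_mix: dict = field(default_factory=lambda: dict(DEFAULT_COVID_RULE_MIX))
    enrollment_medians: dict = field(default_factory=lambda: dict(DEFAULT_ENROLLMENT_MEDIANS))
    enrollment_sigma: float = 1.0  # dispersion on the log scale
    wordcount_medians: dict = field(default_factory=lambda: dict(DEFAULT_WORDCOUNT_MEDIANS))
    wordcount_sigma: float = 0.35
    date_weights: dict = field(default_factory=lambda: dict(DEFAULT_DATE_WEIGHTS))
    adversarial_rate: float = 0.15
    duplicate_rate: float = 0.01
    withdrawn_rate: float = 0.015
    missing_sex_rate: float = 0.01
    start_date_rate: float = 0.85
    detailed_description_rate: float = 0.701
    document_rate: float = 0.03
    facility_rate: float = 0.89
    us_rate: float = 0.227
    auto_recruitment_share: float = 0.831  # of RecruitmentOnly records
    matched_share_of_other: float = 0.274  # matched/representative within OtherMention

    def validate(self) -> None:
        if self.n_studies <= 0:
            raise ConfigurationError("n_studies must be positive")
        for name in ("category_mix", "type_mix", "covid_rule_mix", "date_weights"):
            mix = getattr(self, name)
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(f"{name} sums to {total}, expected 1")
            if any(v < 0 for v in mix.values()):
                raise ConfigurationError(f"{name} has a negative weight")


@dataclass
class TruthRecord:
    """Planted ground truth for one generated registration row."""

    row_index: int
    nct_id: str
    is_duplicate_row: bool
    in_cohort: bool
    cohort_rule: str
    category: str
    subtag: str
    needs_review: bool
    label: str
    rct_rule: str
    adversarial: bool
    template: str
    planted_cues: str


# ---------------------------------------------------------------------------
# Vocabulary (kept free of sex/gender and COVID terms except where planted)
# ---------------------------------------------------------------------------

COVID_PHRASES = [
    "COVID-19", "COVID19", "Covid-19", "SARS-CoV-2", "SARS CoV2", "SARSCoV2",
    "sars-cov-2", "2019-nCoV", "2019 nCov", "2019nCoV", "Coronavirus", "Corona Virus",
]
COVID_CONDITIONS = ["COVID-19", "SARS-CoV-2 Infection", "Coronavirus Disease 2019", "Covid19 Pneumonia"]
NONCOVID_CONDITIONS = ["Influenza", "Chronic Heart Failure", "Type 2 Diabetes", "Seasonal Allergic Rhinitis"]
NEUTRAL_CONDITIONS = ["Severe Acute Respiratory Infection", "Viral Pneumonia", "Acute Respiratory Distress Syndrome"]

DRUGS = ["remdesivir", "favipiravir", "hydroxychloroquine", "tocilizumab", "dexamethasone", "baricitinib"]
BIOLOGICALS = ["convalescent plasma", "BNT162b2 vaccine", "recombinant interferon beta"]
BEHAVIORAL = ["a structured telehealth counseling program", "a mindfulness based stress reduction course"]
DEVICES = ["a helmet based non invasive ventilation system", "a portable oxygen monitoring device"]

COUNTRIES = ["France", "United Kingdom", "Italy", "Spain", "Germany", "Denmark", "Brazil", "Netherlands"]
OK_STATUSES = ["Recruiting", "Not yet recruiting", "Active, not recruiting", "Completed", "Enrolling by invitation"]

FILLER_WORDS = (
    "the study team will collect routine clinical and laboratory data at each scheduled visit and "
    "monitor safety outcomes throughout the follow up period using standardised case forms"
).split()

ANALYSIS_SENTENCES = [
    ("Outcomes will be stratified by sex and age.", "analysis.stratified"),
    ("Sex sub group analyses will be performed for the primary endpoint.", "analysis.subgroup"),
    ("All primary analyses will be adjusted for age and sex.", "analysis.adjusted"),
    ("Sex will be included as a covariate in the regression models.", "analysis.covariate"),
    ("All results will be disaggregated by gender.", "analysis.disaggregated"),
    ("We hypothesize that sex will modify the treatment effect.", "analysis.hypothesis"),
    ("The model will test an interaction between treatment and sex.", "analysis.interaction"),
]
OTHER_MATCHED_SENTENCES = [
    ("Controls will be sex matched to cases.", "other.matched"),
    ("We aim for a sample that is representative of the population by sex and age.", "other.representative"),
    ("The cohort will be gender balanced across sites.", "other.balanced"),
]
OTHER_RECORD_SENTENCES = [
    ("The sex of all participants will be recorded at baseline.", "other.record"),
    ("Results will be reported by sex.", "other.report"),
]
RECRUITMENT_SENTENCES = [
    ("The study will enroll both men and women aged 18 to 80 years.", "recruitment.enrol"),
    ("Male and female patients are eligible for inclusion.", "recruitment.eligible"),
    ("We will recruit women and men from participating hospitals.", "recruitment.recruit"),
]
ELIGIBILITY_SEX_LINE = "- Male or female aged 18 years or older"

BASE_CRITERIA = (
    "Inclusion Criteria:\n"
    "{agedline}\n"
    "- Laboratory confirmed acute respiratory infection\n"
    "- Able to provide informed consent\n"
    "Exclusion Criteria:\n"
    "- Severe renal impairment\n"
    "- Participation in another interventional study"
)
AGED_LINE_PLAIN = "- Aged 18 years or older"

TRAP_SENTENCES = {
    "trap.contraception": (
        "- Women of childbearing potential must agree to use adequate contraception "
        "and have a negative pregnancy test"
    ),
    "trap.literature": "Previous studies have shown that male patients experience more severe outcomes.",
    "trap.donor": "Convalescent plasma will be obtained exclusively from male donors.",
    "trap.lit_analysis": "Previous studies have shown that outcomes stratified by sex differ between groups.",
    "trap.female_substring": "Female and male participants will be recruited at all participating sites.",
    "trap.uncodable": "Results will be presented separately for women and men.",
}
# truth for each trap: (category, subtag, expected needs_review)
TRAP_TRUTH = {
    "trap.contraception": (Category.NO_MENTION, Subtag.SPURIOUS_MENTION, False),
    "trap.literature": (Category.NO_MENTION, Subtag.SPURIOUS_MENTION, False),
    "trap.donor": (Category.NO_MENTION, Subtag.SPURIOUS_MENTION, False),
    "trap.lit_analysis": (Category.NO_MENTION, Subtag.SPURIOUS_MENTION, True),
    "trap.female_substring": (Category.RECRUITMENT_ONLY, None, False),
    "trap.uncodable": (Category.ANALYSIS, None, True),  # deliberately beyond the rule bank
}
# traps available per planted category, with weights within the category
TRAPS_BY_CATEGORY = {
    Category.NO_MENTION.value: (
        ["trap.contraception", "trap.literature", "trap.donor", "trap.lit_analysis"],
        [0.3, 0.25, 0.25, 0.2],
    ),
    Category.RECRUITMENT_ONLY.value: (["trap.female_substring"], [1.0]),
    Category.ANALYSIS.value: (["trap.uncodable"], [0.28]),  # rare: keeps adversarial recovery high
}


def _choice(rng: np.random.Generator, items: Sequence, p: Optional[Sequence[float]] = None):
    idx = rng.choice(len(items), p=np.asarray(p) / np.sum(p) if p is not None else None)
    return items[int(idx)]


def _lognormal(rng: np.random.Generator, median: float, sigma: float) -> int:
    return max(1, int(round(float(rng.lognormal(np.log(median), sigma)))))


def _pad_to_word_count(text: str, target: int) -> str:
    """Append neutral filler tokens until the text holds exactly ``target`` tokens."""
    tokens = text.split()
    if len(tokens) >= target:
        return text
    extra = [FILLER_WORDS[i % len(FILLER_WORDS)] for i in range(target - len(tokens))]
    return (text + " " + " ".join(extra)).strip() if text else " ".join(extra)


# ---------------------------------------------------------------------------
# Per-class structure templates
# ---------------------------------------------------------------------------


def _pharma_plan(rng: np.random.Generator) -> dict:
    iv_name = _choice(rng, DRUGS + BIOLOGICALS)
    iv_type = InterventionType.DRUG if iv_name in DRUGS else InterventionType.BIOLOGICAL
    variant = _choice(
        rng, ["group_type", "group_text", "title_text", "token_missing_alloc"], [0.60, 0.25, 0.12, 0.03]
    )
    experimental = StudyGroup(GroupType.EXPERIMENTAL, "Treatment", f"Participants receive {iv_name}.")
    plain_titles = [
        f"Safety and Efficacy of {iv_name} in Hospitalized Adults",
        f"A Phase 2 Study of {iv_name} for Severe Respiratory Infection",
        f"Evaluation of {iv_name} in Adults With Acute Respiratory Illness",
    ]
    text_titles = [
        f"A Randomized, Placebo Controlled Trial of {iv_name}",
        f"A Randomized Controlled Evaluation of {iv_name} in Outpatients",
        f"An RCT of {iv_name} in Hospitalized Adults",
    ]
    allocation = Allocation.RANDOMIZED
    if variant == "group_type":
        groups = [experimental, StudyGroup(GroupType.PLACEBO_COMPARATOR, "Placebo", "Participants receive matching placebo.")]
        title = _choice(rng, plain_titles + text_titles)
        rct_rule = RctRule.GROUP_TYPE_CONTROL
    elif variant == "group_text":
        groups = [
            experimental,
            StudyGroup(
                GroupType.ACTIVE_COMPARATOR,
                "Standard of care control",
                "Participants receive standard care and serve as the control arm.",
            ),
        ]
        title = _choice(rng, plain_titles)
        rct_rule = RctRule.GROUP_TEXT_CONTROL
    elif variant == "title_text":
        groups = [
            experimental,
            StudyGroup(GroupType.ACTIVE_COMPARATOR, "Standard care", "Participants receive standard supportive care."),
        ]
        title = _choice(rng, text_titles)
        rct_rule = RctRule.TITLE_OR_INTERVENTION_TEXT
    else:  # token_missing_alloc: the all-caps token supplies randomization evidence
        allocation = Allocation.MISSING
        groups = [experimental, StudyGroup(GroupType.PLACEBO_COMPARATOR, "Placebo", "Participants receive matching placebo.")]
        title = f"An RCT of {iv_name} in Hospitalized Adults"
        rct_rule = RctRule.GROUP_TYPE_CONTROL
    return {
        "study_type": StudyType.INTERVENTIONAL,
        "allocation": allocation,
        "groups": groups,
        "interventions": [Intervention(iv_type, f"Participants receive {iv_name} according to the dosing schedule.")],
        "title": title,
        "iv_name": iv_name,
        "rct_rule": rct_rule,
        "template": f"pharma.{variant}",
    }


def _other_intervention_plan(rng: np.random.Generator) -> dict:
    variant = _choice(
        rng,
        ["behavioral_randomized", "nonrandomized_drug", "single_arm_device", "randomized_dose_comparison"],
        [0.45, 0.30, 0.15, 0.10],
    )
    if variant == "behavioral_randomized":
        iv_name = _choice(rng, BEHAVIORAL)
        plan = {
            "allocation": Allocation.RANDOMIZED,
            "groups": [
                StudyGroup(GroupType.EXPERIMENTAL, "Intervention", f"Participants receive {iv_name}."),
                StudyGroup(GroupType.NO_INTERVENTION, "Usual care", "Participants continue usual care."),
            ],
            "interventions": [Intervention(InterventionType.BEHAVIORAL, f"Participants receive {iv_name}.")],
            "title": f"A Randomized Trial of {iv_name}",
        }
    elif variant == "nonrandomized_drug":
        iv_name = _choice(rng, DRUGS)
        plan = {
            "allocation": Allocation.NON_RANDOMIZED,
            "groups": [StudyGroup(GroupType.EXPERIMENTAL, "Treatment", f"Participants receive {iv_name}.")],
            "interventions": [Intervention(InterventionType.DRUG, f"Open label administration of {iv_name}.")],
            "title": f"An Open Label Study of {iv_name}",
        }
    elif variant == "single_arm_device":
        iv_name = _choice(rng, DEVICES)
        plan = {
            "allocation": Allocation.NA,
            "groups": [StudyGroup(GroupType.EXPERIMENTAL, "Device arm", f"All participants use {iv_name}.")],
            "interventions": [Intervention(InterventionType.DEVICE, f"All participants use {iv_name}.")],
            "title": f"A Single Arm Evaluation of {iv_name}",
        }
    else:  # randomized drug without any identifiable control arm
        iv_name = _choice(rng, DRUGS)
        plan = {
            "allocation": Allocation.RANDOMIZED,
            "groups": [
                StudyGroup(GroupType.EXPERIMENTAL, "Standard dose", f"Participants receive {iv_name} at the standard dose."),
                StudyGroup(GroupType.EXPERIMENTAL, "Reduced dose", f"Participants receive {iv_name} at a reduced dose."),
            ],
            "interventions": [Intervention(InterventionType.DRUG, f"Participants receive {iv_name}.")],
            "title": f"A Randomized Dose Comparison Study of {iv_name}",
        }
    plan.update(
        {
            "study_type": StudyType.INTERVENTIONAL,
            "iv_name": variant,
            "rct_rule": None,
            "template": f"other_intervention.{variant}",
        }
    )
    return plan


def _observational_plan(rng: np.random.Generator, registry: bool) -> dict:
    titles = (
        ["National Patient Registry of Acute Respiratory Infections", "Multicenter Registry of Hospitalized Patients"]
        if registry
        else [
            "Clinical Outcomes of Hospitalized Patients: a Prospective Cohort Study",
            "Impact of the Pandemic on Access to Routine Care",
            "Long Term Sequelae After Severe Respiratory Infection",
        ]
    )
    return {
        "study_type": StudyType.PATIENT_REGISTRY if registry else StudyType.OBSERVATIONAL,
        "allocation": Allocation.MISSING,
        "groups": [],
        "interventions": [],
        "title": _choice(rng, titles),
        "iv_name": "",
        "rct_rule": None,
        "template": "registry.base" if registry else "observational.base",
    }


def _expanded_access_plan(rng: np.random.Generator) -> dict:
    iv_name = _choice(rng, DRUGS)
    return {
        "study_type": StudyType.EXPANDED_ACCESS,
        "allocation": Allocation.MISSING,
        "groups": [],
        "interventions": [Intervention(InterventionType.DRUG, f"Expanded access administration of {iv_name}.")],
        "title": f"Expanded Access Program for {iv_name}",
        "iv_name": iv_name,
        "rct_rule": None,
        "template": "expanded_access.base",
    }


_PLAN_BUILDERS = {
    StudyLabel.PHARMA_RCT.value: lambda rng: _pharma_plan(rng),
    StudyLabel.OTHER_INTERVENTION.value: lambda rng: _other_intervention_plan(rng),
    StudyLabel.OBSERVATIONAL.value: lambda rng: _observational_plan(rng, registry=False),
    StudyLabel.PATIENT_REGISTRY.value: lambda rng: _observational_plan(rng, registry=True),
    StudyLabel.EXPANDED_ACCESS.value: lambda rng: _expanded_access_plan(rng),
}

_PHASES = [
    (Phase.EARLY_PHASE_1, 0.04), (Phase.PHASE_1, 0.12), (Phase.PHASE_1_2, 0.08),
    (Phase.PHASE_2, 0.28), (Phase.PHASE_2_3, 0.10), (Phase.PHASE_3, 0.32), (Phase.PHASE_4, 0.06),
]


def _sample_phase(rng: np.random.Generator, study_type: StudyType) -> Optional[Phase]:
    if study_type != StudyType.INTERVENTIONAL:
        return None
    u = rng.random()
    if u < 0.64:
        phases, weights = zip(*_PHASES)
        return _choice(rng, phases, weights)
    if u < 0.80:
        return Phase.NA
    return None


def _month_to_date(rng: np.random.Generator, month: str) -> date:
    year, mon = (int(x) for x in month.split("-"))
    return date(year, mon, 1 + int(rng.integers(0, 28)))


# ---------------------------------------------------------------------------
# Record assembly
# ---------------------------------------------------------------------------


def _build_record(rng: np.random.Generator, idx: int, spec: GeneratorSpec) -> tuple[TrialRegistration, TruthRecord]:
    nct_id = f"NCT{42000000 + idx:08d}"
    label = _choice(rng, list(spec.type_mix), list(spec.type_mix.values()))
    plan = _PLAN_BUILDERS[label](rng)
    covid_rule = _choice(rng, list(spec.covid_rule_mix), list(spec.covid_rule_mix.values()))
    category = _choice(rng, list(spec.category_mix), list(spec.category_mix.values()))

    # --- sex/gender content -------------------------------------------------
    trap: Optional[str] = None
    if category in TRAPS_BY_CATEGORY and rng.random() < spec.adversarial_rate:
        names, weights = TRAPS_BY_CATEGORY[category]
        # the Analysis trap is rare by design: its weight below 1 leaves the
        # remaining probability to the ordinary Analysis templates
        pick = rng.random()
        cum = 0.0
        for name, w in zip(names, weights):
            cum += w
            if pick < cum:
                trap = name
                break

    sexes = SexesEligible.ALL
    if category == Category.FEMALE_ONLY.value:
        sexes = SexesEligible.FEMALE
    elif category == Category.MALE_ONLY.value:
        sexes = SexesEligible.MALE
    elif rng.random() < spec.missing_sex_rate:
        sexes = SexesEligible.MISSING

    brief_extra: list[str] = []
    detailed_extra: list[str] = []
    aged_line = AGED_LINE_PLAIN
    criteria_extra: list[str] = []
    cues: list[str] = []
    subtag: Optional[Subtag] = None
    expected_review = sexes == SexesEligible.MISSING

    def place(sentence: str) -> None:
        (detailed_extra if rng.random() < 0.5 else brief_extra).append(sentence)

    if trap is not None:
        truth_cat, truth_subtag, trap_review = TRAP_TRUTH[trap]
        subtag = truth_subtag
        expected_review = expected_review or trap_review
        cues.append(trap)
        if trap == "trap.contraception":
            criteria_extra.append(TRAP_SENTENCES[trap])
        else:
            place(TRAP_SENTENCES[trap])
        category = truth_cat.value
    elif category == Category.FEMALE_ONLY.value:
        place("This study follows pregnant women during the third trimester.")
        aged_line = "- Pregnant women aged 18 to 45 years"
        cues.append("single_sex.female")
    elif category == Category.MALE_ONLY.value:
        place("The study population consists of adult men with confirmed infection.")
        aged_line = "- Men aged 18 years or older"
        cues.append("single_sex.male")
    elif category == Category.ANALYSIS.value:
        sentence, cue = _choice(rng, ANALYSIS_SENTENCES)
        place(sentence)
        cues.append(cue)
        if rng.random() < 0.5:  # compositional: hierarchy must still pick Analysis
            rec_sentence, rec_cue = _choice(rng, RECRUITMENT_SENTENCES)
            brief_extra.append(rec_sentence)
            cues.append(rec_cue)
    elif category == Category.OTHER_MENTION.value:
        pool = (
            OTHER_MATCHED_SENTENCES
            if rng.random() < spec.matched_share_of_other
            else OTHER_RECORD_SENTENCES
        )
        sentence, cue = _choice(rng, pool)
        place(sentence)
        cues.append(cue)
        subtag = (
            Subtag.MATCHED_OR_REPRESENTATIVE
            if pool is OTHER_MATCHED_SENTENCES
            else Subtag.RECORD_OR_REPORT
        )
        if rng.random() < 0.4:
            aged_line = ELIGIBILITY_SEX_LINE
            cues.append("recruitment.aged")
    elif category == Category.RECRUITMENT_ONLY.value:
        if rng.random() < spec.auto_recruitment_share:
            aged_line = ELIGIBILITY_SEX_LINE  # terms in the eligibility list and nowhere else
            subtag = Subtag.AUTO_ELIGIBILITY_ONLY
            cues.append("auto.eligibility_only")
        else:
            sentence, cue = _choice(rng, RECRUITMENT_SENTENCES)
            brief_extra.append(sentence)
            cues.append(cue)
            if rng.random() < 0.5:
                aged_line = ELIGIBILITY_SEX_LINE

    # --- COVID placement ----------------------------------------------------
    covid = _choice(rng, COVID_PHRASES)
    title = plan["title"]
    conditions = [_choice(rng, NEUTRAL_CONDITIONS)]
    primary = OutcomeRow("primary", "All cause mortality at day 28",
                         "Proportion of participants who die from any cause by day 28.")
    secondary = OutcomeRow("secondary", "Duration of hospital stay",
                           "Number of days from admission to discharge.")
    if covid_rule == CohortRule.TITLE_OR_CONDITION.value:
        placement = rng.random()
        if placement < 0.7:
            title = f"{title} in Patients With {covid}"
        if placement >= 0.3:
            conditions = [_choice(rng, COVID_CONDITIONS)]
    elif covid_rule == CohortRule.PRIMARY_OUTCOME.value:
        primary = OutcomeRow("primary", f"Time to {covid} viral clearance",
                             f"Days from enrollment to two consecutive negative {covid} tests.")
    elif covid_rule == CohortRule.TWO_OTHER_FIELDS.value:
        brief_extra.append(f"This study enrolls patients affected by the {covid} pandemic.")
        secondary = OutcomeRow("secondary", "Respiratory complications",
                               f"Incidence of complications related to {covid} infection.")
    elif covid_rule == "NonCovid":
        conditions = [_choice(rng, NONCOVID_CONDITIONS)]
        if rng.random() < 0.2:
            brief_extra.append("Patients will be monitored using Covidien ventilators.")  # substring trap

    # --- dates, status, enrollment -------------------------------------------
    submitted = _month_to_date(rng, _choice(rng, list(spec.date_weights), list(spec.date_weights.values())))
    start = submitted + timedelta(days=int(rng.integers(0, 45))) if rng.random() < spec.start_date_rate else None
    if plan["study_type"] == StudyType.EXPANDED_ACCESS:
        status = "Available"
    elif rng.random() < spec.withdrawn_rate:
        status = _choice(rng, ["Withdrawn", "No longer available"])
    else:
        status = _choice(rng, OK_STATUSES)

    if plan["study_type"] == StudyType.EXPANDED_ACCESS:
        enrollment, enrollment_type = None, EnrollmentType.MISSING
    else:
        median = spec.enrollment_medians.get(
            f"category:{category}", spec.enrollment_medians.get(f"label:{label}", 200)
        )
        enrollment = _lognormal(rng, median, spec.enrollment_sigma)
        enrollment_type = EnrollmentType.ANTICIPATED if rng.random() < 0.8 else EnrollmentType.ACTUAL

    # --- free text ------------------------------------------------------------
    brief_base = {
        StudyLabel.PHARMA_RCT.value: "This study evaluates an investigational treatment in hospitalized adults with severe respiratory illness.",
        StudyLabel.OTHER_INTERVENTION.value: "This study evaluates a supportive intervention in adults with acute respiratory illness.",
        StudyLabel.OBSERVATIONAL.value: "This observational study describes clinical outcomes among hospitalized adults.",
        StudyLabel.PATIENT_REGISTRY.value: "This registry collects routine clinical data from participating hospitals.",
        StudyLabel.EXPANDED_ACCESS.value: "This program provides access to an investigational treatment outside of ongoing trials.",
    }[label]
    brief = " ".join([brief_base] + brief_extra)
    detailed = ""
    if rng.random() < spec.detailed_description_rate:
        detailed = " ".join(
            [
                "Participants will be followed for 28 days after the first study visit.",
                "Clinical data will be abstracted from hospital charts at each visit.",
                "The primary analysis will use an intention to treat population.",
            ]
            + detailed_extra
        )
    else:
        brief = " ".join([brief] + detailed_extra)

    target_words = _lognormal(rng, spec.wordcount_medians.get(label, 200), spec.wordcount_sigma)
    composed = len(brief.split()) + len(detailed.split())
    if target_words > composed:
        if detailed:
            detailed = _pad_to_word_count(detailed, target_words - len(brief.split()))
        else:
            brief = _pad_to_word_count(brief, target_words)

    criteria = BASE_CRITERIA.format(agedline=aged_line)
    if criteria_extra:
        criteria = criteria + "\n" + "\n".join(criteria_extra)

    facilities: list[str] = []
    if rng.random() < spec.facility_rate:
        n_fac = 1 + int(rng.integers(0, 3))
        facilities = [str(_choice(rng, COUNTRIES)) for _ in range(n_fac)]
        if rng.random() < spec.us_rate:
            facilities[0] = "United States"

    outcomes = [primary, secondary]
    groups = plan["groups"]
    interventions = plan["interventions"]
    texts = assemble_texts(
        official_title=title,
        brief_title=title,
        brief_summary=brief,
        detailed_description=detailed,
        conditions=conditions,
        outcomes=outcomes,
        population="Hospitalized adults with acute respiratory symptoms" if rng.random() < 0.5 else "",
        gender_description="",
        criteria=criteria,
        groups=groups,
        interventions=interventions,
    )
    registration = TrialRegistration(
        nct_id=nct_id,
        study_type=plan["study_type"],
        allocation=plan["allocation"],
        phase=_sample_phase(rng, plan["study_type"]),
        sexes_eligible=sexes,
        status=status,
        start_date=start,
        submitted_date=submitted,
        enrollment_count=enrollment,
        enrollment_type=enrollment_type,
        texts=texts,
        groups=groups,
        interventions=interventions,
        outcomes=outcomes,
        facility_countries=facilities,
        has_document=rng.random() < spec.document_rate,
    )

    # --- planted truth --------------------------------------------------------
    effective = start if start is not None else submitted
    if not (WINDOW_START <= effective <= WINDOW_END):
        in_cohort, rule = False, CohortRule.OUT_OF_WINDOW.value
    elif status.lower() in BAD_STATUSES:
        in_cohort, rule = False, CohortRule.BAD_STATUS.value
    elif covid_rule == "NonCovid":
        in_cohort, rule = False, CohortRule.NOT_MATCHED.value
    else:
        in_cohort, rule = True, covid_rule

    truth = TruthRecord(
        row_index=idx,
        nct_id=nct_id,
        is_duplicate_row=False,
        in_cohort=in_cohort,
        cohort_rule=rule,
        category=category,
        subtag=subtag.value if subtag else "",
        needs_review=expected_review,
        label=label,
        rct_rule=plan["rct_rule"].value if plan["rct_rule"] else "",
        adversarial=trap is not None,
        template=plan["template"] + ("+" + trap if trap else ""),
        planted_cues=";".join(cues),
    )
    return registration, truth


def generate_registrations(spec: GeneratorSpec) -> tuple[list[TrialRegistration], list[TruthRecord]]:
    """Generate registrations plus one TruthRecord per row, deterministically."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    registrations: list[TrialRegistration] = []
    truths: list[TruthRecord] = []
    for idx in range(spec.n_studies):
        reg, truth = _build_record(rng, idx, spec)
        registrations.append(reg)
        truths.append(truth)
    # plant duplicate rows: each replaces a slot with a copy of an earlier record
    n_dup = int(round(spec.duplicate_rate * spec.n_studies))
    if n_dup and spec.n_studies > 1:
        slots = rng.choice(np.arange(1, spec.n_studies), size=min(n_dup, spec.n_studies - 1), replace=False)
        for slot in sorted(int(s) for s in slots):
            source = int(rng.integers(0, slot))
            registrations[slot] = registrations[source]
            truths[slot] = TruthRecord(
                row_index=slot,
                nct_id=registrations[source].nct_id,
                is_duplicate_row=True,
                in_cohort=False,
                cohort_rule=CohortRule.DUPLICATE.value,
                category="",
                subtag="",
                needs_review=False,
                label="",
                rct_rule="",
                adversarial=False,
                template="duplicate",
                planted_cues="",
            )
    return registrations, truths


def write_truth_csv(truths: Sequence[TruthRecord], path: Union[str, Path]) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    names = [f.name for f in dc_fields(TruthRecord)]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(names)
        for t in truths:
            writer.writerow([getattr(t, n) for n in names])
    return path


def read_truth_csv(path: Union[str, Path]) -> list[TruthRecord]:
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.DictReader(fh))
    out = []
    for r in rows:
        out.append(
            TruthRecord(
                row_index=int(r["row_index"]),
                nct_id=r["nct_id"],
                is_duplicate_row=r["is_duplicate_row"] == "True",
                in_cohort=r["in_cohort"] == "True",
                cohort_rule=r["cohort_rule"],
                category=r["category"],
                subtag=r["subtag"],
                needs_review=r["needs_review"] == "True",
                label=r["label"],
                rct_rule=r["rct_rule"],
                adversarial=r["adversarial"] == "True",
                template=r["template"],
                planted_cues=r["planted_cues"],
            )
        )
    return out


def generate_dump(spec: GeneratorSpec, out_dir: Union[str, Path]) -> dict:
    """Write a dump in both dialects plus the truth table; returns the path map."""
    out_dir = Path(out_dir)
    registrations, truths = generate_registrations(spec)
    paths = write_dump_csv(registrations, out_dir / "csv")
    paths["registrations"] = write_registrations_jsonl(registrations, out_dir / "registrations.jsonl")
    paths["truth"] = write_truth_csv(truths, out_dir / "truth.csv")
    return paths
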