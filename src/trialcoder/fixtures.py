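"""Curated, versioned edge-case registrations with expected assignments.

A fixed set of hand-written synthetic registrations, one per documented edge
case of the screening and coding rules: every rule id in the shipped rule
bank is exercised by at least one fixture, including the spurious-mention
traps (contraception clauses, pregnancy tests, donor/parent sex, literature
summaries), the "female"-contains-"male" substring trap, hyphen/case COVID
term variants, eligibility-only recruitment mentions, and phrasings the rule
bank deliberately escalates to human review.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Optional

from .cohort_selection import CohortRule
from .registry_io import (
    Allocation,
    OutcomeRow,
    SexesEligible,
    StudyType,
    TrialRegistration,
    assemble_texts,
    parse_sexes_eligible,
)
from .sexgender_coding import Category, Subtag

_BASE_CRITERIA = (
    "Inclusion Criteria:\n- Aged 18 years or older\n- Confirmed acute respiratory infection\n"
    "Exclusion Criteria:\n- Severe hepatic impairment"
)


@dataclass
class Fixture:
    """One hand-written registration with its expected pipeline verdicts."""

    name: str
    registration: TrialRegistration
    category: Category
    subtag: Optional[Subtag] = None
    needs_review: bool = False
    in_cohort: bool = True
    cohort_rule: CohortRule = CohortRule.TITLE_OR_CONDITION
    must_fire: tuple = ()  # rule ids that must appear in fired_rules


def make_registration(
    nct_id: str,
    *,
    brief_title: str = "A Study of Supportive Care in Hospitalized Adults",
    brief_summary: str = "",
    detailed_description: str = "",
    conditions: tuple = ("COVID-19",),
    criteria: str = _BASE_CRITERIA,
    sexes: str = "All",
    outcomes: tuple = (),
    study_type: StudyType = StudyType.OBSERVATIONAL,
    submitted: date = date(2020, 6, 15),
    status: str = "Recruiting",
) -> TrialRegistration:
    outcome_rows = list(outcomes) or [
        OutcomeRow("primary", "All cause mortality at day 28", "Proportion who die by day 28.")
    ]
    texts = assemble_texts(
        official_title=brief_title,
        brief_title=brief_title,
        brief_summary=brief_summary,
        detailed_description=detailed_description,
        conditions=conditions,
        outcomes=outcome_rows,
        criteria=criteria,
    )
    return TrialRegistration(
        nct_id=nct_id,
        study_type=study_type,
        allocation=Allocation.MISSING,
        sexes_eligible=parse_sexes_eligible(sexes),
        status=status,
        submitted_date=submitted,
        texts=texts,
        outcomes=outcome_rows,
    )


def adversarial_fixtures() -> list[Fixture]:
    """The versioned fixture set; ids are stable across releases."""
    fx: list[Fixture] = []
    n = iter(range(1, 100))

    def make(name: str, *, category, subtag=None, needs_review=False, in_cohort=True,
             cohort_rule=CohortRule.TITLE_OR_CONDITION, must_fire=(), **kw) -> None:
        reg = make_registration(f"NCT9{next(n):07d}", **kw)
        fx.append(Fixture(name, reg, category, subtag, needs_review, in_cohort, cohort_rule, tuple(must_fire)))

    # --- analysis cues, one per rule ---------------------------------------
    make("analysis_stratified", brief_summary="Outcomes will be stratified by sex and age.",
         category=Category.ANALYSIS, must_fire=["analysis.stratified"])
    make("analysis_subgroup", detailed_description="Sex sub-group analyses will be performed.",
         category=Category.ANALYSIS, must_fire=["analysis.subgroup"])
    make("analysis_covariate", detailed_description="Sex will be included as a covariate in all models.",
         category=Category.ANALYSIS, must_fire=["analysis.covariate"])
    make("analysis_adjusted", detailed_description="All analyses will be adjusted for age and sex.",
         category=Category.ANALYSIS, must_fire=["analysis.adjusted"])
    make("analysis_disaggregated", brief_summary="Results will be disaggregated by gender.",
         category=Category.ANALYSIS, must_fire=["analysis.disaggregated"])
    make("analysis_hypothesis", detailed_description="We hypothesize that outcomes differ by sex.",
         category=Category.ANALYSIS, must_fire=["analysis.hypothesis"])
    make("analysis_interaction", detailed_description="We will test a treatment by sex interaction.",
         category=Category.ANALYSIS, must_fire=["analysis.interaction"])
    make("analysis_beats_recruitment",
         brief_summary="The study will enroll both men and women aged 18 to 80 years.",
         detailed_description="Outcomes will be stratified by sex.",
         category=Category.ANALYSIS, must_fire=["analysis.stratified", "recruitment.enrol"])

    # --- other mentions ------------------------------------------------------
    make("other_matched", detailed_description="Controls will be sex-matched to cases.",
         category=Category.OTHER_MENTION, subtag=Subtag.MATCHED_OR_REPRESENTATIVE,
         must_fire=["other.matched"])
    make("other_representative",
         detailed_description="The sample will be representative of the population by sex.",
         category=Category.OTHER_MENTION, subtag=Subtag.MATCHED_OR_REPRESENTATIVE,
         must_fire=["other.representative"])
    make("other_balanced", brief_summary="We aim for a gender-balanced cohort across sites.",
         category=Category.OTHER_MENTION, subtag=Subtag.MATCHED_OR_REPRESENTATIVE,
         must_fire=["other.balanced"])
    make("other_record", detailed_description="The sex of every participant will be recorded.",
         category=Category.OTHER_MENTION, subtag=Subtag.RECORD_OR_REPORT, must_fire=["other.record"])
    make("other_report", detailed_description="Results will be reported by sex.",
         category=Category.OTHER_MENTION, subtag=Subtag.RECORD_OR_REPORT, must_fire=["other.report"])

    # --- recruitment statements ---------------------------------------------
    make("recruitment_enrol", brief_summary="The study will enroll both men and women.",
         category=Category.RECRUITMENT_ONLY, must_fire=["recruitment.enrol", "recruitment.both_sexes_phrase"])
    make("recruitment_recruit", brief_summary="We will recruit women and men from twelve hospitals.",
         category=Category.RECRUITMENT_ONLY, must_fire=["recruitment.recruit"])
    make("recruitment_eligible", brief_summary="Male and female patients are eligible.",
         category=Category.RECRUITMENT_ONLY, must_fire=["recruitment.eligible"])
    make("recruitment_inclusion",
         brief_summary="Inclusion of both male and female participants is planned.",
         category=Category.RECRUITMENT_ONLY, must_fire=["recruitment.inclusion"])
    make("recruitment_auto_eligibility",
         criteria="Inclusion Criteria:\n- Male or female aged 18 years or older\n"
                  "Exclusion Criteria:\n- Severe hepatic impairment",
         category=Category.RECRUITMENT_ONLY, subtag=Subtag.AUTO_ELIGIBILITY_ONLY,
         must_fire=["auto.eligibility_only", "recruitment.aged"])
    make("recruitment_one_sided_review",
         brief_summary="Women will be recruited at two participating sites.",
         category=Category.NO_MENTION, needs_review=True)

    # --- spurious mentions ---------------------------------------------------
    make("spurious_contraception",
         criteria=_BASE_CRITERIA + "\n- Women of childbearing potential must use adequate contraception",
         category=Category.NO_MENTION, subtag=Subtag.SPURIOUS_MENTION,
         must_fire=["spurious.contraception"])
    make("spurious_pregnancy_test",
         criteria=_BASE_CRITERIA + "\n- A negative pregnancy test is mandatory for women at screening",
         category=Category.NO_MENTION, subtag=Subtag.SPURIOUS_MENTION,
         must_fire=["spurious.pregnancy_test"])
    make("spurious_donor", brief_summary="Convalescent plasma from male donors will be administered.",
         category=Category.NO_MENTION, subtag=Subtag.SPURIOUS_MENTION, must_fire=["spurious.donor"])
    make("spurious_parent", detailed_description="The sex of the parents will not be considered.",
         category=Category.NO_MENTION, subtag=Subtag.SPURIOUS_MENTION, must_fire=["spurious.parent"])
    make("spurious_literature",
         detailed_description="Previous studies have shown that men experience higher mortality.",
         category=Category.NO_MENTION, subtag=Subtag.SPURIOUS_MENTION, must_fire=["spurious.literature"])
    make("literature_analysis_review",
         detailed_description="Previous studies have shown that outcomes stratified by sex differ.",
         category=Category.NO_MENTION, subtag=Subtag.SPURIOUS_MENTION, needs_review=True,
         must_fire=["spurious.literature"])

    # --- single-sex designs ----------------------------------------------------
    make("single_sex_female", sexes="Female",
         brief_summary="This study follows pregnant women during the third trimester.",
         category=Category.FEMALE_ONLY, must_fire=["single_sex.female"])
    make("single_sex_male", sexes="MALE",
         brief_summary="The study population consists of adult men.",
         category=Category.MALE_ONLY, must_fire=["single_sex.male"])

    # --- matcher traps and review escalations ----------------------------------
    make("female_substring_trap",
         brief_summary="Female and male participants will be recruited at all sites.",
         category=Category.RECRUITMENT_ONLY, must_fire=["recruitment.recruit"])
    make("uncodable_mention_review",
         detailed_description="Results will be presented separately for women and men.",
         category=Category.NO_MENTION, needs_review=True)
    make("demographics_not_analysis",
         brief_summary="Male and female patients are eligible.",
         detailed_description="Demographic variables will be included as covariates.",
         category=Category.RECRUITMENT_ONLY, must_fire=["recruitment.eligible"])

    # --- cohort-rule edge cases -------------------------------------------------
    make("covid_nospace_title", brief_title="Efficacy of Remdesivir in SARSCoV2 Infection",
         conditions=("Viral Pneumonia",), category=Category.NO_MENTION,
         cohort_rule=CohortRule.TITLE_OR_CONDITION)
    make("covid_hyphen_condition", conditions=("sars cov-2 infection",),
         category=Category.NO_MENTION, cohort_rule=CohortRule.TITLE_OR_CONDITION)
    make("covid_substring_not_matched", brief_title="Covidien Device Registry",
         conditions=("Influenza",), category=Category.NO_MENTION,
         in_cohort=False, cohort_rule=CohortRule.NOT_MATCHED)
    make("covid_primary_outcome_only", conditions=("Viral Pneumonia",),
         outcomes=(OutcomeRow("primary", "Time to COVID-19 viral clearance", "Days to clearance."),),
         category=Category.NO_MENTION, cohort_rule=CohortRule.PRIMARY_OUTCOME)
    make("covid_two_other_fields", conditions=("Viral Pneumonia",),
         brief_summary="This study enrolls patients affected by the covid 19 pandemic.",
         outcomes=(OutcomeRow("primary", "All cause mortality", "Death from any cause."),
                   OutcomeRow("secondary", "Complications", "Incidence of 2019-nCoV related complications.")),
         category=Category.NO_MENTION, cohort_rule=CohortRule.TWO_OTHER_FIELDS)
    make("covid_one_other_field_not_matched", conditions=("Viral Pneumonia",),
         outcomes=(OutcomeRow("primary", "All cause mortality", "Death from any cause."),
                   OutcomeRow("secondary", "Complications", "Incidence of COVID-19 related complications.")),
         category=Category.NO_MENTION, in_cohort=False, cohort_rule=CohortRule.NOT_MATCHED)

    return fx
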