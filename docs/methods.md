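# Methods

`trialcoder` re-implements, as auditable rules, a registry-screening
procedure for measuring how much attention clinical-study registrations pay
to participant sex and gender. It operates on ClinicalTrials.gov-style
records (AACT-dialect relational tables or JSON lines), and ships a
synthetic-registry generator so the entire procedure can be validated
against known ground truth without downloading registry data.

## The screening and coding procedure

### Term matching

All searches share one matching engine. A term list (shipped as editable
YAML) is expanded into patterns:

* plural expansion adds regular `+s`/`+es` variants, consonant-`y` → `ies`,
  and the irregular pairs *man/men* and *woman/women*;
* a trailing asterisk (`pregnan*`, `transg*`) marks a wildcard stem that
  greedily absorbs trailing letters;
* matching is case-insensitive, and any internal hyphen or space of a
  multi-token term matches zero or one of {hyphen, space} in the text, so
  `SARS-CoV-2` hits `SARS CoV2`, `SARSCoV2` and `sars-cov-2` alike;
* a non-wildcard match is rejected when immediately preceded or followed by
  a letter. Digits and punctuation are permitted neighbours. This single
  rule lets `COVID` hit `COVID-19`/`COVID19` while blocking `male` inside
  `female` — both behaviours the screening requires. Wildcard matches are
  subject only to the left-neighbour rule.

Typographic hyphen variants (en/em dash, non-breaking hyphen, minus) and
non-breaking spaces are normalised to their ASCII forms before matching;
the mapping is length-preserving so evidence offsets index the original
text. Token boundaries are nowhere defined in registry text, so the
letter-neighbour rule is this package's own convention; its consequences
are pinned down by a brute-force-scanner equivalence test.

### Cohort selection

COVID-19 terms (`Coronavirus`, `Corona Virus`, `SARS-CoV-2`, `SARS CoV2`,
`SARSCoV2`, `COVID`, `2019 nCov`, `2019nCoV`) are searched in titles, brief
summary, detailed description, conditions and outcome titles/descriptions.
A registration is included when a term occurs in its titles or conditions;
failing that, in a primary outcome measure; failing that, in at least two
*distinct* other in-scope fields (brief summary, detailed description, or a
non-primary outcome). Counting distinct fields — not occurrences — is the
package's reading of "at least two other relevant fields".

Records are kept when their start date (falling back to the first-submitted
date when no start date exists) lies in the inclusive window 1 Jan 2020 –
26 Jan 2021, and their status is not `Withdrawn` or `No longer available`.
Repeated registry ids keep the first record; registrations sharing a
normalised title pair are only *flagged* as candidate duplicates, because
the registry id is the only duplicate criterion we can apply mechanically.

### Sex/gender attention coding

Coding is hierarchical and mutually exclusive. Single-sex designs are set
aside first from the structured eligible-sexes field (`Female` → FemaleOnly,
`Male` → MaleOnly; a missing value flags the study for review). For studies
open to all sexes, the terms `sex, gender, woman, female, man, male, girl,
boy` (and plurals) plus `pregnan*` and `transg*` are searched in titles,
summaries, eligibilities (population, gender description, inclusion
criteria), group titles/descriptions, intervention descriptions and
outcomes. Conditions are deliberately not in this scope.

Each occurrence is judged inside a context window — the containing sentence
(boundaries `.!?;` and newline), clamped to ±120 characters when sentence
bounds are unclear — against a rule bank shipped as YAML:

* **spurious** (negative, evaluated first): contraception requirements,
  pregnancy tests, donor or parent sex, and literature/background phrasing
  ("previous studies", "has been shown"). A window holding a spurious cue
  contributes no positive evidence.
* **analysis**: stratification, subgroup analyses, covariates, interaction
  terms, adjustment, disaggregation, or a stated hypothesis — all inside a
  window that contains a sex/gender term, which is why "demographic
  variables will be analysed" alone can never yield the Analysis category.
* **other mention**: matching/representative/balanced-sample intent
  (subtag `MatchedOrRepresentative`) or record/report intent
  (`RecordOrReport`; matching precedes reporting when both fire).
* **recruitment**: enrol*/recruit*/eligib*/inclusion/aged cues. A
  recruitment statement only counts when its contexts cover both sexes —
  a female-class and a male-class term together, a neutral term (sex,
  gender), or an explicit both-sexes phrase. The phrase alone supplies
  coverage, never candidacy.

Category precedence is FemaleOnly/MaleOnly ≻ Analysis ≻ OtherMention ≻
RecruitmentOnly ≻ NoMention. RecruitmentOnly is also reached automatically
when every non-spurious occurrence sits in the eligibility inclusion-criteria
list (subtag `AutoEligibilityOnly`), mirroring the registry reality that
such studies can only be recruitment mentions. Unlike the original manual
workflow, spurious filtering runs *before* the automatic rule, so a
contraception clause that is the only sex mention codes as
NoMention/SpuriousMention rather than inflating the recruitment category;
this is a deliberate refinement and is pinned by a fixture.

The `needs_review` flag is the machine analogue of escalation to a human
coder: it is set when occurrences survive spurious filtering but no positive
rule fires, when an analysis-style cue appears only inside a
literature/background context, or when the eligible-sexes field is missing.
The original categories (a)/(b) were human judgments; this rule bank is an
explicit, editable approximation of the stated criteria, not a claim to
replicate coder judgment — ambiguity is routed to the review queue instead.

### Pharmacological-RCT identification

Expanded-access, patient-registry and observational records pass through
from study type (the registry flags patient registries on observational
records; the loader resolves that flag into a disjoint five-way type).
An interventional study is a pharmacological RCT when it has randomized
allocation, at least one drug or biological/vaccine intervention, and an
identifiable control arm, tried in fixed precedence: a group typed
placebo/sham comparator or no-intervention (`GroupTypeControl`); a group
title/description matching `control*`/`placebo*` (`GroupTextControl`);
or titles/intervention descriptions containing the all-caps token `RCT`,
or `random*` together with `control*`/`placebo*` anywhere in those fields
(`TitleOrInterventionText`). The registration-level reading of the
random+control fallback is a choice — the source procedure states no
proximity constraint. `RCT` is matched case-sensitively to avoid substring
hits, and a missing allocation counts as randomized only when the text
itself supplies `random*` or the `RCT` token (the token abbreviates
"randomized controlled trial", so it is taken as evidence of both).

### Summaries

Percentages are computed at stated precision with half-up rounding — the
convention under which every printed (count, denominator, percentage)
triple of the emulated audit reproduces exactly. Every emitted table passes
a self-consistency audit (each percentage equals `percentage()` of its own
count and denominator). Medians use the even-size mean-of-central-values
convention; missing enrollment counts are excluded. Monthly series bin by
the first-submitted date (not the effective date used for windowing) with
zero-filled empty months. The geography bucket "US facility" means at least
one facility country equals "United States".

## The synthetic generator

Each record composes independent template layers: a study-class plan
(structure, groups, interventions, titles), a COVID-placement plan (which
fields carry a randomly styled COVID term — hyphen/case variants included),
a sex/gender category template, and neutral filler padding the description
to a target word count. Because layers are compositional, hierarchy
precedence is testable by construction (e.g. an Analysis record can also
carry a recruitment sentence).

Defaults are the emulated study conditions: category shares
2.3/0.5/4.0/5.4/21.2/66.7% (FemaleOnly/MaleOnly/Analysis/OtherMention/
RecruitmentOnly/NoMention), study types 1659:1314:1161:260:26 rescaled,
COVID placement 93:1:1 across the three inclusion rules plus 5% non-COVID
noise (so title/condition placement is ~98% of COVID records), log-normal
enrollment with dispersion 1.0 on the log scale and medians 700 (Analysis)
and 176 (NoMention) by category, 287/400/160/100 by class otherwise,
log-normal word counts (σ=0.35) with medians 245/260/214 by class, monthly
submission weights putting 56% of in-window mass in H1 2020 with a late
spring peak and 4% out-of-window tails, 1% duplicate rows, 1.5% withdrawn
statuses, 85% start-date availability, 70.1% detailed descriptions, 89%
facility information with 22.7% US presence, and 3% attached documents.
Where the emulated audit gives both per-category and per-class enrollment
medians, they cannot hold simultaneously under one simple model; the
category targets win for Analysis and NoMention since those are the
quantities checked downstream.

15% of records in categories with trap variants are adversarial:
contraception clauses, literature summaries, donor-sex mentions, a
literature sentence carrying an analysis cue (expected: spurious plus a
review flag), a "Female and male…" matcher trap, and one deliberately
uncodable Analysis phrasing ("presented separately for women and men",
weight 28% of adversarial Analysis draws) that the rule bank cannot and
should not match — it is the planned honest miss, and it must always arrive
flagged for review. Adversarial recovery is therefore by design below 100%
but far above the 90% floor.

What the generator does **not** emulate: natural-language variety beyond
rule-triggering templates, misspellings, non-English text, multi-sentence
discourse structure, or attached PDF documents. Passing recovery tests
therefore shows that the pipeline implements its stated rules exactly — not
that the rules capture every phrasing in real registry text; on real data
the review queue and the editable rule bank carry that residual.

## Numerical and procedural choices

* Rounding: half-up via `decimal`, never float rounding.
* Child-table text is newline-joined per field; newline is not a permitted
  in-term separator, so terms never match across child rows, and child-row
  order cannot change any verdict.
* Window endpoints are inclusive; the upper endpoint is the snapshot date.
* Ties/degenerate inputs: empty cohorts yield all-zero tables; zero
  denominators and empty median selections raise typed errors.
* Problem sizes: module tests run a 300-record dump; the recovery check
  runs 1000 records (seconds on one core); distribution-fidelity checks run
  2000; the demo analysis in `analysis/` runs the full emulated scale of
  4420. Enrollment-median measurements in the acceptance script use
  dedicated 600-record single-category runs, which estimates the planted
  median with ~5% standard error instead of the much noisier estimate a
  4%-share category would give at mixed composition.
* The H1-2020 submission share measured over the *cohort* (~57–59%) sits
  slightly above the planted in-window share (56%) because effective-date
  windowing trims submissions near the right window edge; this is a
  property of the windowing rule, not a calibration error.

## Known limitations

* The rule bank encodes stated criteria plus obvious cue synonyms; real
  coder judgment was richer. Precision/recall on real registry text is
  unknown and unknowable from synthetic data alone.
* Duplicate detection beyond registry-id identity only flags candidates.
* The publication-screening stage of the emulated audit is out of scope;
  its printed counts enter only as inputs to the percentage arithmetic.
* Supporting-document PDFs are carried as a boolean flag, never parsed.
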