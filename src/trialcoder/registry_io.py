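"""Readers, writers and the in-memory model for trial-registry dumps.

A *registration* is one ClinicalTrials.gov-style protocol record: structured
design metadata (study type, allocation, eligible sexes, dates, enrollment)
plus the free-text fields that downstream term searches target. Two dump
dialects are supported:

``aact_csv``
    A directory of RFC-4180 comma-separated tables using AACT
    (Aggregate Analysis of ClinicalTrials.gov) column names. The ``studies``
    table is mandatory; child tables (conditions, outcomes, eligibilities,
    design groups, designs, interventions, facilities, documents) are
    optional and aggregated per study.

``jsonl``
    One JSON object per line, one registration per object — the native
    format of the synthetic generator and of this module's writer.

Multi-row child text (several conditions, several outcomes of one type) is
joined with a newline separator into a single text per field, which keeps
term adjacency within a row while preserving the per-field search scopes.
Outcome rows are additionally retained per row so primary-outcome rules can
be audited per outcome.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field, replace
from datetime import date
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

from .errors import ConfigurationError

log = logging.getLogger(__name__)

CHILD_TEXT_SEPARATOR = "\n"


class StudyType(str, Enum):
    INTERVENTIONAL = "Interventional"
    OBSERVATIONAL = "Observational"
    PATIENT_REGISTRY = "PatientRegistry"
    EXPANDED_ACCESS = "ExpandedAccess"


class Allocation(str, Enum):
    RANDOMIZED = "Randomized"
    NON_RANDOMIZED = "NonRandomized"
    NA = "NA"
    MISSING = "Missing"


class Phase(str, Enum):
    EARLY_PHASE_1 = "EarlyPhase1"
    PHASE_1 = "Phase1"
    PHASE_1_2 = "Phase1_2"
    PHASE_2 = "Phase2"
    PHASE_2_3 = "Phase2_3"
    PHASE_3 = "Phase3"
    PHASE_4 = "Phase4"
    NA = "NA"


class SexesEligible(str, Enum):
    ALL = "All"
    MALE = "Male"
    FEMALE = "Female"
    MISSING = "Missing"


class EnrollmentType(str, Enum):
    ANTICIPATED = "Anticipated"
    ACTUAL = "Actual"
    MISSING = "Missing"


class GroupType(str, Enum):
    EXPERIMENTAL = "Experimental"
    ACTIVE_COMPARATOR = "ActiveComparator"
    PLACEBO_COMPARATOR = "PlaceboComparator"
    SHAM_COMPARATOR = "ShamComparator"
    NO_INTERVENTION = "NoIntervention"
    OTHER = "Other"
    MISSING = "Missing"


class InterventionType(str, Enum):
    DRUG = "Drug"
    BIOLOGICAL = "Biological"
    BEHAVIORAL = "Behavioral"
    DEVICE = "Device"
    PROCEDURE = "Procedure"
    DIAGNOSTIC_TEST = "DiagnosticTest"
    DIETARY_SUPPLEMENT = "DietarySupplement"
    RADIATION = "Radiation"
    COMBINATION_PRODUCT = "CombinationProduct"
    GENETIC = "Genetic"
    OTHER = "Other"


class FieldName(str, Enum):
    """Catalogue of searchable free-text fields of a registration."""

    OFFICIAL_TITLE = "OfficialTitle"
    BRIEF_TITLE = "BriefTitle"
    BRIEF_SUMMARY = "BriefSummary"
    DETAILED_DESCRIPTION = "DetailedDescription"
    CONDITIONS = "Conditions"
    PRIMARY_OUTCOME_TITLE = "PrimaryOutcomeTitle"
    PRIMARY_OUTCOME_DESCRIPTION = "PrimaryOutcomeDescription"
    SECONDARY_OUTCOME_TITLE = "SecondaryOutcomeTitle"
    SECONDARY_OUTCOME_DESCRIPTION = "SecondaryOutcomeDescription"
    OTHER_OUTCOME_TITLE = "OtherOutcomeTitle"
    OTHER_OUTCOME_DESCRIPTION = "OtherOutcomeDescription"
    ELIGIBILITY_POPULATION = "EligibilityPopulation"
    ELIGIBILITY_GENDER_DESCRIPTION = "EligibilityGenderDescription"
    ELIGIBILITY_CRITERIA = "EligibilityCriteria"
    GROUP_TITLE = "GroupTitle"
    GROUP_DESCRIPTION = "GroupDescription"
    INTERVENTION_DESCRIPTION = "InterventionDescription"


FIELD_ORDER = {f: i for i, f in enumerate(FieldName)}


@dataclass(frozen=True)
class StudyGroup:
    group_type: GroupType
    title: str = ""
    description: str = ""


@dataclass(frozen=True)
class Intervention:
    intervention_type: InterventionType
    description: str = ""


@dataclass(frozen=True)
class OutcomeRow:
    outcome_type: str  # "primary" | "secondary" | "other"
    title: str = ""
    description: str = ""


@dataclass
class TrialRegistration:
    """One registry record with all fields the rule-based searches target."""

    nct_id: str
    study_type: StudyType
    allocation: Allocation = Allocation.MISSING
    phase: Optional[Phase] = None
    sexes_eligible: SexesEligible = SexesEligible.MISSING
    status: str = ""
    start_date: Optional[date] = None
    submitted_date: date = date(2020, 1, 1)
    enrollment_count: Optional[int] = None
    enrollment_type: EnrollmentType = EnrollmentType.MISSING
    texts: dict = field(default_factory=dict)
    groups: list = field(default_factory=list)
    interventions: list = field(default_factory=list)
    outcomes: list = field(default_factory=list)
    facility_countries: list = field(default_factory=list)
    has_document: bool = False

    def __post_init__(self) -> None:
        full = {f: "" for f in FieldName}
        for k, v in self.texts.items():
            full[FieldName(k)] = v or ""
        self.texts = full
        if self.enrollment_count is None:
            self.enrollment_type = EnrollmentType.MISSING
        elif self.enrollment_count < 0:
            raise ValueError(f"negative enrollment for {self.nct_id}")

    def text(self, name: FieldName) -> str:
        return self.texts.get(name, "")

    @property
    def effective_date(self) -> date:
        """Start date when available, else the first-submitted date."""
        return self.start_date if self.start_date is not None else self.submitted_date


def parse_sexes_eligible(raw: Optional[str]) -> SexesEligible:
    """Map the registry's eligible-sexes field ('All'/'Male'/'Female') to the enum.

    Total function: case-insensitive on the three registry values, anything
    else (including empty) maps to ``Missing``.
    """
    value = (raw or "").strip().lower()
    return {
        "all": SexesEligible.ALL,
        "male": SexesEligible.MALE,
        "female": SexesEligible.FEMALE,
    }.get(value, SexesEligible.MISSING)


def parse_date(raw: Optional[str]) -> Optional[date]:
    """Parse ISO 'YYYY-MM-DD' or month-precision 'YYYY-MM' (-> first of month)."""
    value = (raw or "").strip()
    if not value:
        return None
    parts = value.split("-")
    if len(parts) == 2:
        return date(int(parts[0]), int(parts[1]), 1)
    return date.fromisoformat(value)


def word_count(registration: TrialRegistration) -> int:
    """Whitespace-token count across the brief-summary and detailed-description fields."""
    return len(registration.text(FieldName.BRIEF_SUMMARY).split()) + len(
        registration.text(FieldName.DETAILED_DESCRIPTION).split()
    )


def assemble_texts(
    *,
    official_title: str = "",
    brief_title: str = "",
    brief_summary: str = "",
    detailed_description: str = "",
    conditions: Sequence[str] = (),
    outcomes: Sequence[OutcomeRow] = (),
    population: str = "",
    gender_description: str = "",
    criteria: str = "",
    groups: Sequence[StudyGroup] = (),
    interventions: Sequence[Intervention] = (),
    sep: str = CHILD_TEXT_SEPARATOR,
) -> dict:
    """Build the per-field text map, newline-joining multi-row child text."""

    def rows(kind: str, attr: str) -> str:
        return sep.join(getattr(o, attr) for o in outcomes if o.outcome_type == kind and getattr(o, attr))

    return {
        FieldName.OFFICIAL_TITLE: official_title,
        FieldName.BRIEF_TITLE: brief_title,
        FieldName.BRIEF_SUMMARY: brief_summary,
        FieldName.DETAILED_DESCRIPTION: detailed_description,
        FieldName.CONDITIONS: sep.join(c for c in conditions if c),
        FieldName.PRIMARY_OUTCOME_TITLE: rows("primary", "title"),
        FieldName.PRIMARY_OUTCOME_DESCRIPTION: rows("primary", "description"),
        FieldName.SECONDARY_OUTCOME_TITLE: rows("secondary", "title"),
        FieldName.SECONDARY_OUTCOME_DESCRIPTION: rows("secondary", "description"),
        FieldName.OTHER_OUTCOME_TITLE: rows("other", "title"),
        FieldName.OTHER_OUTCOME_DESCRIPTION: rows("other", "description"),
        FieldName.ELIGIBILITY_POPULATION: population,
        FieldName.ELIGIBILITY_GENDER_DESCRIPTION: gender_description,
        FieldName.ELIGIBILITY_CRITERIA: criteria,
        FieldName.GROUP_TITLE: sep.join(g.title for g in groups if g.title),
        FieldName.GROUP_DESCRIPTION: sep.join(g.description for g in groups if g.description),
        FieldName.INTERVENTION_DESCRIPTION: sep.join(i.description for i in interventions if i.description),
    }


# ---------------------------------------------------------------------------
# AACT-dialect string mappings
# ---------------------------------------------------------------------------

_AACT_STUDY_TYPE = {
    "interventional": StudyType.INTERVENTIONAL,
    "observational": StudyType.OBSERVATIONAL,
    "observational [patient registry]": StudyType.PATIENT_REGISTRY,
    "expanded access": StudyType.EXPANDED_ACCESS,
}
_STUDY_TYPE_AACT = {
    StudyType.INTERVENTIONAL: "Interventional",
    StudyType.OBSERVATIONAL: "Observational",
    StudyType.PATIENT_REGISTRY: "Observational [Patient Registry]",
    StudyType.EXPANDED_ACCESS: "Expanded Access",
}
_AACT_ALLOCATION = {
    "randomized": Allocation.RANDOMIZED,
    "non-randomized": Allocation.NON_RANDOMIZED,
    "n/a": Allocation.NA,
    "na": Allocation.NA,
    "": Allocation.MISSING,
}
_ALLOCATION_AACT = {
    Allocation.RANDOMIZED: "Randomized",
    Allocation.NON_RANDOMIZED: "Non-Randomized",
    Allocation.NA: "N/A",
    Allocation.MISSING: "",
}
_AACT_PHASE = {
    "early phase 1": Phase.EARLY_PHASE_1,
    "phase 1": Phase.PHASE_1,
    "phase 1/phase 2": Phase.PHASE_1_2,
    "phase 2": Phase.PHASE_2,
    "phase 2/phase 3": Phase.PHASE_2_3,
    "phase 3": Phase.PHASE_3,
    "phase 4": Phase.PHASE_4,
    "n/a": Phase.NA,
}
_PHASE_AACT = {
    Phase.EARLY_PHASE_1: "Early Phase 1",
    Phase.PHASE_1: "Phase 1",
    Phase.PHASE_1_2: "Phase 1/Phase 2",
    Phase.PHASE_2: "Phase 2",
    Phase.PHASE_2_3: "Phase 2/Phase 3",
    Phase.PHASE_3: "Phase 3",
    Phase.PHASE_4: "Phase 4",
    Phase.NA: "N/A",
}
_AACT_GROUP_TYPE = {
    "experimental": GroupType.EXPERIMENTAL,
    "active comparator": GroupType.ACTIVE_COMPARATOR,
    "placebo comparator": GroupType.PLACEBO_COMPARATOR,
    "sham comparator": GroupType.SHAM_COMPARATOR,
    "no intervention": GroupType.NO_INTERVENTION,
    "other": GroupType.OTHER,
    "": GroupType.MISSING,
}
_GROUP_TYPE_AACT = {
    GroupType.EXPERIMENTAL: "Experimental",
    GroupType.ACTIVE_COMPARATOR: "Active Comparator",
    GroupType.PLACEBO_COMPARATOR: "Placebo Comparator",
    GroupType.SHAM_COMPARATOR: "Sham Comparator",
    GroupType.NO_INTERVENTION: "No Intervention",
    GroupType.OTHER: "Other",
    GroupType.MISSING: "",
}
_AACT_INTERVENTION_TYPE = {
    "drug": InterventionType.DRUG,
    "biological": InterventionType.BIOLOGICAL,
    "behavioral": InterventionType.BEHAVIORAL,
    "device": InterventionType.DEVICE,
    "procedure": InterventionType.PROCEDURE,
    "diagnostic test": InterventionType.DIAGNOSTIC_TEST,
    "dietary supplement": InterventionType.DIETARY_SUPPLEMENT,
    "radiation": InterventionType.RADIATION,
    "combination product": InterventionType.COMBINATION_PRODUCT,
    "genetic": InterventionType.GENETIC,
    "other": InterventionType.OTHER,
}
_INTERVENTION_TYPE_AACT = {
    InterventionType.DRUG: "Drug",
    InterventionType.BIOLOGICAL: "Biological",
    InterventionType.BEHAVIORAL: "Behavioral",
    InterventionType.DEVICE: "Device",
    InterventionType.PROCEDURE: "Procedure",
    InterventionType.DIAGNOSTIC_TEST: "Diagnostic Test",
    InterventionType.DIETARY_SUPPLEMENT: "Dietary Supplement",
    InterventionType.RADIATION: "Radiation",
    InterventionType.COMBINATION_PRODUCT: "Combination Product",
    InterventionType.GENETIC: "Genetic",
    InterventionType.OTHER: "Other",
}

TABLE_NAMES = (
    "studies",
    "brief_summaries",
    "detailed_descriptions",
    "conditions",
    "design_outcomes",
    "eligibilities",
    "design_groups",
    "designs",
    "interventions",
    "facilities",
    "documents",
)


@dataclass
class LoadReport:
    """Bookkeeping from one dump load: rows parsed, skipped and deduplicated."""

    rows_loaded: int = 0
    rows_skipped: int = 0
    duplicate_nct_ids_dropped: int = 0
    skipped_details: list = field(default_factory=list)


def _read_csv_rows(path: Path) -> Iterable[dict]:
    with open(path, newline="", encoding="utf-8") as fh:
        yield from csv.DictReader(fh)


def _group_by_nct(rows: Iterable[dict]) -> dict:
    out: dict = {}
    for row in rows:
        out.setdefault((row.get("nct_id") or "").strip(), []).append(row)
    return out


def load_registry_dump(
    paths: Mapping[str, Union[str, Path]],
    dialect: str = "aact_csv",
    report: Optional[LoadReport] = None,
) -> list[TrialRegistration]:
    """Load a multi-table dump and assemble one registration per study id.

    ``paths`` maps table names to files for the ``aact_csv`` dialect (the
    ``studies`` table is mandatory, everything else optional) or must contain
    a single ``registrations`` entry for the ``jsonl`` dialect. Unparseable
    rows are logged and skipped; duplicate ``nct_id`` rows in the studies
    table keep the first occurrence.
    """
    report = report if report is not None else LoadReport()
    if dialect == "jsonl":
        key = "registrations" if "registrations" in paths else next(iter(paths), None)
        if key is None or not Path(paths[key]).exists():
            raise ConfigurationError("jsonl dialect requires an existing 'registrations' file")
        return read_registrations_jsonl(Path(paths[key]), report=report)
    if dialect != "aact_csv":
        raise ConfigurationError(f"unknown dump dialect: {dialect!r}")
    if "studies" not in paths or not Path(paths["studies"]).exists():
        raise ConfigurationError("the 'studies' table is mandatory and was not found")

    children: dict = {}
    for table in TABLE_NAMES[1:]:
        p = paths.get(table)
        children[table] = _group_by_nct(_read_csv_rows(Path(p))) if p and Path(p).exists() else {}

    registrations: list[TrialRegistration] = []
    seen: set = set()
    for row in _read_csv_rows(Path(paths["studies"])):
        nct_id = (row.get("nct_id") or "").strip()
        if not nct_id:
            report.rows_skipped += 1
            report.skipped_details.append(("studies", "missing nct_id"))
            continue
        if nct_id in seen:
            report.duplicate_nct_ids_dropped += 1
            log.warning("duplicate nct_id %s in studies table: keeping first", nct_id)
            continue
        try:
            registrations.append(_assemble_from_aact(nct_id, row, children))
        except Exception as exc:  # totality: a bad row never aborts the load
            report.rows_skipped += 1
            report.skipped_details.append((nct_id, str(exc)))
            log.warning("skipping unparseable study row %s: %s", nct_id, exc)
            continue
        seen.add(nct_id)
        report.rows_loaded += 1
    return registrations


def _assemble_from_aact(nct_id: str, row: dict, children: dict) -> TrialRegistration:
    def child(table: str) -> list[dict]:
        return children.get(table, {}).get(nct_id, [])

    study_type_raw = (row.get("study_type") or "").strip().lower()
    if study_type_raw not in _AACT_STUDY_TYPE:
        raise ValueError(f"unknown study_type {row.get('study_type')!r}")
    study_type = _AACT_STUDY_TYPE[study_type_raw]

    designs = child("designs")
    alloc_raw = (designs[0].get("allocation") or "").strip().lower() if designs else ""
    allocation = _AACT_ALLOCATION.get(alloc_raw, Allocation.MISSING)

    phase_raw = (row.get("phase") or "").strip().lower()
    phase = _AACT_PHASE.get(phase_raw) if phase_raw else None

    elig = child("eligibilities")
    elig_row = elig[0] if elig else {}

    groups = [
        StudyGroup(
            group_type=_AACT_GROUP_TYPE.get((g.get("group_type") or "").strip().lower(), GroupType.MISSING),
            title=g.get("title") or "",
            description=g.get("description") or "",
        )
        for g in child("design_groups")
    ]
    interventions = []
    for iv in child("interventions"):
        t = (iv.get("intervention_type") or "").strip().lower()
        if t not in _AACT_INTERVENTION_TYPE:
            raise ValueError(f"unknown intervention_type {iv.get('intervention_type')!r}")
        interventions.append(
            Intervention(intervention_type=_AACT_INTERVENTION_TYPE[t], description=iv.get("description") or "")
        )
    outcomes = [
        OutcomeRow(
            outcome_type=(o.get("outcome_type") or "").strip().lower(),
            title=o.get("measure") or "",
            description=o.get("description") or "",
        )
        for o in child("design_outcomes")
    ]

    submitted = parse_date(row.get("study_first_submitted_date"))
    if submitted is None:
        raise ValueError("missing study_first_submitted_date")

    enrollment_raw = (row.get("enrollment") or "").strip()
    enrollment = int(enrollment_raw) if enrollment_raw else None
    enrollment_type_raw = (row.get("enrollment_type") or "").strip().lower()
    enrollment_type = {
        "anticipated": EnrollmentType.ANTICIPATED,
        "actual": EnrollmentType.ACTUAL,
    }.get(enrollment_type_raw, EnrollmentType.MISSING)

    briefs = child("brief_summaries")
    details = child("detailed_descriptions")
    texts = assemble_texts(
        official_title=row.get("official_title") or "",
        brief_title=row.get("brief_title") or "",
        brief_summary=CHILD_TEXT_SEPARATOR.join(b.get("description") or "" for b in briefs),
        detailed_description=CHILD_TEXT_SEPARATOR.join(d.get("description") or "" for d in details),
        conditions=[c.get("name") or "" for c in child("conditions")],
        outcomes=outcomes,
        population=elig_row.get("population") or "",
        gender_description=elig_row.get("gender_description") or "",
        criteria=elig_row.get("criteria") or "",
        groups=groups,
        interventions=interventions,
    )

    return TrialRegistration(
        nct_id=nct_id,
        study_type=study_type,
        allocation=allocation,
        phase=phase,
        sexes_eligible=parse_sexes_eligible(elig_row.get("gender")),
        status=row.get("overall_status") or "",
        start_date=parse_date(row.get("start_date")),
        submitted_date=submitted,
        enrollment_count=enrollment,
        enrollment_type=enrollment_type,
        texts=texts,
        groups=groups,
        interventions=interventions,
        outcomes=outcomes,
        facility_countries=[f.get("country") or "" for f in child("facilities")],
        has_document=bool(child("documents")),
    )


# ---------------------------------------------------------------------------
# JSON-lines dialect
# ---------------------------------------------------------------------------


def registration_to_json(reg: TrialRegistration) -> dict:
    return {
        "nct_id": reg.nct_id,
        "study_type": reg.study_type.value,
        "allocation": reg.allocation.value,
        "phase": reg.phase.value if reg.phase else None,
        "sexes_eligible": reg.sexes_eligible.value,
        "status": reg.status,
        "start_date": reg.start_date.isoformat() if reg.start_date else None,
        "submitted_date": reg.submitted_date.isoformat(),
        "enrollment_count": reg.enrollment_count,
        "enrollment_type": reg.enrollment_type.value,
        "texts": {k.value: v for k, v in reg.texts.items() if v},
        "groups": [
            {"group_type": g.group_type.value, "title": g.title, "description": g.description} for g in reg.groups
        ],
        "interventions": [
            {"intervention_type": i.intervention_type.value, "description": i.description}
            for i in reg.interventions
        ],
        "outcomes": [
            {"outcome_type": o.outcome_type, "title": o.title, "description": o.description} for o in reg.outcomes
        ],
        "facility_countries": list(reg.facility_countries),
        "has_document": reg.has_document,
    }


def registration_from_json(obj: dict) -> TrialRegistration:
    return TrialRegistration(
        nct_id=obj["nct_id"],
        study_type=StudyType(obj["study_type"]),
        allocation=Allocation(obj.get("allocation", "Missing")),
        phase=Phase(obj["phase"]) if obj.get("phase") else None,
        sexes_eligible=SexesEligible(obj.get("sexes_eligible", "Missing")),
        status=obj.get("status", ""),
        start_date=parse_date(obj.get("start_date")),
        submitted_date=parse_date(obj["submitted_date"]),
        enrollment_count=obj.get("enrollment_count"),
        enrollment_type=EnrollmentType(obj.get("enrollment_type", "Missing")),
        texts={FieldName(k): v for k, v in obj.get("texts", {}).items()},
        groups=[
            StudyGroup(GroupType(g["group_type"]), g.get("title", ""), g.get("description", ""))
            for g in obj.get("groups", [])
        ],
        interventions=[
            Intervention(InterventionType(i["intervention_type"]), i.get("description", ""))
            for i in obj.get("interventions", [])
        ],
        outcomes=[
            OutcomeRow(o["outcome_type"], o.get("title", ""), o.get("description", ""))
            for o in obj.get("outcomes", [])
        ],
        facility_countries=obj.get("facility_countries", []),
        has_document=bool(obj.get("has_document", False)),
    )


def write_registrations_jsonl(registrations: Iterable[TrialRegistration], path: Union[str, Path]) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for reg in registrations:
            fh.write(json.dumps(registration_to_json(reg), sort_keys=True, ensure_ascii=False))
            fh.write("\n")
    return path


def read_registrations_jsonl(path: Union[str, Path], report: Optional[LoadReport] = None) -> list[TrialRegistration]:
    report = report if report is not None else LoadReport()
    out: list[TrialRegistration] = []
    seen: set = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            try:
                reg = registration_from_json(json.loads(line))
            except Exception as exc:
                report.rows_skipped += 1
                report.skipped_details.append(("registrations", str(exc)))
                log.warning("skipping unparseable jsonl row: %s", exc)
                continue
            if reg.nct_id in seen:
                report.duplicate_nct_ids_dropped += 1
                continue
            seen.add(reg.nct_id)
            out.append(reg)
            report.rows_loaded += 1
    return out


# ---------------------------------------------------------------------------
# Writing the AACT-dialect tables (round-trip support and synthetic dumps)
# ---------------------------------------------------------------------------


def write_dump_csv(registrations: Sequence[TrialRegistration], out_dir: Union[str, Path]) -> dict:
    """Write registrations as AACT-style CSV tables; returns table->path map."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {t: out_dir / f"{t}.csv" for t in TABLE_NAMES}

    def writer(path: Path, header: list[str]):
        fh = open(path, "w", newline="", encoding="utf-8")
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(header)
        return fh, w

    fhs = {}
    fhs["studies"], studies = writer(
        paths["studies"],
        [
            "nct_id", "official_title", "brief_title", "study_type", "overall_status",
            "phase", "start_date", "study_first_submitted_date", "enrollment", "enrollment_type",
        ],
    )
    fhs["brief_summaries"], briefs = writer(paths["brief_summaries"], ["nct_id", "description"])
    fhs["detailed_descriptions"], details = writer(paths["detailed_descriptions"], ["nct_id", "description"])
    fhs["conditions"], conditions = writer(paths["conditions"], ["nct_id", "name"])
    fhs["design_outcomes"], outcomes = writer(paths["design_outcomes"], ["nct_id", "outcome_type", "measure", "description"])
    fhs["eligibilities"], eligibilities = writer(
        paths["eligibilities"], ["nct_id", "gender", "population", "gender_description", "criteria"]
    )
    fhs["design_groups"], groups = writer(paths["design_groups"], ["nct_id", "group_type", "title", "description"])
    fhs["designs"], designs = writer(paths["designs"], ["nct_id", "allocation"])
    fhs["interventions"], interventions = writer(paths["interventions"], ["nct_id", "intervention_type", "description"])
    fhs["facilities"], facilities = writer(paths["facilities"], ["nct_id", "country"])
    fhs["documents"], documents = writer(paths["documents"], ["nct_id", "document_type"])

    seen: set = set()
    for reg in registrations:
        studies.writerow(
            [
                reg.nct_id,
                reg.text(FieldName.OFFICIAL_TITLE),
                reg.text(FieldName.BRIEF_TITLE),
                _STUDY_TYPE_AACT[reg.study_type],
                reg.status,
                _PHASE_AACT[reg.phase] if reg.phase else "",
                reg.start_date.isoformat() if reg.start_date else "",
                reg.submitted_date.isoformat(),
                reg.enrollment_count if reg.enrollment_count is not None else "",
                reg.enrollment_type.value if reg.enrollment_type != EnrollmentType.MISSING else "",
            ]
        )
        if reg.nct_id in seen:
            # a deliberate duplicate study row: child rows belong to the first copy
            continue
        seen.add(reg.nct_id)
        if reg.text(FieldName.BRIEF_SUMMARY):
            briefs.writerow([reg.nct_id, reg.text(FieldName.BRIEF_SUMMARY)])
        if reg.text(FieldName.DETAILED_DESCRIPTION):
            details.writerow([reg.nct_id, reg.text(FieldName.DETAILED_DESCRIPTION)])
        for c in reg.text(FieldName.CONDITIONS).split(CHILD_TEXT_SEPARATOR):
            if c:
                conditions.writerow([reg.nct_id, c])
        for o in reg.outcomes:
            outcomes.writerow([reg.nct_id, o.outcome_type, o.title, o.description])
        eligibilities.writerow(
            [
                reg.nct_id,
                reg.sexes_eligible.value if reg.sexes_eligible != SexesEligible.MISSING else "",
                reg.text(FieldName.ELIGIBILITY_POPULATION),
                reg.text(FieldName.ELIGIBILITY_GENDER_DESCRIPTION),
                reg.text(FieldName.ELIGIBILITY_CRITERIA),
            ]
        )
        for g in reg.groups:
            groups.writerow([reg.nct_id, _GROUP_TYPE_AACT[g.group_type], g.title, g.description])
        if reg.allocation != Allocation.MISSING:
            designs.writerow([reg.nct_id, _ALLOCATION_AACT[reg.allocation]])
        for iv in reg.interventions:
            interventions.writerow([reg.nct_id, _INTERVENTION_TYPE_AACT[iv.intervention_type], iv.description])
        for country in reg.facility_countries:
            facilities.writerow([reg.nct_id, country])
        if reg.has_document:
            documents.writerow([reg.nct_id, "Statistical Analysis Plan"])

    for fh in fhs.values():
        fh.close()
    return paths
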