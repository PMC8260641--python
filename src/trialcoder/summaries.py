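"""Descriptive summary tables: crosstabs, percentages, medians, monthly series.

All percentages are rounded half-up at the requested precision, which is the
convention that reproduces a printed (count, denominator) pair exactly.
Every emitted table passes a self-consistency audit: each percentage equals
``percentage()`` of its own count and denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import ConfigurationError, EmptySelectionError, UndefinedDenominatorError
from .registry_io import EnrollmentType, FieldName, Phase, TrialRegistration, word_count
from .rct_identification import StudyClass, StudyLabel
from .sexgender_coding import Category, SexGenderAssignment

CATEGORY_ORDER = [c.value for c in Category]
LABEL_ORDER = [l.value for l in StudyLabel]


def percentage(numerator: int, denominator: int, decimals: int = 1) -> float:
    """100·numerator/denominator, rounded half-up to ``decimals`` places."""
    if denominator == 0:
        raise UndefinedDenominatorError("percentage denominator is zero")
    if numerator < 0:
        raise ValueError("negative numerator")
    quantum = Decimal(1).scaleb(-decimals)
    value = (Decimal(100) * Decimal(numerator) / Decimal(denominator)).quantize(
        quantum, rounding=ROUND_HALF_UP
    )
    return float(value)


@dataclass
class SummaryTable:
    """A labelled count matrix with percentages under a stated denominator policy."""

    name: str
    row_labels: list
    col_labels: list
    counts: np.ndarray
    denominator: Union[int, np.ndarray]  # grand total, or per-column totals
    decimals: int = 1
    percentages: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if (self.counts < 0).any():
            raise ValueError(f"{self.name}: negative count")
        dens = np.broadcast_to(np.asarray(self.denominator, dtype=int), (self.counts.shape[1],))
        self.percentages = np.array(
            [
                [percentage(int(c), int(d), self.decimals) if d else float("nan") for c, d in zip(row, dens)]
                for row in self.counts
            ]
        )

    def validate(self) -> None:
        """Audit: every percentage equals percentage() of its count and denominator."""
        dens = np.broadcast_to(np.asarray(self.denominator, dtype=int), (self.counts.shape[1],))
        for i, row in enumerate(self.counts):
            for j, c in enumerate(row):
                if dens[j] and self.percentages[i, j] != percentage(int(c), int(dens[j]), self.decimals):
                    raise AssertionError(f"{self.name}: inconsistent percentage at ({i},{j})")

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for j, col in enumerate(self.col_labels):
            frames.append(
                pd.DataFrame(
                    {
                        (str(col), "count"): self.counts[:, j],
                        (str(col), "pct"): self.percentages[:, j],
                    },
                    index=self.row_labels,
                )
            )
        out = pd.concat(frames, axis=1)
        out.index.name = self.name
        return out


# ---------------------------------------------------------------------------
# The per-study analysis frame
# ---------------------------------------------------------------------------

_PHASE_BUCKETS = {
    Phase.EARLY_PHASE_1: "Early Phase 1",
    Phase.PHASE_1: "Phase 1",
    Phase.PHASE_1_2: "Phase 1/2",
    Phase.PHASE_2: "Phase 2",
    Phase.PHASE_2_3: "Phase 2/3",
    Phase.PHASE_3: "Phase 3",
    Phase.PHASE_4: "Phase 4",
    Phase.NA: "Not applicable",
}

VARIABLES = ("category", "label", "phase_bucket", "us_any", "enrollment_type", "submission_month")


def study_frame(
    cohort: Sequence[TrialRegistration],
    assignments: Sequence[SexGenderAssignment],
    classes: Sequence[StudyClass],
) -> pd.DataFrame:
    """One row per cohort study with every summarised variable.

    ``phase_bucket`` is 'No phase information' when the phase field is absent
    or 'Not applicable'; ``us_any`` buckets studies by whether any facility
    country is the United States (or 'No facility information').
    """
    a_by_id = {a.nct_id: a for a in assignments}
    c_by_id = {c.nct_id: c for c in classes}
    if set(a_by_id) != {r.nct_id for r in cohort} or set(c_by_id) != {r.nct_id for r in cohort}:
        raise ConfigurationError("assignments/classes must cover exactly the cohort nct_ids")
    rows = []
    for reg in cohort:
        phase = reg.phase
        phase_provided = phase is not None and phase != Phase.NA
        if reg.facility_countries:
            us_any = "US facility" if "United States" in reg.facility_countries else "Non-US only"
        else:
            us_any = "No facility information"
        rows.append(
            {
                "nct_id": reg.nct_id,
                "category": a_by_id[reg.nct_id].category.value,
                "subtag": (a_by_id[reg.nct_id].subtag or ""),
                "needs_review": a_by_id[reg.nct_id].needs_review,
                "label": c_by_id[reg.nct_id].label.value,
                "phase_bucket": _PHASE_BUCKETS[phase] if phase_provided else "No phase information",
                "phase_provided": phase_provided,
                "us_any": us_any,
                "enrollment_type": reg.enrollment_type.value,
                "enrollment_count": reg.enrollment_count,
                "submission_month": reg.submitted_date.strftime("%Y-%m"),
                "word_count": word_count(reg),
                "has_document": reg.has_document,
            }
        )
    columns = [
        "nct_id", "category", "subtag", "needs_review", "label", "phase_bucket", "phase_provided",
        "us_any", "enrollment_type", "enrollment_count", "submission_month", "word_count", "has_document",
    ]
    return pd.DataFrame(rows, columns=columns)


def _levels(frame: pd.DataFrame, var: str) -> list:
    if var == "category":
        return [c for c in CATEGORY_ORDER if c in set(frame[var])] or CATEGORY_ORDER
    if var == "label":
        return [l for l in LABEL_ORDER if l in set(frame[var])] or LABEL_ORDER
    return sorted(frame[var].dropna().unique().tolist())


def crosstab(
    frame: pd.DataFrame,
    row: str,
    col: Optional[str] = None,
    name: Optional[str] = None,
    decimals: int = 1,
) -> SummaryTable:
    """Count studies per (row, col) cell over the study frame.

    ``col=None`` yields a one-column tally. Percentages use the grand total
    as denominator. Supported variables: category, label, phase_bucket,
    us_any, enrollment_type, submission_month.
    """
    for var in (row, col) if col else (row,):
        if var not in VARIABLES:
            raise ConfigurationError(f"unknown crosstab variable {var!r}")
    row_levels = _levels(frame, row)
    if col is None:
        counts = np.array([[int((frame[row] == r).sum())] for r in row_levels])
        col_labels = ["All studies"]
    else:
        col_levels = _levels(frame, col)
        counts = np.array(
            [[int(((frame[row] == r) & (frame[col] == c)).sum()) for c in col_levels] for r in row_levels]
        )
        col_labels = col_levels
    return SummaryTable(
        name=name or (f"{row} x {col}" if col else row),
        row_labels=row_levels,
        col_labels=col_labels,
        counts=counts,
        denominator=max(len(frame), 1) if len(frame) else 1,
        decimals=decimals,
    )


def enrollment_median(
    frame: pd.DataFrame,
    category: Optional[str] = None,
    label: Optional[str] = None,
) -> float:
    """Median enrollment over the selection; missing counts are excluded.

    An even-sized selection yields the mean of the two central values.
    """
    sel = frame
    if category is not None:
        sel = sel[sel["category"] == category]
    if label is not None:
        sel = sel[sel["label"] == label]
    counts = sel["enrollment_count"].dropna()
    if counts.empty:
        raise EmptySelectionError("no enrollment counts in selection")
    return float(counts.median())


def monthly_series(
    cohort: Sequence[TrialRegistration],
    assignments: Optional[Sequence[SexGenderAssignment]] = None,
) -> pd.DataFrame:
    """Registrations per submission month with zero-filled empty months.

    Binned by the date first submitted (not the effective date used for
    windowing); columns give the total and per-category counts.
    """
    months = pd.PeriodIndex([r.submitted_date for r in cohort], freq="M")
    if len(months) == 0:
        return pd.DataFrame(columns=["month", "count"])
    span = pd.period_range(months.min(), months.max(), freq="M")
    by_id = {a.nct_id: a.category.value for a in assignments} if assignments else {}
    df = pd.DataFrame(
        {
            "month": months,
            "category": [by_id.get(r.nct_id, "") for r in cohort],
        }
    )
    out = pd.DataFrame({"month": span.astype(str)})
    tally = df.groupby("month").size().reindex(span, fill_value=0)
    out["count"] = tally.to_numpy()
    if assignments:
        for cat in CATEGORY_ORDER:
            col = df[df["category"] == cat].groupby("month").size().reindex(span, fill_value=0)
            out[cat] = col.to_numpy()
    return out


def wordcount_medians(frame: pd.DataFrame, by: str = "label") -> pd.Series:
    """Median description word count per group (brief + detailed fields)."""
    return frame.groupby(by)["word_count"].median()


def make_all_tables(
    frame: pd.DataFrame,
    cohort: Sequence[TrialRegistration],
    assignments: Sequence[SexGenderAssignment],
) -> dict:
    """The standard output set, each as a pandas DataFrame."""
    n = len(frame)
    categories = crosstab(frame, "category", name="categories")
    category_by_type = crosstab(frame, "category", "label", name="category_by_type")
    phases = crosstab(frame, "phase_bucket", name="phases")
    geography = crosstab(frame, "us_any", "category", name="geography")
    for t in (categories, category_by_type, phases, geography):
        t.validate()

    med_rows = []
    for cat in _levels(frame, "category"):
        sel = frame[frame["category"] == cat]["enrollment_count"].dropna()
        if len(sel):
            med_rows.append({"group": f"category:{cat}", "n": len(sel), "median_enrollment": float(sel.median())})
    for lab in _levels(frame, "label"):
        sel = frame[frame["label"] == lab]["enrollment_count"].dropna()
        if len(sel):
            med_rows.append({"group": f"label:{lab}", "n": len(sel), "median_enrollment": float(sel.median())})

    wc = wordcount_medians(frame).rename("median_word_count").reset_index()

    return {
        "categories": categories.to_frame(),
        "category_by_type": category_by_type.to_frame(),
        "phases": phases.to_frame(),
        "geography": geography.to_frame(),
        "enrollment_medians": pd.DataFrame(med_rows, columns=["group", "n", "median_enrollment"]),
        "monthly": monthly_series(cohort, assignments),
        "wordcounts": wc,
        "overview": pd.DataFrame(
            {
                "quantity": [
                    "studies",
                    "with_detailed_description",
                    "with_document",
                    "needs_review",
                ],
                "count": [
                    n,
                    sum(1 for r in cohort if r.texts[FieldName.DETAILED_DESCRIPTION].strip()),
                    int(frame["has_document"].sum()),
                    int(frame["needs_review"].sum()),
                ],
            }
        ),
    }


def write_tables(tables: dict, out_dir) -> dict:
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in tables.items():
        p = out_dir / f"{name}.csv"
        df.to_csv(p, index=isinstance(df.index, pd.MultiIndex) or df.index.name is not None)
        paths[name] = p
    return paths
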