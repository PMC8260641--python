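#!/usr/bin/env python
"""Produce the full summary-table set for the coded cohort.

Writes categories, category-by-type, phases, geography, enrollment medians,
monthly submission series and word-count medians under results/tables/, and
prints the quantities that summarise attention to sex/gender: the share of
analysis planners by study type, enrollment medians of analysis planners
versus studies with no mention, and the monthly trend.
"""

from pathlib import Path

from trialcoder.rct_identification import classify_all
from trialcoder.registry_io import read_registrations_jsonl
from trialcoder.sexgender_coding import assign_all
from trialcoder.summaries import (
    enrollment_median,
    make_all_tables,
    study_frame,
    write_tables,
)

ROOT = Path(__file__).resolve().parents[1]

if __name__ == "__main__":
    cohort = read_registrations_jsonl(ROOT / "scratch" / "cohort.jsonl")
    assignments = assign_all(cohort)
    classes = classify_all(cohort)
    frame = study_frame(cohort, assignments, classes)
    tables = make_all_tables(frame, cohort, assignments)
    paths = write_tables(tables, ROOT / "results" / "tables")
    print(f"wrote {len(paths)} tables to {ROOT / 'results' / 'tables'}")

    med_analysis = enrollment_median(frame, category="Analysis")
    med_none = enrollment_median(frame, category="NoMention")
    print(f"median enrollment, analysis planners : {med_analysis:.0f}")
    print(f"median enrollment, no mention        : {med_none:.0f}")

    monthly = tables["monthly"]
    h1 = monthly[monthly["month"].between("2020-01", "2020-06")]["count"].sum()
    print(f"submitted in H1 2020: {h1} of {len(cohort)} ({100 * h1 / len(cohort):.0f}%)")
    wc = tables["wordcounts"]
    print("median description word count by label:")
    for _, row in wc.iterrows():
        print(f"  {row['label']:<18}: {row['median_word_count']:.0f}")
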