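#!/usr/bin/env python
"""Code every cohort study into its sex/gender attention category.

Writes per-category counts and percentages to results/category_counts.csv,
the full assignment table to scratch/assignments.csv, and prints the
headline split (analysis planners, matching/reporting, recruitment-only,
single-sex, no mention) with the share flagged for human review.
"""

import csv
from collections import Counter
from pathlib import Path

from trialcoder.registry_io import read_registrations_jsonl
from trialcoder.sexgender_coding import assign_all
from trialcoder.summaries import percentage

ROOT = Path(__file__).resolve().parents[1]

if __name__ == "__main__":
    cohort = read_registrations_jsonl(ROOT / "scratch" / "cohort.jsonl")
    assignments = assign_all(cohort)

    counts = Counter(a.category.value for a in assignments)
    n = len(assignments)
    out = ROOT / "results" / "category_counts.csv"
    out.parent.mkdir(parents=True, exist_ok=True)
    with open(out, "w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["category", "count", "pct"])
        for cat in ("FemaleOnly", "MaleOnly", "Analysis", "OtherMention", "RecruitmentOnly", "NoMention"):
            w.writerow([cat, counts.get(cat, 0), percentage(counts.get(cat, 0), n, 1)])

    with open(ROOT / "scratch" / "assignments.csv", "w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["nct_id", "category", "subtag", "fired_rules", "n_matches", "needs_review"])
        for a in assignments:
            w.writerow([a.nct_id, a.category.value, a.subtag.value if a.subtag else "",
                        ";".join(a.fired_rules), len(a.evidence), a.needs_review])

    flagged = sum(1 for a in assignments if a.needs_review)
    print(f"coded {n} cohort studies:")
    for cat in ("Analysis", "OtherMention", "RecruitmentOnly", "FemaleOnly", "MaleOnly", "NoMention"):
        c = counts.get(cat, 0)
        print(f"  {cat:<16}: {c:>5} ({percentage(c, n, 1)}%)")
    print(f"  flagged for review: {flagged} ({percentage(flagged, n, 1)}%)")
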