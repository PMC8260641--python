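#!/usr/bin/env python
"""Label each cohort study: pharmacological RCT, other intervention,
observational, patient registry or expanded access.

Writes per-label counts to results/label_counts.csv and the full class
table to scratch/classes.csv; prints which rule identified each
pharmacological RCT's control arm (group type, group text, or title/
intervention text fallbacks).
"""

import csv
from collections import Counter
from pathlib import Path

from trialcoder.rct_identification import classify_all
from trialcoder.registry_io import read_registrations_jsonl
from trialcoder.summaries import percentage

ROOT = Path(__file__).resolve().parents[1]

if __name__ == "__main__":
    cohort = read_registrations_jsonl(ROOT / "scratch" / "cohort.jsonl")
    classes = classify_all(cohort)

    counts = Counter(c.label.value for c in classes)
    rules = Counter(c.rct_rule.value for c in classes if c.rct_rule)
    n = len(classes)
    out = ROOT / "results" / "label_counts.csv"
    out.parent.mkdir(parents=True, exist_ok=True)
    with open(out, "w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["label", "count", "pct"])
        for label in ("Observational", "OtherIntervention", "PharmaRCT", "PatientRegistry", "ExpandedAccess"):
            w.writerow([label, counts.get(label, 0), percentage(counts.get(label, 0), n, 1)])

    with open(ROOT / "scratch" / "classes.csv", "w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["nct_id", "label", "rct_rule"])
        for c in classes:
            w.writerow([c.nct_id, c.label.value, c.rct_rule.value if c.rct_rule else ""])

    print(f"labeled {n} cohort studies:")
    for label, c in counts.most_common():
        print(f"  {label:<18}: {c:>5} ({percentage(c, n, 1)}%)")
    print("pharmacological RCT control-arm evidence:")
    for rule, c in rules.most_common():
        print(f"  {rule:<24}: {c}")
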