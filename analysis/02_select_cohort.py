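#!/usr/bin/env python
"""Screen the dump for COVID-19 relevance and apply window/status filters.

Writes the cohort to scratch/cohort.jsonl and a small exclusion tally to
results/exclusion_counts.csv; prints how each inclusion rule contributed —
on realistic mixes almost every cohort study enters via its titles or
conditions, mirroring the published 98%/2% split.
"""

import csv
from collections import Counter
from pathlib import Path

from trialcoder.cohort_selection import select_cohort
from trialcoder.registry_io import read_registrations_jsonl, write_registrations_jsonl
from trialcoder.summaries import percentage

ROOT = Path(__file__).resolve().parents[1]

if __name__ == "__main__":
    registrations = read_registrations_jsonl(ROOT / "scratch" / "dump" / "registrations.jsonl")
    cohort, decisions, dedup_log = select_cohort(registrations)
    write_registrations_jsonl(cohort, ROOT / "scratch" / "cohort.jsonl")

    rules = Counter(d.rule.value for d in decisions)
    out = ROOT / "results" / "exclusion_counts.csv"
    out.parent.mkdir(parents=True, exist_ok=True)
    with open(out, "w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["rule", "count"])
        w.writerows(sorted(rules.items()))

    print(f"cohort: {len(cohort)} of {len(registrations)} loaded registrations")
    included = [d for d in decisions if d.included]
    title_share = percentage(rules.get("TitleOrCondition", 0), len(included), 1)
    print(f"  via titles/conditions : {rules.get('TitleOrCondition', 0)} ({title_share}%)")
    print(f"  via primary outcomes  : {rules.get('PrimaryOutcome', 0)}")
    print(f"  via two other fields  : {rules.get('TwoOtherFields', 0)}")
    for rule in ("NotMatched", "OutOfWindow", "BadStatus", "Duplicate"):
        print(f"  excluded {rule:<13}: {rules.get(rule, 0)}")
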