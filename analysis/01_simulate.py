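#!/usr/bin/env python
"""Generate the full-scale synthetic registry dump for the demo analysis.

Emulates the structure of the COVID-19 registration sample at its published
size (4420 records plus screening noise): category and study-type mixes,
COVID term placement, submission timing, enrollment and word-count medians,
adversarial trap templates and planted duplicates. The dump (both dialects)
and its truth table land under scratch/dump/; downstream scripts read the
JSON-lines dialect.
"""

from pathlib import Path

from trialcoder.synthetic_data import GeneratorSpec, generate_dump

ROOT = Path(__file__).resolve().parents[1]
SEED = 20210126
N = 4420

if __name__ == "__main__":
    spec = GeneratorSpec(n_studies=N, seed=SEED)
    paths = generate_dump(spec, ROOT / "scratch" / "dump")
    print(f"generated {N} registrations (seed {SEED})")
    print(f"  jsonl dialect : {paths['registrations']}")
    print(f"  csv dialect   : {paths['studies'].parent}")
    print(f"  truth table   : {paths['truth']}")
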