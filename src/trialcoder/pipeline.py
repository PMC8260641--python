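"""End-to-end orchestration: select → code → rct → summarize, with a manifest.

One structured YAML config governs a run; the manifest records the config
snapshot, input/output digests, per-stage record counts and the package
version, so a coding run is reproducible and auditable. Two runs over
identical inputs and config produce byte-identical outputs.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import yaml

from . import __version__, config as cfgmod
from .cohort_selection import WINDOW_END, WINDOW_START, CohortRule, select_cohort
from .errors import ConfigurationError
from .rct_identification import classify_all
from .registry_io import LoadReport, load_registry_dump, parse_date, write_registrations_jsonl
from .sexgender_coding import assign_all
from .summaries import make_all_tables, study_frame, write_tables


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    config: dict
    input_digests: dict
    counts: dict
    version: str = __version__
    output_digests: dict = field(default_factory=dict)

    def validate(self) -> None:
        """Stage counts must be mutually consistent."""
        c = self.counts
        if c["loaded"] != c["cohort"] + sum(c["excluded_by_rule"].values()):
            raise AssertionError("loaded != cohort + excluded")
        if sum(c["by_category"].values()) != c["cohort"]:
            raise AssertionError("category counts do not sum to cohort size")
        if sum(c["by_label"].values()) != c["cohort"]:
            raise AssertionError("label counts do not sum to cohort size")

    def to_json(self) -> str:
        return json.dumps(
            {
                "version": self.version,
                "config": self.config,
                "input_digests": self.input_digests,
                "counts": self.counts,
                "output_digests": self.output_digests,
            },
            sort_keys=True,
            indent=2,
        )


def _resolve_dump_paths(dump_cfg: dict) -> tuple[dict, str]:
    dialect = dump_cfg.get("dialect", "aact_csv")
    if "paths" in dump_cfg:
        paths = {k: Path(v) for k, v in dump_cfg["paths"].items()}
    elif "dir" in dump_cfg:
        d = Path(dump_cfg["dir"])
        if dialect == "jsonl":
            paths = {"registrations": d / "registrations.jsonl"}
        else:
            paths = {p.stem: p for p in sorted(d.glob("*.csv"))}
    else:
        raise ConfigurationError("dump config needs 'paths' or 'dir'")
    for name, p in paths.items():
        if name == "studies" or (dialect == "jsonl" and name == "registrations"):
            if not Path(p).exists():
                raise ConfigurationError(f"required dump file does not exist: {p}")
    if not paths:
        raise ConfigurationError("dump config resolved to no files")
    return paths, dialect


def _write_csv(path: Path, header: list[str], rows: list[list]) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(header)
        w.writerows(rows)


def run_all(run_config: Union[dict, str, Path], out_dir: Optional[Union[str, Path]] = None) -> RunManifest:
    """Execute the four stages on one dump and write all outputs plus a manifest."""
    if not isinstance(run_config, dict):
        with open(run_config, encoding="utf-8") as fh:
            run_config = yaml.safe_load(fh)
    cfg = dict(run_config)
    out_dir = Path(out_dir or cfg.get("out_dir", "results/run"))
    out_dir.mkdir(parents=True, exist_ok=True)

    paths, dialect = _resolve_dump_paths(cfg.get("dump", {}))
    input_digests = {name: _sha256(Path(p)) for name, p in sorted(paths.items()) if Path(p).exists()}

    report = LoadReport()
    registrations = load_registry_dump(paths, dialect=dialect, report=report)

    window_cfg = cfg.get("window", {})
    start = parse_date(str(window_cfg.get("start", ""))) or WINDOW_START
    end = parse_date(str(window_cfg.get("end", ""))) or WINDOW_END

    covid_cfg = cfgmod.load_covid_config(cfg.get("covid_terms"))
    sg_cfg = cfgmod.load_sexgender_config(cfg.get("sexgender_terms"))
    bank = cfgmod.load_rule_bank(cfg.get("sexgender_rules"))

    cohort, decisions, dedup_log = select_cohort(registrations, covid_cfg.terms, start, end)

    try:
        assignments = assign_all(cohort, sg_cfg, bank)
    except Exception as exc:
        raise RuntimeError(f"stage 'code' failed: {exc}") from exc
    try:
        classes = classify_all(cohort)
    except Exception as exc:
        raise RuntimeError(f"stage 'rct' failed: {exc}") from exc
    frame = study_frame(cohort, assignments, classes)
    tables = make_all_tables(frame, cohort, assignments)

    # ---- outputs -------------------------------------------------------------
    write_registrations_jsonl(cohort, out_dir / "cohort.jsonl")
    _write_csv(
        out_dir / "exclusions.csv",
        ["nct_id", "rule"],
        [[d.nct_id, d.rule.value] for d in decisions if not d.included],
    )
    _write_csv(
        out_dir / "dedup_log.csv",
        ["nct_id", "reason", "kept"],
        [[e["nct_id"], e["reason"], e["kept"]] for e in dedup_log],
    )
    _write_csv(
        out_dir / "assignments.csv",
        ["nct_id", "category", "subtag", "fired_rules", "n_matches", "needs_review"],
        [
            [a.nct_id, a.category.value, a.subtag.value if a.subtag else "",
             ";".join(a.fired_rules), len(a.evidence), a.needs_review]
            for a in assignments
        ],
    )
    _write_csv(
        out_dir / "review_queue.csv",
        ["nct_id", "category", "fired_rules", "n_matches"],
        [
            [a.nct_id, a.category.value, ";".join(a.fired_rules), len(a.evidence)]
            for a in assignments
            if a.needs_review
        ],
    )
    _write_csv(
        out_dir / "classes.csv",
        ["nct_id", "label", "rct_rule"],
        [[c.nct_id, c.label.value, c.rct_rule.value if c.rct_rule else ""] for c in classes],
    )
    table_paths = write_tables(tables, out_dir / "tables")

    excluded_by_rule: dict = {}
    for d in decisions:
        if not d.included:
            excluded_by_rule[d.rule.value] = excluded_by_rule.get(d.rule.value, 0) + 1
    by_category: dict = {}
    for a in assignments:
        by_category[a.category.value] = by_category.get(a.category.value, 0) + 1
    by_label: dict = {}
    for c in classes:
        by_label[c.label.value] = by_label.get(c.label.value, 0) + 1

    manifest = RunManifest(
        config={k: str(v) if isinstance(v, Path) else v for k, v in cfg.items()},
        input_digests=input_digests,
        counts={
            "rows_loaded": report.rows_loaded,
            "rows_skipped": report.rows_skipped,
            "file_duplicates_dropped": report.duplicate_nct_ids_dropped,
            "loaded": len(registrations),
            "cohort": len(cohort),
            "excluded_by_rule": excluded_by_rule,
            "by_category": by_category,
            "by_label": by_label,
            "needs_review": sum(1 for a in assignments if a.needs_review),
        },
    )
    manifest.validate()
    output_files = [out_dir / f for f in
                    ("cohort.jsonl", "exclusions.csv", "dedup_log.csv", "assignments.csv",
                     "review_queue.csv", "classes.csv")] + sorted(table_paths.values())
    manifest.output_digests = {str(p.relative_to(out_dir)): _sha256(p) for p in output_files}
    (out_dir / "manifest.json").write_text(manifest.to_json() + "\n", encoding="utf-8")
    return manifest
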