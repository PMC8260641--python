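"""Loading of term lists and the sex/gender rule bank.

Term lists and the rule bank ship as editable YAML inside the package
(``trialcoder/data``) and can be overridden per run by passing a file path
to the loaders. The auditability of every coding decision rests on these
files: each classification records the rule ids that fired.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import yaml

from .errors import ConfigurationError
from .registry_io import FieldName
from .textmatch import TermSpec

RULE_KINDS = ("spurious", "analysis", "other_mention", "recruitment")


@dataclass(frozen=True)
class TermConfig:
    """A term list plus the field scope it is searched in."""

    terms: tuple[TermSpec, ...]
    scope: tuple[FieldName, ...]
    sex_classes: dict = field(default_factory=dict, hash=False)  # term surface -> female|male|neutral


@dataclass(frozen=True)
class Rule:
    """One coding rule: cue terms tested inside a match's context window."""

    rule_id: str
    kind: str  # one of RULE_KINDS
    cues: tuple[TermSpec, ...]
    subtag: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind not in RULE_KINDS:
            raise ConfigurationError(f"rule {self.rule_id!r}: unknown kind {self.kind!r}")


@dataclass(frozen=True)
class RuleBank:
    """The ordered rule set; negative (spurious) rules are applied first."""

    rules: tuple[Rule, ...]

    def __post_init__(self) -> None:
        ids = [r.rule_id for r in self.rules]
        if len(ids) != len(set(ids)):
            raise ConfigurationError("duplicate rule ids in rule bank")

    def of_kind(self, kind: str) -> tuple[Rule, ...]:
        return tuple(r for r in self.rules if r.kind == kind)

    @property
    def rule_ids(self) -> tuple[str, ...]:
        return tuple(r.rule_id for r in self.rules)


def _read_yaml(name: str, path: Optional[Union[str, Path]]) -> dict:
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            return yaml.safe_load(fh)
    return yaml.safe_load(resources.files("trialcoder.data").joinpath(name).read_text(encoding="utf-8"))


def _term_from_entry(entry: dict) -> TermSpec:
    return TermSpec(
        surface=entry["surface"],
        wildcard=bool(entry.get("wildcard", False)),
        expand_plural=bool(entry.get("plural", False)),
        case_sensitive=bool(entry.get("case_sensitive", False)),
    )


def _term_config(raw: dict) -> TermConfig:
    try:
        scope = tuple(FieldName(f) for f in raw["scope"])
    except ValueError as exc:
        raise ConfigurationError(f"unknown field name in scope: {exc}") from exc
    terms = tuple(_term_from_entry(e) for e in raw["terms"])
    classes = {e["surface"]: e["sex_class"] for e in raw["terms"] if "sex_class" in e}
    return TermConfig(terms=terms, scope=scope, sex_classes=classes)


def load_covid_config(path: Optional[Union[str, Path]] = None) -> TermConfig:
    """The COVID-19 term list and search scope (overridable via ``path``)."""
    return _term_config(_read_yaml("covid_terms.yaml", path))


def load_sexgender_config(path: Optional[Union[str, Path]] = None) -> TermConfig:
    """The sex/gender term list, search scope and per-term sex classes."""
    return _term_config(_read_yaml("sexgender_terms.yaml", path))


def load_rule_bank(path: Optional[Union[str, Path]] = None) -> RuleBank:
    """The context rule bank for sex/gender coding."""
    raw = _read_yaml("sexgender_rules.yaml", path)
    rules = tuple(
        Rule(
            rule_id=r["id"],
            kind=r["kind"],
            cues=tuple(_term_from_entry(c) for c in r["cues"]),
            subtag=r.get("subtag"),
        )
        for r in raw["rules"]
    )
    return RuleBank(rules=rules)
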