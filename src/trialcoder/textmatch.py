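"""Case-insensitive, hyphen-blind, plural- and wildcard-aware term matching.

The matcher implements four rules over the scoped free-text fields of a
registration:

(i)   comparison is case-insensitive;
(ii)  any internal hyphen or space in a multi-token term matches zero or one
      of {hyphen, space} in the text, so "SARS-CoV-2" hits "SARS CoV2",
      "SARSCoV2" and "sars-cov-2" alike;
(iii) a non-wildcard match is rejected when immediately preceded or followed
      by a letter — digits and punctuation are permitted neighbours, which
      lets "COVID" hit "COVID-19" and "COVID19" while blocking "male"
      inside "female";
(iv)  a wildcard term ("pregnan*") greedily absorbs trailing letters and is
      therefore only subject to the left-neighbour rule.

Plural expansion is morphological: regular "+s"/"+es" and consonant-y →
"ies" variants, plus the irregular pairs man/men and woman/women. Before
matching, typographic hyphen variants and non-breaking spaces are normalised
to their ASCII forms (a length-preserving mapping, so reported offsets index
the original text).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Optional, Sequence, Union

from .errors import ConfigurationError
from .registry_io import FIELD_ORDER, FieldName

_LETTER = r"[^\W\d_]"

# length-preserving normalisation: typographic hyphens/minus -> '-', NBSP -> ' '
_TRANSLATE = {ord(c): "-" for c in "‐‑‒–—−"}
_TRANSLATE[0x00A0] = " "


def normalize(text: str) -> str:
    return text.translate(_TRANSLATE)


@dataclass(frozen=True)
class TermSpec:
    """One search term: a surface string, optionally wildcarded or pluralised.

    ``wildcard`` terms are written with a trailing asterisk ("transg*") and
    never also expand plurals. ``case_sensitive`` supports all-caps token
    matching (used for the "RCT" acronym).
    """

    surface: str
    wildcard: bool = False
    expand_plural: bool = False
    case_sensitive: bool = False

    def __post_init__(self) -> None:
        if not self.surface:
            raise ConfigurationError("empty term surface")
        if self.wildcard and self.expand_plural:
            raise ConfigurationError(f"wildcard term {self.surface!r} cannot also expand plurals")
        if self.wildcard and not self.surface.endswith("*"):
            raise ConfigurationError(f"wildcard term {self.surface!r} must end with '*'")


@dataclass(frozen=True)
class TermMatch:
    """One occurrence of a term: evidence record backing every classification."""

    term: str  # the TermSpec surface that fired
    field: FieldName
    start: int
    end: int  # 0-based, half-open
    surface_form: str


_IRREGULAR_PLURALS = {"man": "men", "woman": "women"}


def _plural_variants(word: str) -> list[str]:
    lower = word.lower()
    if lower in _IRREGULAR_PLURALS:
        return [_IRREGULAR_PLURALS[lower]]
    if re.search(r"(s|x|z|ch|sh)$", lower):
        return [word + "es"]
    if re.search(r"[^aeiou]y$", lower):
        return [word[:-1] + "ies"]
    return [word + "s"]


def expand_terms(spec: TermSpec) -> list[str]:
    """Return the pattern set for one term: the surface plus plural variants.

    Wildcard patterns keep their trailing '*'; the plural of a multi-token
    term is formed on its last token.
    """
    if spec.wildcard:
        return [spec.surface]
    variants = [spec.surface]
    if spec.expand_plural:
        head, sep, last = spec.surface.rpartition(" ")
        variants.extend(head + sep + p for p in _plural_variants(last))
    return variants


def _separator_flexible(literal: str) -> str:
    """Regex core where each internal hyphen/space run matches zero or one of {hyphen, space}."""
    parts = [p for p in re.split(r"[\- ]+", literal) if p]
    return r"[\- ]?".join(re.escape(p) for p in parts)


def _variant_regex(variant: str) -> str:
    if variant.endswith("*"):
        return f"(?<!{_LETTER}){_separator_flexible(variant[:-1])}{_LETTER}*"
    return f"(?<!{_LETTER}){_separator_flexible(variant)}(?!{_LETTER})"


@lru_cache(maxsize=512)
def _compiled(spec: TermSpec) -> tuple:
    flags = 0 if spec.case_sensitive else re.IGNORECASE
    return tuple(re.compile(_variant_regex(v), flags) for v in expand_terms(spec))


def find_in_text(text: str, terms: Sequence[TermSpec]) -> list[tuple[TermSpec, int, int, str]]:
    """All term occurrences in one text as (term, start, end, surface_form)."""
    norm = normalize(text)
    hits: list[tuple[TermSpec, int, int, str]] = []
    for ti, spec in enumerate(terms):
        spans = set()
        for pattern in _compiled(spec):
            for m in pattern.finditer(norm):
                spans.add((m.start(), m.end()))
        hits.extend((spec, s, e, text[s:e]) for s, e in sorted(spans))
    # deterministic order: offset, then term list order
    order = {id(t): i for i, t in enumerate(terms)}
    hits.sort(key=lambda h: (h[1], h[2], order[id(h[0])]))
    return hits


def find_matches(
    texts: Mapping[Union[FieldName, str], str],
    scope: Iterable[Union[FieldName, str]],
    terms: Sequence[TermSpec],
) -> list[TermMatch]:
    """All term occurrences in the scoped fields, in field order then offset order."""
    try:
        scope_fields = sorted({FieldName(f) for f in scope}, key=FIELD_ORDER.get)
    except ValueError as exc:
        raise ConfigurationError(f"unknown field in search scope: {exc}") from exc
    text_map = {FieldName(k): v for k, v in texts.items()}
    matches: list[TermMatch] = []
    for fname in scope_fields:
        text = text_map.get(fname) or ""
        if not text:
            continue
        for spec, start, end, surface in find_in_text(text, terms):
            matches.append(TermMatch(spec.surface, fname, start, end, surface))
    return matches
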