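"""Term-matching engine: plural/wildcard expansion, neighbour rules,
hyphen/space/case blindness, and equivalence with a brute-force scanner."""

import re

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trialcoder.config import load_covid_config, load_sexgender_config
from trialcoder.errors import ConfigurationError
from trialcoder.registry_io import FieldName
from trialcoder.textmatch import TermSpec, expand_terms, find_in_text, find_matches, normalize

COVID_TERMS = load_covid_config().terms
SG_TERMS = load_sexgender_config().terms
ALL_TERMS = COVID_TERMS + SG_TERMS


# ---------------------------------------------------------------------------
# an independent brute-force scanner implementing the matching rules directly
# ---------------------------------------------------------------------------


def _ends_from(text: str, pos: int, tokens: list) -> set:
    if not text.startswith(tokens[0], pos):
        return set()
    after = pos + len(tokens[0])
    if len(tokens) == 1:
        return {after}
    ends = set()
    ends |= _ends_from(text, after, tokens[1:])  # zero separator
    if after < len(text) and text[after] in "- ":
        ends |= _ends_from(text, after + 1, tokens[1:])  # one separator
    return ends


def oracle_spans(text: str, spec: TermSpec) -> set:
    """All (start, end) spans for one term, by checking every substring."""
    norm = normalize(text)
    low = norm if spec.case_sensitive else norm.lower()
    spans = set()
    for variant in expand_terms(spec):
        wildcard = variant.endswith("*")
        stem = variant[:-1] if wildcard else variant
        stem = stem if spec.case_sensitive else stem.lower()
        tokens = [t for t in re.split(r"[\- ]+", stem) if t]
        for start in range(len(low)):
            if start > 0 and low[start - 1].isalpha():
                continue
            for end in _ends_from(low, start, tokens):
                if wildcard:
                    while end < len(low) and low[end].isalpha():
                        end += 1
                elif end < len(low) and low[end].isalpha():
                    continue
                spans.add((start, end))
    return spans


def impl_spans(text: str, spec: TermSpec) -> set:
    return {(s, e) for t, s, e, _ in find_in_text(text, [spec]) if t is spec}


# ---------------------------------------------------------------------------
# expansion
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "spec, expected",
    [
        (TermSpec("woman", expand_plural=True), {"woman", "women"}),
        (TermSpec("man", expand_plural=True), {"man", "men"}),
        (TermSpec("sex", expand_plural=True), {"sex", "sexes"}),
        (TermSpec("boy", expand_plural=True), {"boy", "boys"}),
        (TermSpec("girl", expand_plural=True), {"girl", "girls"}),
        (TermSpec("pregnancy test", expand_plural=True), {"pregnancy test", "pregnancy tests"}),
        (TermSpec("pregnan*", wildcard=True), {"pregnan*"}),
    ],
)
def test_expand_terms(spec, expected):
    assert set(expand_terms(spec)) == expected


def test_wildcard_matches_any_trailing_letters():
    spans = impl_spans("Pregnant people; pregnancy outcomes; pregnancies.", TermSpec("pregnan*", wildcard=True))
    assert len(spans) == 3


# ---------------------------------------------------------------------------
# the matching rules
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "text, surface, n",
    [
        ("Efficacy in SARSCoV2 infection", "SARS CoV2", 1),  # separator collapse
        ("Efficacy in SARS-CoV-2 infection", "SARS-CoV-2", 1),
        ("Efficacy in sars cov-2 infection", "SARS-CoV-2", 1),
        ("COVID19 pneumonia and covid-19 sequelae", "COVID", 2),  # digit neighbours allowed
        ("the 2019-nCoV outbreak", "2019 nCov", 1),
        ("female participants", "male", 0),  # letter-neighbour rejection
        ("female participants", "female", 1),
        ("Covidien ventilators", "COVID", 0),  # substring trap
        ("unisex design", "sex", 0),
        ("sexes eligible", "sex", 1),  # via the plural variant only
    ],
)
def test_neighbour_and_separator_rules(text, surface, n):
    spec = next((t for t in ALL_TERMS if t.surface == surface), None) or TermSpec(surface)
    assert len(impl_spans(text, spec)) == n


def test_plural_match_reports_plural_surface():
    hits = find_in_text("both sexes will be recorded", [TermSpec("sex", expand_plural=True)])
    assert [h[3] for h in hits] == ["sexes"]


def test_typographic_hyphen_normalisation():
    # en dash between the term tokens must behave like an ASCII hyphen
    spec = TermSpec("SARS-CoV-2")
    assert len(impl_spans("confirmed SARS–CoV–2 infection", spec)) == 1


def test_unknown_scope_field_is_configuration_error():
    with pytest.raises(ConfigurationError):
        find_matches({FieldName.BRIEF_TITLE: "x"}, ["NotAField"], [TermSpec("sex")])


def test_matches_ordered_by_field_then_offset():
    texts = {
        FieldName.BRIEF_TITLE: "COVID and COVID",
        FieldName.OFFICIAL_TITLE: "COVID study",
    }
    matches = find_matches(texts, [FieldName.BRIEF_TITLE, FieldName.OFFICIAL_TITLE], COVID_TERMS)
    keys = [(m.field, m.start) for m in matches]
    assert keys == sorted(keys, key=lambda k: (list(FieldName).index(k[0]), k[1]))


def test_match_invariant_surface_equals_slice():
    text = "Sex-disaggregated reporting of COVID-19 and Covid19 data"
    for spec in ALL_TERMS:
        for t, s, e, surf in find_in_text(text, [spec]):
            assert text[s:e] == surf and e > s


# ---------------------------------------------------------------------------
# property: implementation == brute-force oracle on planted texts
# ---------------------------------------------------------------------------

_FILLERS = ["xq", "zz", "19", "7%", "(q)", "w."]
_SEPS = [" ", " - ", ", ", " 9 "]


def _render(surface: str, sep_choice: int, case_choice: int) -> str:
    seps = ["", "-", " "]
    out = []
    for i, ch in enumerate(surface):
        if ch in "- ":
            out.append(seps[(sep_choice + i) % 3])
        else:
            out.append(ch.upper() if (case_choice >> (i % 8)) & 1 else ch.lower())
    return "".join(out)


@st.composite
def planted_text(draw):
    k = draw(st.integers(1, 6))
    pieces = []
    for _ in range(k):
        if draw(st.booleans()):
            term = draw(st.sampled_from(ALL_TERMS))
            pieces.append(_render(term.surface, draw(st.integers(0, 2)), draw(st.integers(0, 255))))
        else:
            pieces.append(draw(st.sampled_from(_FILLERS)))
    sep = draw(st.sampled_from(_SEPS))
    return sep.join(pieces)


@given(planted_text())
@settings(max_examples=150, deadline=None)
def test_oracle_equivalence_on_planted_texts(text):
    """find_in_text equals an all-substrings scanner applying the rules directly."""
    for spec in ALL_TERMS:
        assert impl_spans(text, spec) == oracle_spans(text, spec), (text, spec.surface)


def _case_flip(text: str, mask: int) -> str:
    return "".join(
        (ch.upper() if (mask >> (i % 8)) & 1 else ch.lower()) if ch.isalpha() else ch
        for i, ch in enumerate(text)
    )


@given(planted_text(), st.booleans(), st.integers(0, 255))
@settings(max_examples=100, deadline=None)
def test_hyphen_and_case_invariance(text, swap_hyphens, case_mask):
    """Swapping hyphens for spaces and re-casing letters never changes the
    per-term match counts."""
    base = {spec.surface: len(impl_spans(text, spec)) for spec in ALL_TERMS}
    variant = _case_flip(text.replace("-", " ") if swap_hyphens else text, case_mask)
    alt = {spec.surface: len(impl_spans(variant, spec)) for spec in ALL_TERMS}
    assert base == alt, (text, variant)
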