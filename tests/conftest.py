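import pytest

from trialcoder.cohort_selection import select_cohort
from trialcoder.fixtures import adversarial_fixtures
from trialcoder.rct_identification import classify_all
from trialcoder.sexgender_coding import assign_all
from trialcoder.synthetic_data import GeneratorSpec, generate_registrations


@pytest.fixture(scope="session")
def small_dump():
    """A 300-record synthetic dump with its planted truth."""
    return generate_registrations(GeneratorSpec(n_studies=300, seed=11))


@pytest.fixture(scope="session")
def coded_small(small_dump):
    """The small dump run through the whole pipeline once."""
    registrations, truths = small_dump
    cohort, decisions, dedup_log = select_cohort(registrations)
    assignments = assign_all(cohort)
    classes = classify_all(cohort)
    return {
        "registrations": registrations,
        "truths": truths,
        "cohort": cohort,
        "decisions": decisions,
        "dedup_log": dedup_log,
        "assignments": assignments,
        "classes": classes,
    }


@pytest.fixture(scope="session")
def fixture_set():
    return adversarial_fixtures()
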