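import pytest

from msikit import CaseRecord, calibrated_config, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A deterministic synthetic cohort of ~2,300 complicated cases."""
    cohort, denom = generate_cohort(calibrated_config(seed=11, n_deliveries=20000))
    return cohort, denom


@pytest.fixture
def shock_case():
    return CaseRecord("shock-only", {"shock"})


def make_case(case_id="c", markers=(), died=False, **flags):
    return CaseRecord(case_id, set(markers), died=died, **flags)
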