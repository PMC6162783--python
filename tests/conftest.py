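import warnings

import pytest

import hiftload as hl


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition cohort (seed 7): 25 participants, ~30 sessions."""
    return hl.generate_cohort(hl.GeneratorConfig(seed=7))


@pytest.fixture(scope="session")
def default_loads(default_cohort):
    participants, sessions = default_cohort
    return hl.loads_to_frame(hl.quantify_sessions(participants, sessions))


@pytest.fixture(scope="session")
def clean_cohort():
    """Fully attended cohort with no missingness (seed 3)."""
    cfg = hl.GeneratorConfig(seed=3, adherence_rate=1.0,
                             missing_hr_rate=0.0, missing_rpe_rate=0.0)
    return hl.generate_cohort(cfg)


@pytest.fixture(scope="session")
def clean_loads(clean_cohort):
    participants, sessions = clean_cohort
    return hl.loads_to_frame(hl.quantify_sessions(participants, sessions))


@pytest.fixture(autouse=True)
def _no_unraisable_warning_noise():
    """Keep expected data-quality warnings from failing under -W error."""
    with warnings.catch_warnings():
        warnings.simplefilter("always")
        yield
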