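import dataclasses

import pytest
from hypothesis import settings

import cvreact as cv

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def scenarios():
    """Group-mean scenarios for the three study conditions."""
    return cv.reference_scenarios()


@pytest.fixture(scope="session")
def sl_noiseless(scenarios):
    """Sea-level scenario, no noise, 1 Hz."""
    return scenarios["SL"].noiseless(sample_rate_hz=1.0)


@pytest.fixture(scope="session")
def sl_processed(sl_noiseless):
    trial = cv.simulate_trial(sl_noiseless)
    return cv.normalize_mcav(cv.reduce_to_1s(trial))


@pytest.fixture(scope="session")
def analyze_noiseless(scenarios):
    """Run the full per-trial pipeline on a noiseless 1 Hz trial."""

    def _run(condition, **overrides):
        sc = scenarios[condition].noiseless(sample_rate_hz=1.0, **overrides)
        return cv.analyze_trial(cv.simulate_trial(sc))

    return _run


@pytest.fixture(scope="session")
def abp_scenario(scenarios):
    """Canonical threshold scenario: breakpoint at 42 mmHg, steep upper slope."""
    return dataclasses.replace(
        scenarios["SL"],
        t_abp_mmHg=42.0,
        sample_rate_hz=1.0,
    )
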