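import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lineup2ht import ModelSpec, fit_model, load_delay_study

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def study():
    """The packaged four-delay eyewitness identification dataset."""
    return load_delay_study()


@pytest.fixture(scope="session")
def conditions(study):
    return tuple(cond.condition_id for cond in study)


@pytest.fixture(scope="session")
def base_spec(conditions):
    return ModelSpec.base(conditions)


@pytest.fixture(scope="session")
def base_fit(study, base_spec):
    """Base-model ML fit (shared b) with Wald intervals."""
    return fit_model(study, base_spec, n_starts=20, seed=1)


@pytest.fixture(scope="session")
def equality_fits(study, base_spec):
    """Fits with dP, g and dA respectively equated across conditions."""
    return {
        family: fit_model(
            study, base_spec.with_equated(family), n_starts=20, seed=1,
            compute_ci=False,
        )
        for family in ("dP", "g", "dA")
    }


@pytest.fixture(scope="session")
def study_dp(base_fit, conditions):
    """Per-condition detection estimates and delays from the base fit."""
    delays = [0.0, 1.0, 8.0, 33.0]
    dp = [base_fit.params_for(cond).dP for cond in conditions]
    return delays, dp
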