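import numpy as np
import pytest

from asjm import (
    default_cohort_params,
    default_model_params,
    default_protocol,
    point_fit,
    simulate_cohort,
)
from asjm.cohort_sim import registry_model_params


@pytest.fixture(scope="session")
def truth_params():
    return default_model_params()


@pytest.fixture(scope="session")
def registry_params():
    return registry_model_params()


@pytest.fixture(scope="session")
def truth_fit(truth_params):
    """Point-mass 'fit' at the shipped generating parameters."""
    return point_fit(truth_params)


@pytest.fixture(scope="session")
def small_cohort():
    """An 80-patient default-protocol cohort with ground truth."""
    records, truth = simulate_cohort(
        default_cohort_params(80), default_protocol(), seed=424242
    )
    return records, truth


@pytest.fixture()
def flat_params(truth_params):
    """Null-association, constant-hazard parameters (closed-form world)."""
    p = truth_params.copy()
    p.alpha[:] = 0.0
    p.h0[:] = 0.1
    p.centers[:] = 0.0
    p.centers[0] = 65.0
    return p
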