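import numpy as np
import pytest

from citpk.covariates import SubjectCovariates
from citpk.defaults import (
    default_demographics,
    default_design,
    final_omega,
    final_sigma,
    final_theta,
)
from citpk.simulate import simulate_trial


@pytest.fixture(scope="session")
def theta():
    return final_theta()


@pytest.fixture(scope="session")
def omega():
    return final_omega()


@pytest.fixture(scope="session")
def sigma():
    return final_sigma()


@pytest.fixture(scope="session")
def reference_covariates():
    """A typical male EM/RM subject at the cohort means."""
    return SubjectCovariates(age=77.8, weight=71.5, bmi=26.3, sex=0,
                             cyp2c19_group=1)


@pytest.fixture(scope="session")
def trial(theta, omega, sigma):
    """One simulated 81-subject trial at the published parameters."""
    ds, truth = simulate_trial(
        default_design(), default_demographics(), theta, omega, sigma, seed=20210
    )
    return ds, truth


@pytest.fixture(scope="session")
def small_trial(theta, omega, sigma):
    """A 25-subject trial for quicker estimation tests."""
    design = default_design()
    design.n_subjects = 25
    ds, truth = simulate_trial(
        design, default_demographics(), theta, omega, sigma, seed=512
    )
    return ds, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
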