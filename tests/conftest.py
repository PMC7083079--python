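"""Shared fixtures: parameter sets, explored groups, small synthetic cohorts.

Everything is generated programmatically at test time; session scope keeps
the expensive pieces (exploration, cohort generation) to one computation.
"""

import numpy as np
import pytest

from ogttfit.cohort import CohortSpec, generate_cohort
from ogttfit.feasible import explore_feasible_set
from ogttfit.fitting import OptimizerSettings
from ogttfit.objective import CostWeights
from ogttfit.params import default_box, default_parameters
from ogttfit.solver import SolverSettings


@pytest.fixture(scope="session")
def box():
    return default_box()


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def rk4():
    return SolverSettings(method="rk4")


@pytest.fixture(scope="session")
def weights():
    return CostWeights()


@pytest.fixture(scope="session")
def fast_opt():
    """Reduced optimizer budgets for unit-scale fitting tests."""
    return OptimizerSettings(n_sa=400, n_pattern=300, n_gradient=200, n_stage=120)


@pytest.fixture(scope="session")
def groups(box):
    """Profile groups from a small feasible-set exploration."""
    return explore_feasible_set(box, n=4000, seed=7, k=4)


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Six noiseless virtual patients spanning the archetypes, with truth."""
    spec = CohortSpec(n_patients=6, seed=11, noise_sd_G=0.0, noise_sd_I=0.0)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def noisy_cohort():
    """Six virtual patients with default measurement noise, with truth."""
    spec = CohortSpec(n_patients=6, seed=13)
    return generate_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
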