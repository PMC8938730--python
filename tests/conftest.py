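"""Shared fixtures: parameter sets and session-scoped simulation runs.

The expensive multi-cohort experiments are computed once per session and
shared by the unit and acceptance tests.  All randomness is seeded.
"""

import numpy as np
import pytest

import segsim as ss
from segsim.fixtures import FixtureOptions


@pytest.fixture(scope="session")
def default_params():
    return ss.default_parameter_fixture()


@pytest.fixture(scope="session")
def frozen_toy():
    """Everything frozen: no deaths, no behavior/employment dynamics."""
    return ss.toy_parameter_fixture(FixtureOptions(
        zero_mortality=True, frozen_behaviors=True, frozen_employment=True))


@pytest.fixture(scope="session")
def static_toy():
    """Frozen dynamics and zero onset: state shares constant forever."""
    return ss.toy_parameter_fixture(FixtureOptions(
        zero_mortality=True, frozen_behaviors=True, frozen_employment=True,
        zero_onset=True))


def make_worker(**overrides):
    """A plausible reference worker; keyword overrides for variations."""
    base = dict(
        id=0, race="white", gender="female", age=40, family_history=True,
        bmi=27.0, smoking="never", physically_active=True,
        occupational_class="aide", employment="full_time",
        ever_unemployed=False, pwe=ss.PWEProfile(0.0, 0.0, 0.0),
        health_state="prehypertensive", on_medication=False, adherence="none",
    )
    base.update(overrides)
    return ss.Worker(**base)


@pytest.fixture(scope="session")
def experiment(default_params):
    """All five scenarios, both races, 10 cohorts x 10,000 workers."""
    cfg = ss.ExperimentConfig(n_cohorts=10, cohort_size=10_000, seed=1)
    return ss.run_experiment(cfg, default_params)


@pytest.fixture(scope="session")
def null_experiment():
    """Exchangeable population (race and gradient effects zeroed), scenario B."""
    params = ss.default_parameter_fixture(gradient_strength=0.0, race_effect=0.0)
    cfg = ss.ExperimentConfig(n_cohorts=10, cohort_size=4_000, seed=3,
                              scenarios=("B",))
    return ss.run_experiment(cfg, params)


@pytest.fixture(scope="session")
def sensitivity_result(default_params):
    """±25% one-way sensitivity on a reduced grid (status quo and scenario D)."""
    cfg = ss.ExperimentConfig(n_cohorts=3, cohort_size=4_000, seed=5,
                              scenarios=("status_quo", "D"))
    return ss.run_sensitivity(cfg, default_params)


@pytest.fixture(scope="session")
def trajectories(default_params):
    """Full per-worker state trajectories for one default-fixture cohort."""
    counts, traj = ss.run_cohort(3_000, "black", None, default_params, seed=7,
                                 return_trajectories=True)
    return counts, traj


def career_gap_se(result, scenario: str) -> float:
    """Monte-Carlo SE of the black−white career-average contrast."""
    b = result.cohort_career_averages(scenario, "black")
    w = result.cohort_career_averages(scenario, "white")
    return float(np.sqrt(b.var(ddof=1) / b.size + w.var(ddof=1) / w.size))
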