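import numpy as np
import pytest

from fisherman.agent import AgentParams, simulate_session
from fisherman.cohort import (
    CohortSpec,
    generate_cohort,
    simulate_cohort_experiment,
    subjects_frame,
)
from fisherman.fitting import fit_cohort
from fisherman.task import generate_schedule


@pytest.fixture(scope="session")
def schedule():
    return generate_schedule(seed=1)


@pytest.fixture(scope="session")
def agent_params():
    return AgentParams(
        vigour_cost=0.3,
        reward_sensitivity=0.25,
        noise_sd=0.2,
        rod_vigour_cost=0.3,
        min_latency=0.15,
        fatigue_drift=1e-4,
    )


@pytest.fixture(scope="session")
def session_record(schedule, agent_params):
    return simulate_session(schedule, agent_params, np.random.default_rng(2))


@pytest.fixture(scope="session")
def coupled_cohort():
    """A 20-subject cohort with apathy-S_R coupling 0.6, fully simulated
    and fitted; shared by the statistics tests."""
    spec = CohortSpec(n=20, seed=7, apathy_sr_coupling=0.6)
    profiles, params_list = generate_cohort(spec)
    subjects = subjects_frame(profiles, params_list, with_truth=True)
    records, schedules = simulate_cohort_experiment(profiles, params_list, seed=11)
    fits = fit_cohort(records, schedules, seed=3)
    return {
        "spec": spec,
        "profiles": profiles,
        "params_list": params_list,
        "subjects": subjects,
        "records": records,
        "schedules": schedules,
        "fits": fits,
    }
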