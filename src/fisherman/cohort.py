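"""Synthetic participant cohorts.

Generates demographics, questionnaire scores and agent parameters with the
statistical structure the behavioural findings presuppose: behavioural
apathy (bAMI) positively coupled to reward sensitivity S_R, social and
emotional apathy (sAMI/eAMI) uncoupled, and anxiety/depression (HADS)
mildly positively related to apathy. The apathy->S_R link is a lognormal
stand-in — the real generative relationship is unknown; only the observed
rank correlation is targeted — calibrated analytically so the realised
Spearman correlation matches the requested coupling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .agent import AgentParams, simulate_session
from .task import DEFAULT_PRICES, TaskSchedule, generate_schedule

SUBJECT_COLUMNS = [
    "participant_id", "age", "gender", "bAMI", "sAMI", "eAMI", "HADS_A", "HADS_D",
]
TRUTH_COLUMNS = [
    "true_vigour_cost", "true_reward_sensitivity", "true_noise_sd",
    "true_rod_vigour_cost", "true_fatigue_drift",
]


@dataclass(frozen=True)
class SubjectProfile:
    participant_id: str
    age: int
    gender: str  # "female" | "male"
    bAMI: float  # behavioural apathy, 0-4
    sAMI: float
    eAMI: float
    HADS_A: float  # anxiety, 0-21
    HADS_D: float  # depression, 0-21


@dataclass
class CohortSpec:
    """Recipe for one synthetic cohort.

    ``apathy_sr_coupling`` is the target Spearman correlation between bAMI
    and S_R. ``young_weight`` is the probability a participant falls in the
    young band (18-35) rather than the older band (36-65). Parameter priors
    are lognormal (location given as the median) except the fixed motor
    floor and the uniform fatigue drift.
    """

    n: int
    seed: int
    apathy_sr_coupling: float = 0.6
    young_weight: float = 1.0
    # apathy / questionnaire structure
    bami_mean: float = 1.5
    bami_sd: float = 0.9
    hads_coupling: float = 0.35  # Pearson link of HADS scores to apathy
    # agent-parameter priors
    vigour_cost_median: float = 0.3
    vigour_cost_log_sd: float = 0.2
    rod_vigour_cost_median: float = 0.3
    rod_vigour_cost_log_sd: float = 0.2
    reward_sensitivity_median: float = 0.25
    reward_sensitivity_log_sd: float = 0.7
    noise_sd_median: float = 0.2
    noise_sd_log_sd: float = 0.3
    min_latency: float = 0.15
    fatigue_drift_max: float = 2e-4
    id_prefix: str = "sub"


def _trunc_normal(rng: np.random.Generator, mean, sd, lo, hi, size=None) -> np.ndarray:
    a, b = (lo - np.asarray(mean)) / sd, (hi - np.asarray(mean)) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(spec: CohortSpec) -> tuple[list[SubjectProfile], list[AgentParams]]:
    """Draw a cohort of subject profiles and matching agent parameters.

    S_R is generated as exp(a + b * z + e) where z is the standardised bAMI
    score. For a bivariate-normal pair the Spearman correlation rho_s maps
    to the Pearson correlation r = 2 sin(pi * rho_s / 6); b and the noise
    scale are chosen so the latent log S_R has that Pearson correlation
    with z while keeping its total log-scale sd fixed.
    """
    if spec.n < 2:
        raise ValueError("cohort needs at least two participants")
    if abs(spec.apathy_sr_coupling) > 0.95:
        raise ValueError(
            f"coupling {spec.apathy_sr_coupling} infeasible under the lognormal link (|rho| <= 0.95)"
        )
    rng = np.random.default_rng(spec.seed)

    bami = _trunc_normal(rng, spec.bami_mean, spec.bami_sd, 0.0, 4.0, size=spec.n)
    z = (bami - bami.mean()) / bami.std(ddof=0)

    sigma_log = spec.reward_sensitivity_log_sd
    r = 2.0 * np.sin(np.pi * spec.apathy_sr_coupling / 6.0)
    b = r * sigma_log
    noise_scale = sigma_log * np.sqrt(max(0.0, 1.0 - r * r))
    log_sr = np.log(spec.reward_sensitivity_median) + b * z + rng.normal(0.0, noise_scale, spec.n)
    sr = np.exp(log_sr)

    sami = _trunc_normal(rng, spec.bami_mean, spec.bami_sd, 0.0, 4.0, size=spec.n)
    eami = _trunc_normal(rng, spec.bami_mean, spec.bami_sd, 0.0, 4.0, size=spec.n)
    hads_a = _trunc_normal(rng, 5.0 + 3.0 * spec.hads_coupling * z, 3.0, 0.0, 21.0)
    hads_d = _trunc_normal(rng, 4.0 + 3.0 * spec.hads_coupling * z, 3.0, 0.0, 21.0)

    young = rng.random(spec.n) < spec.young_weight
    age = np.where(
        young, rng.integers(18, 36, size=spec.n), rng.integers(36, 66, size=spec.n)
    )
    gender = np.where(rng.random(spec.n) < 0.5, "female", "male")

    cv = np.exp(rng.normal(np.log(spec.vigour_cost_median), spec.vigour_cost_log_sd, spec.n))
    cv_rod = np.exp(
        rng.normal(np.log(spec.rod_vigour_cost_median), spec.rod_vigour_cost_log_sd, spec.n)
    )
    noise = np.exp(rng.normal(np.log(spec.noise_sd_median), spec.noise_sd_log_sd, spec.n))
    drift = rng.uniform(0.0, spec.fatigue_drift_max, spec.n)

    profiles, params = [], []
    for i in range(spec.n):
        pid = f"{spec.id_prefix}-{i:03d}"
        profiles.append(
            SubjectProfile(
                participant_id=pid,
                age=int(age[i]),
                gender=str(gender[i]),
                bAMI=float(bami[i]),
                sAMI=float(sami[i]),
                eAMI=float(eami[i]),
                HADS_A=float(hads_a[i]),
                HADS_D=float(hads_d[i]),
            )
        )
        params.append(
            AgentParams(
                vigour_cost=float(cv[i]),
                reward_sensitivity=float(sr[i]),
                noise_sd=float(noise[i]),
                rod_vigour_cost=float(cv_rod[i]),
                min_latency=spec.min_latency,
                fatigue_drift=float(drift[i]),
            )
        )
    return profiles, params


def subjects_frame(
    profiles: list[SubjectProfile],
    params_list: list[AgentParams] | None = None,
    with_truth: bool = False,
) -> pd.DataFrame:
    df = pd.DataFrame([vars(p) for p in profiles], columns=SUBJECT_COLUMNS)
    if with_truth:
        if params_list is None:
            raise ValueError("params_list required when with_truth=True")
        df["true_vigour_cost"] = [p.vigour_cost for p in params_list]
        df["true_reward_sensitivity"] = [p.reward_sensitivity for p in params_list]
        df["true_noise_sd"] = [p.noise_sd for p in params_list]
        df["true_rod_vigour_cost"] = [p.rod_vigour_cost for p in params_list]
        df["true_fatigue_drift"] = [p.fatigue_drift for p in params_list]
    return df


def simulate_cohort_experiment(
    profiles: list[SubjectProfile],
    params_list: list[AgentParams],
    seed: int,
    price_set=DEFAULT_PRICES,
    interval_bounds: tuple[float, float] = (12.0, 13.0),
) -> tuple[pd.DataFrame, dict[str, TaskSchedule]]:
    """Simulate the full experiment for every participant.

    Each participant gets an independent schedule (own price order and
    rod-break times) and a counterbalanced environment order. Returns the
    concatenated long-format behavioural record and the schedules by id.
    """
    if len(profiles) != len(params_list):
        raise ValueError("profiles and params_list must be aligned")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(profiles))
    records = []
    schedules: dict[str, TaskSchedule] = {}
    for i, (profile, params) in enumerate(zip(profiles, params_list)):
        sched_seed = int(children[i].generate_state(1)[0] % (2**31))
        schedule = generate_schedule(
            seed=sched_seed,
            price_set=price_set,
            interval_bounds=interval_bounds,
            participant_id=profile.participant_id,
            env_order="high-first" if i % 2 == 0 else "low-first",
        )
        rng = np.random.default_rng(children[i].spawn(1)[0])
        records.append(simulate_session(schedule, params, rng))
        schedules[profile.participant_id] = schedule
    return pd.concat(records, ignore_index=True), schedules
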