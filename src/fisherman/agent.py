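"""Average-reward RL agent for free-operant action initiation.

Each [price, environment] pair is a state. An agent in a state chooses the
latency tau of its next tap by trading the vigour cost of acting quickly,
C_v / tau, against the opportunity cost of time (OCT): the reward foregone
while waiting, Rbar * tau, where Rbar is the average subjective reward per
second. Minimising C_v/tau + Rbar*tau with the self-consistent closure
Rbar = (u - C_v/tau*) / tau* (net reward rate achieved at the optimum)
gives the closed forms

    tau* = 2 C_v / u,        Rbar = u^2 / (4 C_v),

with u the subjective reward of one tap in that state. Subjective reward is
a power transform of the objective reward, u = (price * multiplier)^S_R:
with reward sensitivity S_R = 0 all states feel equally (and fully)
rewarding; large S_R spreads subjective value across states.

Rod-fixing taps earn nothing; they are invigorated purely by the
environment's reward rate (the cost of time spent not fishing), so the rod
latency minimises C_v_rod/tau + Rbar_env*tau with Rbar_env exogenous:
tau_rod = sqrt(C_v_rod / Rbar_env).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .task import EnvironmentSpec, TaskSchedule

RECORD_COLUMNS = [
    "participant_id",
    "environment",
    "block",
    "epoch_index",
    "price",
    "action_type",
    "timestamp_s",
    "latency_s",
    "cumulative_taps",
    "straddles_boundary",
]


@dataclass(frozen=True)
class AgentParams:
    """Generative/behavioural parameters of one subject.

    vigour_cost
        C_v, cost coefficient of fishing taps (subjective-reward-units x s).
    reward_sensitivity
        S_R >= 0, exponent of the subjective-reward power law.
    noise_sd
        Standard deviation of log-latency noise (log-seconds).
    rod_vigour_cost
        Cost coefficient for rod-fixing taps.
    min_latency
        Fastest motor latency (s); all latencies are clamped here.
    fatigue_drift
        Drift in log-latency per cumulative tap within an environment
        (generative only; the fitted model ignores it).
    """

    vigour_cost: float
    reward_sensitivity: float
    noise_sd: float = 0.2
    rod_vigour_cost: float = 0.3
    min_latency: float = 0.15
    fatigue_drift: float = 0.0

    def __post_init__(self) -> None:
        if self.vigour_cost <= 0 or self.rod_vigour_cost <= 0:
            raise ValueError("vigour costs must be positive")
        if self.min_latency <= 0:
            raise ValueError("min_latency must be positive")
        if self.noise_sd < 0 or self.reward_sensitivity < 0 or self.fatigue_drift < 0:
            raise ValueError("noise_sd, reward_sensitivity and fatigue_drift must be >= 0")


@dataclass(frozen=True)
class StateValue:
    price: float
    environment: str
    u: float  # subjective reward of one tap
    reward_rate: float  # Rbar, subjective reward per second (unclamped)
    tau_star: float  # optimal latency, clamped at min_latency
    oct_per_second: float  # == reward_rate; OCT over latency tau is Rbar*tau


def subjective_reward(price: float, environment_multiplier: float, reward_sensitivity: float) -> float:
    """u = (price * multiplier)^S_R; S_R = 0 collapses all rewards to 1."""
    if price < 0 or environment_multiplier < 0:
        raise ValueError("price and multiplier must be non-negative")
    if reward_sensitivity < 0:
        raise ValueError("reward_sensitivity must be >= 0")
    return float((price * environment_multiplier) ** reward_sensitivity)


def optimal_latency(u: float, vigour_cost: float, min_latency: float) -> float:
    """tau* = max(min_latency, 2 C_v / u), the self-consistent optimum."""
    if u <= 0:
        raise ValueError("subjective reward must be positive (rod taps use rod_fix_latency)")
    if vigour_cost <= 0:
        raise ValueError("vigour_cost must be positive")
    return max(float(min_latency), 2.0 * vigour_cost / u)


def state_reward_rate(u: float, vigour_cost: float) -> float:
    """Unclamped self-consistent reward rate Rbar = u^2 / (4 C_v)."""
    return float(u * u / (4.0 * vigour_cost))


def rod_fix_latency(env_reward_rate: float, rod_vigour_cost: float, min_latency: float) -> float:
    """tau_rod = max(min_latency, sqrt(C_v_rod / Rbar_env))."""
    if env_reward_rate <= 0:
        raise ValueError("environment reward rate must be positive (no finite optimum at 0)")
    if rod_vigour_cost <= 0:
        raise ValueError("rod_vigour_cost must be positive")
    return max(float(min_latency), float(np.sqrt(rod_vigour_cost / env_reward_rate)))


def environment_reward_rate(
    schedule: TaskSchedule, env: EnvironmentSpec, params: AgentParams
) -> float:
    """Environment-level reward rate: unweighted mean of the six per-state
    unclamped Rbar values. Drives rod-fixing, where no price is shown."""
    rates = [
        state_reward_rate(
            subjective_reward(p, env.multiplier, params.reward_sensitivity), params.vigour_cost
        )
        for p in schedule.price_set
    ]
    return float(np.mean(rates))


def state_table(schedule: TaskSchedule, params: AgentParams) -> pd.DataFrame:
    """One row per [price, environment] state (6 x 2 = 12 rows)."""
    rows = []
    for env in schedule.environments:
        for p in schedule.price_set:
            u = subjective_reward(p, env.multiplier, params.reward_sensitivity)
            rbar = state_reward_rate(u, params.vigour_cost)
            rows.append(
                StateValue(
                    price=p,
                    environment=env.label,
                    u=u,
                    reward_rate=rbar,
                    tau_star=optimal_latency(u, params.vigour_cost, params.min_latency),
                    oct_per_second=rbar,
                )
            )
    return pd.DataFrame(rows)


def sample_latency(
    tau_star: float,
    noise_sd: float,
    fatigue_drift: float,
    cumulative_taps: int,
    rng: np.random.Generator,
    min_latency: float = 0.0,
) -> float:
    """Lognormal latency around the optimum with multiplicative fatigue:
    tau = exp(log tau* + drift * taps + eps), eps ~ N(0, sd^2), floored at
    min_latency. Noiseless (sd = drift = 0) returns tau* exactly."""
    log_tau = np.log(tau_star) + fatigue_drift * cumulative_taps
    if noise_sd > 0:
        log_tau += rng.normal(0.0, noise_sd)
    return max(float(min_latency), float(np.exp(log_tau)))


def simulate_session(
    schedule: TaskSchedule, params: AgentParams, rng: np.random.Generator
) -> pd.DataFrame:
    """Simulate one participant playing both environments.

    The clock advances tap by tap. A fishing latency is chosen from the
    state at initiation; the tap is labelled with the state at completion
    and flagged if the interval spans a price change. When the clock
    reaches a rod-break time the pending fishing tap is abandoned and five
    rod taps are emitted at rod latencies (the task clock keeps running, so
    price epochs elapse underneath). Cumulative tap counts reset at each
    environment onset.
    """
    duration = schedule.duration
    rows: list[tuple] = []
    for env in schedule.environments:
        rbar_env = environment_reward_rate(schedule, env, params)
        tau_rod_star = rod_fix_latency(rbar_env, params.rod_vigour_cost, params.min_latency)
        t = 0.0
        cum = 0
        break_times = [b.time for b in schedule.rod_breaks]
        taps_required = [b.taps_required for b in schedule.rod_breaks]
        next_break = 0

        def emit_rod_episode(t: float, cum: int, n_taps: int) -> tuple[float, int]:
            for _ in range(n_taps):
                tau = sample_latency(
                    tau_rod_star, params.noise_sd, params.fatigue_drift, cum,
                    rng, params.min_latency,
                )
                t += tau
                cum += 1
                t_label = min(t, duration)
                epoch = schedule.epoch_at(t_label)
                rows.append(
                    (
                        schedule.participant_id, env.label, epoch.block_index,
                        schedule.epochs.index(epoch), np.nan, "rod", t, tau, cum - 1, 0,
                    )
                )
            return t, cum

        while True:
            if next_break < len(break_times) and break_times[next_break] <= t:
                t, cum = emit_rod_episode(t, cum, taps_required[next_break])
                next_break += 1
                continue
            if t >= duration:
                break
            epoch_i = schedule.epoch_at(t)
            u = subjective_reward(epoch_i.price, env.multiplier, params.reward_sensitivity)
            tau_star = optimal_latency(u, params.vigour_cost, params.min_latency)
            tau = sample_latency(
                tau_star, params.noise_sd, params.fatigue_drift, cum, rng, params.min_latency
            )
            t_next = t + tau
            if next_break < len(break_times) and break_times[next_break] <= t_next:
                # rod breaks before this tap completes: abandon it
                t = break_times[next_break]
                continue
            if t_next > duration:
                break
            epoch_j = schedule.epoch_at(t_next)
            straddles = int(epoch_j is not epoch_i)
            cum += 1
            rows.append(
                (
                    schedule.participant_id, env.label, epoch_j.block_index,
                    schedule.epochs.index(epoch_j), epoch_j.price, "fish",
                    t_next, tau, cum - 1, straddles,
                )
            )
            t = t_next

    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def total_yen(record: pd.DataFrame) -> float:
    """Yen earned in a session: sum of epoch prices over fishing taps."""
    fish = record[record["action_type"] == "fish"]
    return float(fish["price"].sum())
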