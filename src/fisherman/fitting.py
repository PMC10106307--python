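"""Maximum-likelihood recovery of agent parameters from behavioural records.

Observed fishing latencies are modelled as lognormal around the model's
optimal latency for the current state,

    log tau_i ~ Normal( log max(tau_min, 2 C_v / (price_i * mult_i)^S_R), sigma^2 ),

with free parameters (C_v, S_R, sigma). In log space the unclamped mean is
linear in log(price * multiplier) with slope -S_R and intercept log 2 C_v,
which makes the model identifiable from the 12-state design and provides
the warm start for the optimiser. Rod-fixing latencies are excluded (the
rod cost is not fitted) and the data are cleaned exactly as in the
statistical pipeline (straddling taps and scaled-MAD outliers removed per
environment), so both analysis arms see the same observations. The motor
floor tau_min is not a free parameter: it is set to 0.95 x the subject's
fastest retained latency, standing in for the task's separate
maximum-tapping-speed assessment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .agent import state_reward_rate, subjective_reward
from .stats import mad_outlier_mask
from .task import TaskSchedule

BOUNDS = ((-3.0, 3.0), (0.0, 4.0), (-4.0, 1.0))  # log C_v, S_R, log sigma
N_RESTARTS = 10
MIN_OBSERVATIONS = 50


@dataclass
class FitResult:
    participant_id: str
    vigour_cost_hat: float
    reward_sensitivity_hat: float
    noise_sd_hat: float
    log_likelihood: float
    n_obs: int
    converged: bool
    n_restarts_used: int
    bic_model: float
    bic_null: float
    tau_min_used: float


def _clean_latencies(record: pd.DataFrame, mad_k: float = 3.0) -> pd.DataFrame:
    fish = record[
        (record["action_type"] == "fish") & (record["straddles_boundary"] == 0)
    ]
    keep = []
    for _, group in fish.groupby("environment", sort=False):
        keep.append(group[~mad_outlier_mask(group["latency_s"].to_numpy(), k=mad_k)])
    return pd.concat(keep).sort_index()


def _negloglik(theta: np.ndarray, y: np.ndarray, log_pm: np.ndarray, tau_min: float) -> float:
    log_cv, s_r, log_sigma = theta
    sigma = np.exp(log_sigma)
    mu = np.maximum(np.log(tau_min), np.log(2.0) + log_cv - s_r * log_pm)
    resid = (y - mu) / sigma
    return float(y.size * (log_sigma + 0.5 * np.log(2.0 * np.pi)) + 0.5 * np.sum(resid**2))


def fit_agent(
    record: pd.DataFrame,
    schedule: TaskSchedule,
    n_restarts: int = N_RESTARTS,
    seed: int = 0,
    mad_k: float = 3.0,
    min_obs: int = MIN_OBSERVATIONS,
) -> FitResult:
    """Fit (C_v, S_R, sigma) to one subject's fishing latencies.

    Multi-restart bounded L-BFGS-B over (log C_v, S_R, log sigma): one warm
    start from the log-log regression of latency on price x multiplier,
    plus seeded random restarts within the bounds. A fit that never reaches
    optimiser convergence is returned flagged, not raised.
    """
    clean = _clean_latencies(record, mad_k=mad_k)
    if len(clean) < min_obs:
        raise ValueError(f"only {len(clean)} usable fishing latencies (need >= {min_obs})")

    mult = {env.label: env.multiplier for env in schedule.environments}
    pm = clean["price"].to_numpy() * clean["environment"].map(mult).to_numpy()
    log_pm = np.log(pm)
    y = np.log(clean["latency_s"].to_numpy())
    tau_min = 0.95 * float(np.min(clean["latency_s"]))

    # warm start from the unclamped log-log line: y ~ log 2C_v - S_R log(pm)
    slope, intercept = np.polyfit(log_pm, y, 1)
    s_r0 = float(np.clip(-slope, BOUNDS[1][0], BOUNDS[1][1]))
    log_cv0 = float(np.clip(intercept - np.log(2.0), BOUNDS[0][0], BOUNDS[0][1]))
    resid0 = y - (np.log(2.0) + log_cv0 - s_r0 * log_pm)
    log_sig0 = float(np.clip(np.log(max(np.std(resid0), 1e-6)), BOUNDS[2][0], BOUNDS[2][1]))

    rng = np.random.default_rng(seed)
    starts = [np.array([log_cv0, s_r0, log_sig0])]
    lo = np.array([b[0] for b in BOUNDS])
    hi = np.array([b[1] for b in BOUNDS])
    for _ in range(n_restarts - 1):
        starts.append(lo + rng.random(3) * (hi - lo))

    best = None
    converged = False
    used = 0
    for x0 in starts:
        used += 1
        res = minimize(
            _negloglik, x0, args=(y, log_pm, tau_min),
            method="L-BFGS-B", bounds=BOUNDS, tol=1e-8,
        )
        if best is None or res.fun < best.fun:
            best = res
        converged = converged or bool(res.success)

    log_cv, s_r, log_sigma = best.x
    ll = -best.fun
    n = y.size
    # null model: one state-independent lognormal latency (2 parameters)
    sig_null = max(float(np.std(y)), np.exp(BOUNDS[2][0]))
    ll_null = -n * (np.log(sig_null) + 0.5 * np.log(2.0 * np.pi)) - 0.5 * np.sum(
        ((y - y.mean()) / sig_null) ** 2
    )
    return FitResult(
        participant_id=str(record["participant_id"].iloc[0]),
        vigour_cost_hat=float(np.exp(log_cv)),
        reward_sensitivity_hat=float(s_r),
        noise_sd_hat=float(np.exp(log_sigma)),
        log_likelihood=float(ll),
        n_obs=int(n),
        converged=converged,
        n_restarts_used=used,
        bic_model=float(3 * np.log(n) - 2 * ll),
        bic_null=float(2 * np.log(n) - 2 * ll_null),
        tau_min_used=tau_min,
    )


def delta_oct(fit: FitResult, schedule: TaskSchedule) -> float:
    """Modelled opportunity-cost span: reward rate of the highest state
    (max price, high environment) minus the lowest (min price, low
    environment), under the fitted parameters."""
    prices = schedule.price_set
    mult = {env.label: env.multiplier for env in schedule.environments}
    u_hi = subjective_reward(max(prices), mult["high"], fit.reward_sensitivity_hat)
    u_lo = subjective_reward(min(prices), mult["low"], fit.reward_sensitivity_hat)
    return state_reward_rate(u_hi, fit.vigour_cost_hat) - state_reward_rate(
        u_lo, fit.vigour_cost_hat
    )


def median_latency_highest_state(
    record: pd.DataFrame, schedule: TaskSchedule, min_obs: int = 5
) -> float:
    """Median non-straddling fishing latency in the highest-reward state
    (max price, high environment); NaN with a diagnostic if under-observed."""
    max_price = max(schedule.price_set)
    fish = record[
        (record["action_type"] == "fish")
        & (record["straddles_boundary"] == 0)
        & (record["environment"] == "high")
        & (np.isclose(record["price"], max_price))
    ]
    if len(fish) < min_obs:
        import warnings

        warnings.warn(
            f"{record['participant_id'].iloc[0] if len(record) else '?'}: "
            f"only {len(fish)} latencies in the highest state (need >= {min_obs})"
        )
        return float("nan")
    return float(fish["latency_s"].median())


def fit_cohort(
    records: pd.DataFrame,
    schedules: dict[str, TaskSchedule],
    seed: int = 0,
    n_restarts: int = N_RESTARTS,
    mad_k: float = 3.0,
) -> pd.DataFrame:
    """Fit every participant; returns the fits table used downstream."""
    rows = []
    for i, (pid, record) in enumerate(records.groupby("participant_id", sort=True)):
        schedule = schedules[pid]
        fit = fit_agent(record, schedule, n_restarts=n_restarts, seed=seed + i, mad_k=mad_k)
        rows.append(
            {
                "participant_id": pid,
                "vigour_cost_hat": fit.vigour_cost_hat,
                "reward_sensitivity_hat": fit.reward_sensitivity_hat,
                "noise_sd_hat": fit.noise_sd_hat,
                "log_likelihood": fit.log_likelihood,
                "n_obs": fit.n_obs,
                "converged": fit.converged,
                "bic_model": fit.bic_model,
                "bic_null": fit.bic_null,
                "delta_oct": delta_oct(fit, schedule),
                "median_latency_highest_state": median_latency_highest_state(record, schedule),
            }
        )
    return pd.DataFrame(rows)
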