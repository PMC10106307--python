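# fisherman

Average-reward reinforcement-learning modelling of *free-operant action
initiation*: when people are free to act whenever they like, what sets
the latency of the next action, and why do apathetic individuals time
their actions differently?

The package implements the complete analysis chain around a two-
environment foraging task (the "Fisherman Game"): participants tap to
catch fish at a price that changes every 12–13 s, in a high-value and a
low-value environment, with occasional unrewarded rod-fixing episodes.
It provides

- a **task simulator** (per-participant schedules: price order, epoch
  durations, rod breaks),
- an **opportunity-cost agent**: each `[price, environment]` pair is a
  state with subjective reward `u = (price × multiplier)^S_R`; the chosen
  latency minimises the vigour cost `C_v/τ` plus the opportunity cost of
  time `R̄·τ`, giving `τ* = 2C_v/u` and `R̄ = u²/(4C_v)`; rod fixing is
  invigorated purely by the environment's reward rate,
  `τ_rod = √(C_v_rod/R̄_env)`,
- a **synthetic cohort** generator whose behavioural apathy scores
  (bAMI) are coupled to reward sensitivity `S_R` at a calibrated rank
  correlation, with uncoupled social/emotional apathy and HADS
  covariates,
- **maximum-likelihood fitting** of `(C_v, S_R, σ)` per subject, with
  the derived ΔOCT (modelled opportunity-cost span) and highest-state
  median latency,
- the **statistical pipeline**: scaled-MAD outlier removal, a REML
  linear mixed model of log latency on price, environment and cumulative
  taps with subject-level random slopes, apathy GLMs with age/gender/HADS
  covariates, the paired rod-fixing test and a Spearman correlation
  battery.

The model and analyses are described in [docs/methods.md](docs/methods.md).

## Worked example

The numbered scripts under `analysis/` run the study-scale analysis (45
young adults, apathy–sensitivity coupling 0.6) and write their outputs
under `results/run-default/`:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_fit_agents.py
python analysis/03_latency_analysis.py
python analysis/04_report.py
```

which prints (master seed 1):

```
cohort: 45 subjects, realised bAMI-S_R Spearman = 0.70 (target 0.6)
simulated 34063 taps (31363 fishing), ~756 per subject
fitted 45 subjects; 45 converged
recovery Spearman: S_R 0.997, C_v 0.994
LMM fixed effects on log latency:
  price: beta = -0.2367 [-0.2722, -0.2011], p = 5.95e-39
  environment: beta = -0.6844 [-0.8239, -0.5449], p = 6.93e-22
  cumulative_taps: beta = +7.274e-05 [3.445e-05, 0.000111], p = 0.000197
rod fixing, high - low: t(44) = -9.07, p = 1.26e-11
Spearman correlations with bAMI (young band):
  price_slope: rho = -0.70, p = 8.45e-08
  reward_sensitivity_hat: rho = +0.70, p = 1.06e-07
  delta_oct: rho = +0.64, p = 1.8e-06
  median_latency_highest_state: rho = -0.45, p = 0.0021
bAMI ~ price slope GLM: beta = -3.97, t = -4.72, p = 3.06e-05
```

Reading these numbers: latencies shorten as the price rises and in the
high-value environment (negative price and environment betas on log
latency), responding drifts slower over a session (positive
cumulative-taps beta), and even the unrewarded rod fixing is faster where
the opportunity cost of time is high (negative paired t). At the
individual level, higher behavioural apathy goes with a more negative
price slope (stronger latency adjustment to reward), higher fitted reward
sensitivity, a larger modelled opportunity-cost span — and, because the
highest-reward state feels most valuable to reward-sensitive individuals,
*faster* responding in that one state (negative median-latency
correlation).

The same chain is available as one command and as a console script:

```bash
fisherman run --config config.yaml      # cohort -> simulate -> fit -> analyse
fisherman report --run-dir results/run-default
```

plus stage-level subcommands (`fisherman schedule / simulate / cohort /
fit / analyse`). All randomness derives from the single master seed in
the config; a rerun of the same configuration is byte-identical.

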