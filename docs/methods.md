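# Methods

## The decision problem

The package models free-operant action initiation in a two-environment
foraging task (the "Fisherman Game"). A participant taps to catch fish;
each tap earns the currently displayed price (six prices between ¥0.1 and
¥2.5 per tap, changing every 12–13 s, each seen four times per
environment). The two environments differ only in what the fictional yen
are worth (reaching ¥3000 pays £4.00 in the high-value environment, £0.50
in the low-value one), and six times per environment the rod breaks and
must be fixed with five unrewarded taps. Nothing prompts action: when to
tap is entirely the participant's choice.

The agent treats each `[price, environment]` pair as a state of an
average-reward decision process. Delaying the next tap by a latency τ
forgoes reward at the state's average rate R̄ — the opportunity cost of
time (OCT), R̄·τ — while acting quickly incurs a vigour cost C_v/τ that
grows as τ approaches the motor floor. The chosen latency minimises

    cost(τ) = C_v / τ + R̄ · τ.

R̄ is closed self-consistently as the net reward rate achieved at the
optimum, R̄ = (u − C_v/τ*)/τ*, which yields the closed forms

    τ* = 2 C_v / u,    R̄ = u² / (4 C_v),

verified in the tests against an independent damped fixed-point iteration
(τ ← √(C_v/R̄(τ))) and a grid minimisation of the cost curve. τ* is
clamped below at the motor floor τ_min.

Subjective reward is a one-parameter power transform of the objective
reward,

    u = (price × multiplier)^{S_R},

with reward sensitivity S_R ≥ 0. S_R = 0 collapses all states to u = 1
(all rewards feel equally, and fully, rewarding — the motivated
phenotype); large S_R spreads subjective value across states, so latency
tracks price and environment strongly (the apathetic phenotype). The
environment multiplier is 1 for the high-value environment and 0.125 for
the low-value one — the ratio of the two stated payments (£0.50/£4.00),
the only quantitative asymmetry between environments available.

Rod fixing earns nothing, so its latency is driven purely by the cost of
time spent away from fishing: with the environment's reward rate R̄_env
taken as exogenous, τ_rod = √(C_v_rod / R̄_env), again clamped at τ_min.
R̄_env is the unweighted mean of the six per-state unclamped rates of
that environment (no price is displayed while the rod is broken, so only
environment-level information is assumed available). This predicts faster
rod fixing in the high-value environment for any agent with S_R > 0.

The model deliberately contains no learning: the task displays the
current price and environment value at all times, so reward rates are
treated as known. Latencies are emitted, not chosen from a discretised
menu; there is no speed–accuracy trade-off.

## Generative noise model

Observed latencies are lognormal around the optimum:

    τ = exp( log τ* + δ·(cumulative taps) + ε ),   ε ~ N(0, σ²),

floored at τ_min. The multiplicative form matches the analysis pipeline,
which models log latencies. δ is a slow fatigue drift (log-latency per
tap within an environment); it is generative only — the fitted model
ignores it, so the recovery suite doubles as a mis-specification check,
and the mixed model's cumulative-taps term has a real target to find.

During simulation the clock runs continuously through each environment.
A fishing latency is sampled from the state at initiation; the tap is
labelled with the state at completion and flagged (`straddles_boundary`)
when the interval spans a price change — flagged taps are excluded from
both fitting and the mixed model. When the clock reaches a rod-break
time, the pending fishing tap is abandoned and five rod taps are emitted;
the price clock keeps running underneath, as in the task. Cumulative tap
counts reset at each environment onset.

## Task schedule generator

Per participant: a random permutation of four copies of each of the six
prices (24 epochs = 2 blocks × 12 changes), epoch durations uniform on
[12, 13] s, and six rod-break times uniform over the environment with a
minimum spacing of 10 s (resampled on violation, so fix episodes cannot
overlap). Price order, durations and break times are shared by the two
environments of one participant; environment order alternates across
participants. Epoch intervals are half-open, `[start, start+duration)`,
and time is measured from each environment's onset. The four interior
prices default to {0.5, 1.0, 1.5, 2.0}: the task fixes only the endpoints
(¥0.1, ¥2.5) and the count, so an even grid is used and the set is
configurable.

## Synthetic cohort

The cohort generator produces the *structure the behavioural findings
presuppose*, not a mechanism claimed by anyone: behavioural apathy (bAMI,
0–4) coupled to reward sensitivity at a target Spearman ρ; social and
emotional apathy (sAMI/eAMI) uncoupled from everything behavioural;
anxiety/depression (HADS, 0–21) mildly positively related to apathy; ages
uniform within the young (18–35) and older (36–65) bands.

bAMI is truncated normal on [0, 4] (mean 1.5, sd 0.9, matching the scale
and exemplar magnitudes of the instrument). S_R is lognormal around a
median of 0.25 with the latent link

    log S_R = log 0.25 + b·z(bAMI) + e,

where z is the standardised bAMI score, and (b, sd(e)) are set
analytically from the target Spearman ρ using the bivariate-normal
rank-correlation identity r = 2·sin(πρ/6), holding the total log-scale sd
at 0.7. The calibration is validated empirically (realised ρ within ±0.1
of target at n ≥ 40, averaged over seeds). Couplings |ρ| > 0.95 are
rejected as infeasible under this link.

Parameter priors (units in the subjective-reward currency and seconds):

| parameter | prior | rationale |
|---|---|---|
| C_v | LogNormal(log 0.3, 0.2) | with the u values spanned by the task this puts τ* at ≈0.45–1.7 s, i.e. sub-second-to-seconds tapping and ≈800 latencies per subject in ~10 min of environments |
| C_v_rod | LogNormal(log 0.3, 0.2) | rod latencies ≈0.5–1 s, slower in the poor environment |
| σ | LogNormal(log 0.2, 0.3) | ≈20% latency variability, typical for repeated simple actions |
| τ_min | 0.15 s fixed | fastest comfortable tapping rate |
| δ | Uniform(0, 2×10⁻⁴) per tap | up to ~0.16 log units of slowing over a session |
| S_R | lognormal link above, median 0.25, log-sd 0.7 | see below |

Two deliberate calibration choices. First, C_v is centred well below 1:
because u = (price × multiplier)^{S_R} is mostly below 1, a unit vigour
cost would give optimal latencies of tens of seconds in the poor states —
a degenerate session with almost no taps. Second, the motor-cost spread
(log-sd 0.2) is kept narrower than the reward-sensitivity spread (log-sd
0.7): individual differences are carried by the motivational parameter of
interest, with relatively homogeneous motor costs across healthy young
adults. This is what makes apathy visible not only in the price slope but
also in the *absolute* latency of the highest-reward state — under the
model, high-S_R individuals have the largest u in that state and
therefore the shortest τ*, so apathy correlates negatively with the
highest-state median latency even though apathy slows responding
elsewhere.

What the generator does **not** emulate: item-level psychometrics of the
questionnaires; the age moderation of the apathy effect (older cohorts
are generated by the same mechanism — the moderation is an empirical
finding, not a stated mechanism, so it is not built in); attention
lapses, pauses, or strategic non-responding; learning or exploration.
Passing tests therefore show that the pipeline recovers the structure it
was pointed at, under its own noise model — not that real participants
obey it.

## Model fitting

Per subject, maximum likelihood of the lognormal latency model

    log τ_i ~ N( log max(τ_min, 2 C_v / (price_i·mult_i)^{S_R}), σ² )

over cleaned fishing latencies (straddling taps and scaled-MAD outliers
removed per environment — the same exclusions as the statistical
pipeline). Rod latencies are not fitted. τ_min is fixed at 0.95 × the
subject's fastest retained latency, standing in for the task's separate
maximum-tapping-speed assessment. Optimisation is bounded L-BFGS-B over
(log C_v, S_R, log σ) with bounds [−3, 3] × [0, 4] × [−4, 1], tolerance
1e−8, one warm start from the log-log regression (slope −S_R, intercept
log 2C_v) plus nine seeded random restarts. The lower bound on log σ also
regularises the noiseless limit. BIC is reported against a
state-independent lognormal null (one latency, 2 parameters vs 3).

Derived per-subject quantities: ΔOCT = R̄(max price, high) − R̄(min
price, low) under the fitted parameters — the modelled span of subjective
opportunity cost — and the median cleaned latency in the highest-reward
state (≥ 5 observations required, else missing).

## Statistical pipeline

1. **Outliers**: an observation is an outlier when |y − median| > 3 ×
   1.4826 × MAD, applied to raw latencies per subject per environment,
   before the log transform. The 1.4826 factor is the usual
   normal-consistency scaling; a constant vector flags nothing (strict
   inequality against a zero MAD).
2. **Mixed model**: natural-log latency ~ price + environment dummy
   (high = 1, so negative means faster under high OCT) + cumulative taps,
   REML, with correlated subject-level random intercept and all three
   slopes (unstructured covariance; diagonal fallback on
   non-convergence). Cumulative taps are internally rescaled (/100) for
   optimiser conditioning and reported per tap. Subject-level sensitivity
   = total (fixed + predicted random) slope.
3. **Apathy GLMs**: OLS of an apathy outcome on one sensitivity slope
   plus age, gender (binary indicator) and the two HADS subscales, within
   an age band (young 18–35, older 36–65, or all).
4. **Rod fixing**: paired t across subjects of mean log rod latency,
   high minus low environment (t = 0, p = 1 returned for degenerate
   zero-variance pairings).
5. **Correlation battery**: Spearman ρ of bAMI with the subject price
   slope, fitted S_R, ΔOCT and the highest-state median latency.

## Problem sizes and determinism

The shipped analyses use a 45-subject young cohort with coupling 0.6
(≈750 taps per subject), a 30-subject parameter-recovery run, and
20-seed replications for the null checks — sizes chosen to match the
study's young-adult arm while keeping every analysis re-runnable in
minutes on one core. All randomness flows from one master seed through
`numpy.random.SeedSequence` spawning, stage by stage; CSV/JSON outputs
use fixed float formatting, so a rerun of the same configuration is
byte-identical.

## Known limitations

- The subjective-reward transform, the self-consistent closure of R̄ and
  the lognormal likelihood are this package's concrete commitments where
  the underlying theory admits alternatives (e.g. a smooth vigour penalty
  near the motor floor instead of a hard clamp, softmax latency choice,
  learned reward rates).
- The apathy→S_R link is a statistical stand-in targeting a rank
  correlation; it carries no mechanistic claim.
- σ is shared between fishing and rod taps in generation, but rod taps
  are excluded from fitting; C_v_rod is never estimated.
- The mixed model's diagonal fallback changes the random-effects
  covariance, not the fixed-effect definitions; fits that need it are
  flagged via `fit_method`.
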