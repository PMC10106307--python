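"""Fisherman-Game task schedules.

A session consists of two environments (high- and low-value water) played
back to back. Within an environment the price paid per fish changes every
12-13 s, drawn from a six-price set; each price is seen exactly four times
(24 epochs = 2 blocks x 12 price changes). The fishing rod breaks six times
per environment and must be fixed with five unrewarded taps. Price order,
epoch durations and rod-break times are randomised per participant but
identical across the two environments of one participant, so the only
difference between environments is the subjective value of earnings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

DEFAULT_PRICES: tuple[float, ...] = (0.1, 0.5, 1.0, 1.5, 2.0, 2.5)
#: subjective scaling of yen in each environment; the ratio is the printed
#: payment asymmetry (GBP 0.50 / GBP 4.00 for the same yen total).
HIGH_MULTIPLIER = 1.0
LOW_MULTIPLIER = 0.125
YEN_TARGET = 3000.0

ROD_BREAKS_PER_ENV = 6
ROD_TAPS_REQUIRED = 5
ROD_BREAK_MIN_SPACING = 10.0  # seconds; avoids overlapping fix episodes


@dataclass(frozen=True)
class PriceEpoch:
    """One constant-price interval; [start_time, start_time + duration)."""

    price: float
    start_time: float
    duration: float
    block_index: int  # 1 or 2

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration

    def contains(self, t: float) -> bool:
        return self.start_time <= t < self.end_time


@dataclass(frozen=True)
class EnvironmentSpec:
    label: str  # "high" | "low"
    multiplier: float
    yen_target: float = YEN_TARGET
    payment: float = 4.00  # pounds for reaching the yen target


@dataclass(frozen=True)
class RodBreakEvent:
    time: float  # seconds from environment onset
    taps_required: int = ROD_TAPS_REQUIRED


@dataclass(frozen=True)
class TaskState:
    """State returned by :func:`state_at`."""

    price: float
    environment: str
    in_rod_break: bool = False


@dataclass
class TaskSchedule:
    """Per-participant schedule, shared between the two environments.

    ``epochs`` and ``rod_breaks`` are identical in both environments by task
    design, so a single copy is stored and the environment only contributes
    its value multiplier.
    """

    participant_id: str
    seed: int
    epochs: list[PriceEpoch]
    environments: tuple[EnvironmentSpec, EnvironmentSpec]
    rod_breaks: list[RodBreakEvent] = field(default_factory=list)

    @property
    def price_sequence(self) -> list[float]:
        return [e.price for e in self.epochs]

    @property
    def durations(self) -> list[float]:
        return [e.duration for e in self.epochs]

    @property
    def duration(self) -> float:
        """Total environment duration (seconds)."""
        return self.epochs[-1].end_time if self.epochs else 0.0

    @property
    def price_set(self) -> list[float]:
        return sorted(set(self.price_sequence))

    def environment(self, label: str) -> EnvironmentSpec:
        for env in self.environments:
            if env.label == label:
                return env
        raise KeyError(f"no environment labelled {label!r}")

    def epoch_at(self, t: float) -> PriceEpoch:
        """Epoch covering time ``t`` (half-open intervals)."""
        if not 0.0 <= t <= self.duration:
            raise ValueError(
                f"t={t:.3f}s outside environment duration [0, {self.duration:.3f}]"
            )
        if t == self.duration:  # closing boundary belongs to the last epoch
            return self.epochs[-1]
        starts = [e.start_time for e in self.epochs]
        idx = int(np.searchsorted(starts, t, side="right")) - 1
        return self.epochs[idx]

    def epoch_index_at(self, t: float) -> int:
        return self.epochs.index(self.epoch_at(t))

    # -- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "participant_id": self.participant_id,
            "seed": int(self.seed),
            "price_sequence": [float(p) for p in self.price_sequence],
            "durations": [float(d) for d in self.durations],
            "rod_break_times": [float(b.time) for b in self.rod_breaks],
            "rod_taps_required": self.rod_breaks[0].taps_required
            if self.rod_breaks
            else ROD_TAPS_REQUIRED,
            "environments": [
                {"label": e.label, "multiplier": e.multiplier, "payment": e.payment}
                for e in self.environments
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "TaskSchedule":
        epochs = _build_epochs(d["price_sequence"], d["durations"])
        envs = tuple(
            EnvironmentSpec(label=e["label"], multiplier=e["multiplier"], payment=e["payment"])
            for e in d["environments"]
        )
        taps = int(d.get("rod_taps_required", ROD_TAPS_REQUIRED))
        breaks = [RodBreakEvent(time=float(t), taps_required=taps) for t in d["rod_break_times"]]
        return cls(
            participant_id=d["participant_id"],
            seed=int(d["seed"]),
            epochs=epochs,
            environments=envs,  # type: ignore[arg-type]
            rod_breaks=breaks,
        )

    @classmethod
    def from_json(cls, path) -> "TaskSchedule":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _build_epochs(prices: Sequence[float], durations: Sequence[float]) -> list[PriceEpoch]:
    epochs: list[PriceEpoch] = []
    t = 0.0
    n = len(prices)
    for i, (p, d) in enumerate(zip(prices, durations)):
        block = 1 if i < n // 2 else 2
        epochs.append(PriceEpoch(price=float(p), start_time=t, duration=float(d), block_index=block))
        t += float(d)
    return epochs


def generate_schedule(
    seed: int,
    price_set: Sequence[float] = DEFAULT_PRICES,
    repeats: int = 4,
    interval_bounds: tuple[float, float] = (12.0, 13.0),
    participant_id: str | None = None,
    env_order: str = "high-first",
) -> TaskSchedule:
    """Draw one participant's schedule.

    The price order is a random permutation of ``repeats`` copies of each of
    the six prices; epoch durations are uniform on ``interval_bounds``. Both
    are shared by the two environments. Rod-break times are attached by
    :func:`generate_rod_breaks` using a sub-seed derived from ``seed``.
    """
    price_set = tuple(float(p) for p in price_set)
    if len(price_set) != 6:
        raise ValueError(f"price_set must contain six prices, got {len(price_set)}")
    if len(set(price_set)) != 6:
        raise ValueError("price_set values must be distinct")
    if any(p <= 0 for p in price_set):
        raise ValueError("all prices must be positive")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    lo, hi = float(interval_bounds[0]), float(interval_bounds[1])
    if not (0 < lo <= hi):
        raise ValueError(f"degenerate interval bounds {interval_bounds}")

    ss = np.random.SeedSequence(seed)
    ss_prices, ss_breaks = ss.spawn(2)
    rng = np.random.default_rng(ss_prices)

    prices = np.repeat(price_set, repeats)
    rng.shuffle(prices)
    durations = rng.uniform(lo, hi, size=prices.size)
    epochs = _build_epochs(prices.tolist(), durations.tolist())

    if env_order == "high-first":
        envs = (
            EnvironmentSpec("high", HIGH_MULTIPLIER, payment=4.00),
            EnvironmentSpec("low", LOW_MULTIPLIER, payment=0.50),
        )
    elif env_order == "low-first":
        envs = (
            EnvironmentSpec("low", LOW_MULTIPLIER, payment=0.50),
            EnvironmentSpec("high", HIGH_MULTIPLIER, payment=4.00),
        )
    else:
        raise ValueError(f"env_order must be 'high-first' or 'low-first', got {env_order!r}")

    schedule = TaskSchedule(
        participant_id=participant_id if participant_id is not None else f"sub-{seed}",
        seed=int(seed),
        epochs=epochs,
        environments=envs,
    )
    schedule.rod_breaks = generate_rod_breaks(
        int(ss_breaks.generate_state(1)[0] % (2**31)), schedule
    )
    return schedule


def generate_rod_breaks(
    seed: int,
    schedule: TaskSchedule,
    n_breaks: int = ROD_BREAKS_PER_ENV,
    taps_required: int = ROD_TAPS_REQUIRED,
    min_spacing: float = ROD_BREAK_MIN_SPACING,
) -> list[RodBreakEvent]:
    """Draw rod-break times, uniform over the environment with a minimum
    spacing between breaks (resampled on violation). The same list applies
    to both environments of the participant."""
    rng = np.random.default_rng(seed)
    duration = schedule.duration
    for _ in range(10_000):
        times = np.sort(rng.uniform(0.0, duration, size=n_breaks))
        if np.all(np.diff(times) >= min_spacing):
            return [RodBreakEvent(time=float(t), taps_required=taps_required) for t in times]
    raise RuntimeError("could not place rod breaks with the requested spacing")


def state_at(
    schedule: TaskSchedule,
    environment_label: str,
    t: float,
    rod_episodes: Sequence[tuple[float, float]] | None = None,
) -> TaskState:
    """State at time ``t`` of one environment.

    ``rod_episodes`` are resolved (start, end) intervals of rod-fix episodes
    from a simulated or recorded session; if ``t`` falls inside one, a
    rod-break marker is returned (no price is displayed while the rod is
    broken).
    """
    schedule.environment(environment_label)  # validates the label
    epoch = schedule.epoch_at(t)  # validates t
    if rod_episodes is not None:
        for start, end in rod_episodes:
            if start <= t < end:
                return TaskState(price=float("nan"), environment=environment_label, in_rod_break=True)
    return TaskState(price=epoch.price, environment=environment_label, in_rod_break=False)
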