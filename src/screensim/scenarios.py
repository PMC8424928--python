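"""Arrival plans, customer-type mix, and the three improvement policies.

The day origin t = 0 is the 7:00 AM opening.  Observed check-in behaviour is
summarized by an hourly histogram over 2342 customers: 16 arrived before
opening, 1222 during 7-8 AM (52.2%), 877 during 8-9 AM (37.4%), and 227 at
9 AM or later.  Empirical plans draw a bin by those probabilities and a time
uniformly inside it; pre-opening arrivals fall in the [-30, 0) window and
are served from t = 0, and the open-ended late tail is spread over 9:00-9:30.

Three policies transform a baseline scenario:

* **S1** — book a predetermined customer-type mix (default: uniform across
  the six types);
* **S2** — add capacity at the endoscopy bottleneck L (default +1 room);
* **S3** — replace free check-in with scheduled batch arrivals (default:
  batches of 5 every 25 minutes from opening, spreading the same 2.5-hour
  check-in window evenly instead of letting customers bunch).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigError
from .model import Model

__all__ = [
    "ArrivalHistogram",
    "DEFAULT_HISTOGRAM",
    "ScheduleParams",
    "ScenarioConfig",
    "gen_arrivals_empirical",
    "gen_arrivals_scheduled",
    "sample_mix",
    "make_arrival_plan",
    "apply_policy",
    "POLICIES",
]


@dataclass(frozen=True)
class ArrivalHistogram:
    """Non-overlapping (start, end, probability) check-in bins, minutes."""

    bins: tuple[tuple[float, float, float], ...]

    def __post_init__(self):
        if not self.bins:
            raise ConfigError("arrival histogram has no bins")
        total = sum(p for _, _, p in self.bins)
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"histogram probabilities sum to {total}, expected 1")
        spans = sorted((s, e) for s, e, _ in self.bins)
        if any(not s < e for s, e in spans) or any(
            a[1] > b[0] for a, b in zip(spans, spans[1:])
        ):
            raise ConfigError("histogram bins must be non-overlapping intervals")


#: observed check-in histogram (counts 16 / 1222 / 877 / 227 out of 2342)
DEFAULT_HISTOGRAM = ArrivalHistogram(
    bins=(
        (-30.0, 0.0, 16 / 2342),
        (0.0, 60.0, 1222 / 2342),
        (60.0, 120.0, 877 / 2342),
        (120.0, 150.0, 227 / 2342),
    )
)


@dataclass(frozen=True)
class ScheduleParams:
    start: float = 0.0
    batch: int = 5
    interval: float = 25.0

    def __post_init__(self):
        if self.batch < 1:
            raise ConfigError(f"batch size must be >= 1, got {self.batch}")
        if self.interval <= 0:
            raise ConfigError(f"interval must be > 0, got {self.interval}")


@dataclass(frozen=True)
class ScenarioConfig:
    """A runnable experiment: volume, mix, arrivals, overrides, replications."""

    volume: int = 30
    mix: Mapping[str, float] | None = None  # None = model's observed mix
    arrival_mode: str = "empirical"  # empirical | scheduled
    histogram: ArrivalHistogram = DEFAULT_HISTOGRAM
    schedule: ScheduleParams = ScheduleParams()
    capacity_overrides: Mapping[str, int] = field(default_factory=dict)
    replications: int = 50
    base_seed: int = 0
    truncate: bool = False
    policy: str = "baseline"

    def __post_init__(self):
        if self.volume < 1:
            raise ConfigError(f"volume must be >= 1, got {self.volume}")
        if self.arrival_mode not in ("empirical", "scheduled"):
            raise ConfigError(f"unknown arrival mode {self.arrival_mode!r}")
        if self.mix is not None:
            _check_mix(self.mix)
        if self.replications < 1:
            raise ConfigError(f"replications must be >= 1, got {self.replications}")


def _check_mix(mix: Mapping[str, float]) -> None:
    if any(p < 0 for p in mix.values()):
        raise ConfigError("mix proportions must be >= 0")
    total = sum(mix.values())
    if abs(total - 1.0) > 1e-6:
        raise ConfigError(f"mix proportions sum to {total}, expected 1")


def gen_arrivals_empirical(
    n: int, hist: ArrivalHistogram, rng: np.random.Generator
) -> list[float]:
    """Draw ``n`` check-in times: bin by probability, uniform within bin."""
    if n < 1:
        raise ConfigError(f"n must be >= 1, got {n}")
    probs = np.array([p for _, _, p in hist.bins])
    idx = rng.choice(len(hist.bins), size=n, p=probs / probs.sum())
    lo = np.array([s for s, _, _ in hist.bins])[idx]
    hi = np.array([e for _, e, _ in hist.bins])[idx]
    return sorted(rng.uniform(lo, hi).tolist())


def gen_arrivals_scheduled(
    n: int, start: float = 0.0, batch: int = 5, interval: float = 20.0
) -> list[float]:
    """Deterministic batch schedule: groups of ``batch`` every ``interval``."""
    if n < 1 or batch < 1:
        raise ConfigError("n and batch must be >= 1")
    if interval <= 0:
        raise ConfigError(f"interval must be > 0, got {interval}")
    times = []
    for k in range(math.ceil(n / batch)):
        m = min(batch, n - k * batch)
        times.extend([start + k * interval] * m)
    return times


def sample_mix(
    n: int, proportions: Mapping[str, float], rng: np.random.Generator
) -> list[str]:
    """``n`` independent categorical draws of customer-type ids."""
    _check_mix(proportions)
    ids = sorted(proportions)
    p = np.array([proportions[t] for t in ids], dtype=float)
    if n == 0:
        return []
    return [ids[i] for i in rng.choice(len(ids), size=n, p=p / p.sum())]


def make_arrival_plan(
    scenario: ScenarioConfig, model: Model, rng: np.random.Generator
) -> list[tuple[float, str]]:
    """Realize one day's (time, type) arrival list for a scenario."""
    if scenario.arrival_mode == "empirical":
        times = gen_arrivals_empirical(scenario.volume, scenario.histogram, rng)
    else:
        s = scenario.schedule
        times = gen_arrivals_scheduled(scenario.volume, s.start, s.batch, s.interval)
    mix = scenario.mix if scenario.mix is not None else model.mix
    types = sample_mix(scenario.volume, mix, rng)
    return list(zip(times, types))


POLICIES = ("baseline", "S1_mix", "S2_capacity", "S3_schedule")


def apply_policy(
    base: ScenarioConfig, policy: str, params: Mapping | None = None
) -> ScenarioConfig:
    """Pure transformation of a baseline scenario into a policy scenario.

    * ``S1_mix``: replace the type mix (``params["mix"]``, default uniform).
    * ``S2_capacity``: add ``params["delta"]`` (default +1) servers to the
      endoscopy station L in every capacity window.
    * ``S3_schedule``: switch to scheduled batch arrivals
      (``params["schedule"]``, default batches of 5 every 25 min).
    """
    params = dict(params or {})
    if policy == "baseline":
        return replace(base, policy="baseline")
    if policy in ("S1_mix", "s1"):
        mix = params.get("mix") or {t: 1 / 6 for t in ("X1", "X2", "X3", "Y1", "Y2", "Y3")}
        _check_mix(mix)
        return replace(base, mix=dict(mix), policy="S1_mix")
    if policy in ("S2_capacity", "s2"):
        delta = int(params.get("delta", 1))
        station = params.get("station", "L")
        overrides = dict(base.capacity_overrides)
        overrides[station] = overrides.get(station, 0) + delta
        return replace(base, capacity_overrides=overrides, policy="S2_capacity")
    if policy in ("S3_schedule", "s3"):
        sched = params.get("schedule", ScheduleParams())
        if isinstance(sched, Mapping):
            sched = ScheduleParams(**sched)
        return replace(base, arrival_mode="scheduled", schedule=sched, policy="S3_schedule")
    raise ConfigError(f"unknown policy {policy!r}")
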