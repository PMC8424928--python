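"""Seeded discrete-event engine for one simulated screening day.

The engine is a classic event-calendar simulator: a binary heap of
``(time, seq)``-ordered events, one FIFO queue per station, and time-varying
station capacities.  Three event kinds exist — entity arrival at a station,
service completion, and a scheduled capacity change (e.g. the noon switch of
a shared room).  Service starts are not scheduled; they happen eagerly
whenever a server is free, which keeps the calendar small and makes FIFO
order trivial to maintain.

Determinism: ``seq`` is a strictly increasing creation counter used as the
tie-break for simultaneous events, and all service durations are drawn from
one caller-supplied generator in event order, so identical
``(model, arrivals, seed)`` reproduce the run bit for bit.

Capacity drops are non-preemptive: a customer mid-examination at noon
finishes normally; the reduced capacity only gates new admissions.
"""

from __future__ import annotations

import heapq
import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .distributions import sample
from .errors import ModelConsistencyError
from .model import HORIZON, Model, Sex, Station, capacity_at

__all__ = ["StepRecord", "EntityState", "StationStats", "DayResult", "run_day"]

_ARRIVAL, _END, _CAP = 0, 1, 2


@dataclass
class StepRecord:
    station: str
    queue_entry: float
    service_start: float | None = None
    service_end: float | None = None

    @property
    def wait(self) -> float:
        return self.service_start - self.queue_entry

    @property
    def duration(self) -> float:
        return self.service_end - self.service_start


@dataclass
class EntityState:
    """One customer's trajectory through their route."""

    id: int
    type_id: str
    sex: Sex
    plan_time: float  # time on the arrival plan; may precede opening (t < 0)
    arrival_time: float  # effective arrival, clamped to opening at t = 0
    route: tuple[str, ...]
    position: int = 0
    steps: list[StepRecord] = field(default_factory=list)
    exit_time: float | None = None

    @property
    def finished(self) -> bool:
        return self.exit_time is not None

    @property
    def waiting_time(self) -> float:
        return sum(s.wait for s in self.steps)

    @property
    def service_time(self) -> float:
        return sum(s.duration for s in self.steps)

    @property
    def total_time(self) -> float:
        return self.exit_time - self.arrival_time


@dataclass
class StationStats:
    """Accumulated queue statistics for one station over the run."""

    code: str
    served: int = 0
    wait_sum: float = 0.0
    queue_len_integral: float = 0.0
    busy_integral: float = 0.0
    capacity_integral: float = 0.0  # finite-capacity windows only

    @property
    def mean_wait(self) -> float:
        return self.wait_sum / self.served if self.served else 0.0

    def time_avg_queue(self, elapsed: float) -> float:
        return self.queue_len_integral / elapsed if elapsed > 0 else 0.0

    @property
    def utilization(self) -> float:
        return self.busy_integral / self.capacity_integral if self.capacity_integral > 0 else 0.0


@dataclass
class DayResult:
    entities: list[EntityState]
    stations: dict[str, StationStats]
    end_time: float
    event_log: list[tuple] | None = None

    def log_digest(self) -> int:
        """Stable hash of the event log (requires collect_log=True)."""
        if self.event_log is None:
            raise ValueError("run with collect_log=True to digest the event log")
        return hash(tuple(self.event_log))


class _StationRT:
    __slots__ = ("station", "spec", "queue", "busy", "stats", "last_t")

    def __init__(self, station: Station, spec):
        self.station = station
        self.spec = spec
        self.queue: list[EntityState] = []  # used as FIFO via index
        self.busy = 0
        self.stats = StationStats(code=station.code)
        self.last_t = 0.0


def _cap_integral(station: Station, end: float) -> float:
    total = 0.0
    for w in station.windows:
        if math.isinf(w.capacity) or w.capacity == 0:
            continue
        lo, hi = max(w.start, 0.0), min(w.end, end)
        if hi > lo:
            total += w.capacity * (hi - lo)
    return total


def run_day(
    model: Model,
    arrivals,
    rng: np.random.Generator,
    truncate: bool = False,
    collect_log: bool = False,
) -> DayResult:
    """Simulate one day: every planned arrival flows through its route.

    ``arrivals`` is an ordered sequence of ``(time_minutes, type_id)``.
    Plan times may be negative (early birds before the 7:00 AM opening);
    they are admitted at t = 0 and their waiting clock starts then.

    By default the run drains past the nominal 9-hour horizon until the
    system is empty; ``truncate=True`` stops processing at the horizon and
    leaves late entities unfinished.
    """
    times = [t for t, _ in arrivals]
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValueError("arrival plan must be sorted by time")

    seq = itertools.count()
    heap: list[tuple] = []
    log: list[tuple] | None = [] if collect_log else None

    rts: dict[str, _StationRT] = {
        code: _StationRT(st, model.service.get(code)) for code, st in model.stations.items()
    }

    entities: list[EntityState] = []
    for i, (t, type_id) in enumerate(arrivals):
        ct = model.types[type_id]
        ent = EntityState(
            id=i,
            type_id=type_id,
            sex=ct.sex,
            plan_time=float(t),
            arrival_time=max(0.0, float(t)),
            route=model.routes[type_id].steps,
        )
        entities.append(ent)
        heapq.heappush(heap, (ent.arrival_time, next(seq), _ARRIVAL, ent))

    # schedule the finite capacity-change boundaries of every station
    for code, rt in rts.items():
        for w in rt.station.windows:
            if 0.0 < w.start < math.inf:
                heapq.heappush(heap, (w.start, next(seq), _CAP, rt))

    def integrate(rt: _StationRT, now: float) -> None:
        dt = now - rt.last_t
        if dt > 0:
            rt.stats.queue_len_integral += len(rt.queue) * dt
            rt.stats.busy_integral += rt.busy * dt
            rt.last_t = now

    def try_admit(rt: _StationRT, now: float) -> None:
        cap = capacity_at(rt.station, now)
        while rt.queue and rt.busy < cap:
            ent = rt.queue.pop(0)
            rt.busy += 1
            rec = ent.steps[-1]
            rec.service_start = now
            rt.stats.wait_sum += rec.wait
            dur = 0.0 if rt.spec is None else float(sample(rt.spec, rng))
            heapq.heappush(heap, (now + dur, next(seq), _END, ent))
            if log is not None:
                log.append((round(now, 9), "start", ent.id, ent.type_id, rt.station.code))

    def enqueue(ent: EntityState, now: float) -> None:
        code = ent.route[ent.position]
        rt = rts[code]
        if not rt.station.admits(ent.sex):
            raise ModelConsistencyError(
                f"route of type {ent.type_id} sends a {ent.sex.value} customer "
                f"to {ent.sex.value}-excluded station {code}"
            )
        integrate(rt, now)
        ent.steps.append(StepRecord(station=code, queue_entry=now))
        rt.queue.append(ent)
        if log is not None:
            log.append((round(now, 9), "queue", ent.id, ent.type_id, code))
        try_admit(rt, now)

    end_time = 0.0
    while heap:
        now, _, kind, obj = heapq.heappop(heap)
        if truncate and now > HORIZON:
            end_time = HORIZON
            break
        end_time = max(end_time, now)
        if kind == _ARRIVAL:
            enqueue(obj, now)
        elif kind == _END:
            ent: EntityState = obj
            rt = rts[ent.route[ent.position]]
            integrate(rt, now)
            rt.busy -= 1
            rec = ent.steps[-1]
            if rec.service_end is not None:
                raise ModelConsistencyError(f"entity {ent.id} finished twice at {rec.station}")
            rec.service_end = now
            rt.stats.served += 1
            if log is not None:
                log.append((round(now, 9), "end", ent.id, ent.type_id, rt.station.code))
            ent.position += 1
            if ent.position >= len(ent.route):
                ent.exit_time = now
            else:
                enqueue(ent, now)
            try_admit(rt, now)
        else:  # capacity change
            rt = obj
            integrate(rt, now)
            try_admit(rt, now)

    for rt in rts.values():
        integrate(rt, end_time)
        rt.stats.capacity_integral = _cap_integral(rt.station, end_time)

    if not truncate:
        stuck = [e for e in entities if not e.finished]
        if stuck:
            where = sorted({e.route[e.position] for e in stuck})
            raise ModelConsistencyError(
                f"{len(stuck)} entities stranded at permanently closed station(s) {where}"
            )

    return DayResult(
        entities=entities,
        stations={c: rt.stats for c, rt in rts.items()},
        end_time=end_time,
        event_log=log,
    )
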