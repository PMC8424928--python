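"""Synthetic RFID-wristband visit logs and the three-rule data cleaning.

Real input data for this kind of model comes from wristband sensors logged
at each examination-room door: one record per customer per station with
entry and exit timestamps.  Two defects dominate such logs: a sensor miss
(one of the two timestamps absent) and occasional extreme durations.  The
generator reproduces that structure from the model's own service-time laws
so the cleaning and fitting stages can be exercised without field data:
durations are drawn from the station distributions, timestamps laid end to
end from a histogram check-in time, a fraction of records lose a timestamp,
and a fraction get their duration inflated by a fixed outlier factor.

Cleaning applies, in order: (1) drop records of customers outside the six
modelled types; (2) drop records missing either timestamp; (3) per station,
drop records whose duration exceeds twice that station's mean duration,
the mean being computed once on the survivors of rules 1-2 (no iterative
re-trimming).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .distributions import sample
from .errors import ConfigError
from .model import Model
from .scenarios import DEFAULT_HISTOGRAM, gen_arrivals_empirical, sample_mix

__all__ = [
    "VisitRecord",
    "gen_visit_log",
    "clean_visit_log",
    "durations_by_station",
    "write_visit_log",
    "read_visit_log",
]

CSV_HEADER = ["customer_id", "type", "station", "entry_min", "exit_min", "day"]

# nominal desk-handling time for the zero-service bookkeeping steps (check-in
# A, leaving V): the sensor still sees a short dwell at the door
_DESK_DWELL = (0.2, 1.0)


@dataclass(frozen=True)
class VisitRecord:
    customer_id: int
    type_id: str
    station: str
    entry: float | None
    exit: float | None
    day: int = 0

    def __post_init__(self):
        if self.entry is not None and self.exit is not None and not self.exit > self.entry:
            raise ValueError(
                f"exit must be after entry, got [{self.entry}, {self.exit}] at {self.station}"
            )

    @property
    def complete(self) -> bool:
        return self.entry is not None and self.exit is not None

    @property
    def duration(self) -> float:
        return self.exit - self.entry


def gen_visit_log(
    n_customers: int,
    model: Model,
    rng: np.random.Generator,
    miss_rate: float = 0.03,
    outlier_rate: float = 0.01,
    outlier_factor: float = 3.0,
    mix: Mapping[str, float] | None = None,
    days: int = 1,
) -> list[VisitRecord]:
    """Generate wristband-style records for ``n_customers`` across ``days``.

    Each customer walks their route; stations are stamped end to end from a
    histogram check-in time (queueing delay is irrelevant here: only the
    entry-to-exit duration feeds the fitting stage).  With probability
    ``miss_rate`` a record loses its entry or exit timestamp; with
    probability ``outlier_rate`` the duration is multiplied by
    ``outlier_factor``.
    """
    for name, rate in (("miss_rate", miss_rate), ("outlier_rate", outlier_rate)):
        if not 0.0 <= rate < 1.0:
            raise ConfigError(f"{name} must be in [0, 1), got {rate}")
    if outlier_factor < 2.0:
        raise ConfigError(f"outlier_factor must be >= 2, got {outlier_factor}")
    mix = dict(mix) if mix is not None else model.mix
    types = sample_mix(n_customers, mix, rng)
    checkins = gen_arrivals_empirical(n_customers, DEFAULT_HISTOGRAM, rng)
    records: list[VisitRecord] = []
    for cid, (type_id, t0) in enumerate(zip(types, checkins)):
        day = cid % days
        t = max(0.0, t0)
        for code in model.routes[type_id].steps:
            spec = model.service.get(code)
            if spec is None:
                dur = float(rng.uniform(*_DESK_DWELL))
            else:
                dur = float(sample(spec, rng))
            if outlier_rate and rng.random() < outlier_rate:
                dur *= outlier_factor
            entry, exit_ = t, t + dur
            t = exit_
            e1: float | None = entry
            e2: float | None = exit_
            if miss_rate and rng.random() < miss_rate:
                if rng.random() < 0.5:
                    e1 = None
                else:
                    e2 = None
            records.append(VisitRecord(cid, type_id, code, e1, e2, day))
    return records


KNOWN_TYPES = ("X1", "X2", "X3", "Y1", "Y2", "Y3")


def clean_visit_log(
    records: Sequence[VisitRecord], known_types: Iterable[str] = KNOWN_TYPES
) -> tuple[list[VisitRecord], dict]:
    """Apply the three screening rules; returns (kept, removal report).

    The report maps ``"rule1"``/``"rule2"`` to total removals and
    ``"rule3"`` to a per-station removal count, plus ``"kept"`` and
    ``"input"`` totals and the per-station trim thresholds used.
    """
    known = set(known_types)
    report: dict = {
        "input": len(records),
        "rule1_unknown_type": 0,
        "rule2_missing_timestamp": 0,
        "rule3_outlier": {},
        "thresholds": {},
    }
    stage1: list[VisitRecord] = []
    for r in records:
        if r.type_id not in known:
            report["rule1_unknown_type"] += 1
        else:
            stage1.append(r)
    stage2: list[VisitRecord] = []
    for r in stage1:
        if not r.complete:
            report["rule2_missing_timestamp"] += 1
        else:
            stage2.append(r)

    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for r in stage2:
        sums[r.station] = sums.get(r.station, 0.0) + r.duration
        counts[r.station] = counts.get(r.station, 0) + 1
    thresholds = {c: 2.0 * sums[c] / counts[c] for c in sums}
    report["thresholds"] = thresholds

    kept: list[VisitRecord] = []
    for r in stage2:
        if r.duration > thresholds[r.station]:
            report["rule3_outlier"][r.station] = report["rule3_outlier"].get(r.station, 0) + 1
        else:
            kept.append(r)
    report["kept"] = len(kept)
    report["removed"] = len(records) - len(kept)
    return kept, report


def durations_by_station(records: Sequence[VisitRecord]) -> dict[str, list[float]]:
    """Group complete-record durations per station, order preserved."""
    out: dict[str, list[float]] = {}
    for r in records:
        if r.complete:
            out.setdefault(r.station, []).append(r.duration)
    return out


# ---------------------------------------------------------------------------
# CSV round-trip


def write_visit_log(records: Sequence[VisitRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(CSV_HEADER)
        for r in records:
            w.writerow(
                [
                    r.customer_id,
                    r.type_id,
                    r.station,
                    "" if r.entry is None else f"{r.entry:.4f}",
                    "" if r.exit is None else f"{r.exit:.4f}",
                    r.day,
                ]
            )


def read_visit_log(path: str | Path) -> list[VisitRecord]:
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != CSV_HEADER:
            raise ConfigError(f"unexpected visit-log header {reader.fieldnames}")
        for row in reader:
            records.append(
                VisitRecord(
                    customer_id=int(row["customer_id"]),
                    type_id=row["type"],
                    station=row["station"],
                    entry=float(row["entry_min"]) if row["entry_min"] else None,
                    exit=float(row["exit_min"]) if row["exit_min"] else None,
                    day=int(row["day"]),
                )
            )
    return records
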