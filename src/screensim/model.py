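"""Static model of the screening center: stations, customer types, routes.

Time is measured in minutes from a 7:00 AM day origin, so the noon
morning/afternoon switch sits at t = 300 and the nominal 9-hour operating
horizon ends at t = 540.  Several rooms are shared across examinations, so a
station's capacity is a *schedule* of half-open windows ``[start, end)``
rather than a single number: the height/weight station runs mornings only,
the urology consultation afternoons only, and one vision/hearing lane opens
at noon when the shared ophthalmology room frees up.

Station codes A..V follow the center's item coding; A (check-in) and V
(leaving) are zero-duration bookkeeping steps, and P is the lunch break —
modelled as an uncapacitated station whose sit-down time counts as service,
not waiting.

Six customer types (X1..X3 female, Y1..Y3 male) each follow a fixed ordered
route through the stations.  Routes encode the clinical sequencing rules:
fasting examinations (blood draw G, abdominal ultrasound I, endoscopy L and
its anesthesia recovery M) precede lunch, abdominal precedes endoscopy, and
recovery immediately follows the endoscopy.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .distributions import DistributionSpec, Family
from .errors import ConfigError, ParameterError

__all__ = [
    "NOON",
    "HORIZON",
    "STATION_NAMES",
    "CapacityWindow",
    "Station",
    "CustomerType",
    "Route",
    "Model",
    "Sex",
    "default_config",
    "load_model",
    "validate_route",
    "capacity_at",
]

#: minutes from the 7:00 AM day origin
NOON = 300.0
#: nominal operating horizon (9 hours); the engine drains past it
HORIZON = 540.0
INF = math.inf


class Sex(str, Enum):
    FEMALE = "female"
    MALE = "male"


STATION_NAMES: dict[str, str] = {
    "A": "Check-in at the front desk",
    "B": "Changing health examination clothes (dressing)",
    "C": "Confirmation of data, completion of a questionnaire",
    "D": "Basic measurement of height and weight",
    "E": "Vision and hearing",
    "F": "Measurement of blood pressure",
    "G": "Blood drawing",
    "H": "ECG examination",
    "I": "Abdominal ultrasound",
    "J": "Cardiac ultrasound",
    "K": "Low-dose computed tomography of the lung screening",
    "L": "Gastrointestinal endoscopy with anesthesia",
    "M": "Endoscopic anesthesia recovery",
    "N": "Thyroid ultrasound",
    "O": "Female breast ultrasound or monograph",
    "P": "Lunch",
    "Q": "Consultation with ophthalmologist",
    "R": "Consultation with otolaryngologist",
    "S": "Consultation with gynecologist and obstetrician",
    "T": "Consultation with urologist",
    "U": "Low-dose computed tomography of the coronary artery",
    "V": "Leaving the medical center",
}

# service-time law per station, Arena convention; A and V take no time
_SERVICE: dict[str, dict | None] = {
    "A": None,
    "B": {"family": "UNIF", "params": [5, 10]},
    "C": {"family": "UNIF", "params": [15, 20]},
    "D": {"family": "ERLA", "params": [1.23, 2], "offset": 1.0},
    "E": {"family": "ERLA", "params": [0.546, 2], "offset": 0.999},
    "F": {"family": "EXPO", "params": [0.626], "offset": 0.999},
    "G": {"family": "ERLA", "params": [1.06, 3], "offset": 0.999},
    "H": {"family": "LOGN", "params": [3.42, 1.37], "offset": 1.0},
    "I": {"family": "LOGN", "params": [2.88, 2.52], "offset": 1.0},
    "J": {"family": "GAMM", "params": [1.41, 5.12], "offset": 1.0},
    "K": {"family": "UNIF", "params": [5, 10]},
    "L": {"family": "UNIF", "params": [15, 30]},
    "M": {"family": "UNIF", "params": [15, 20]},
    "N": {"family": "LOGN", "params": [4.51, 3.04], "offset": 1.0},
    "O": {"family": "BETA", "params": [1.35, 2.55], "offset": 0.999, "scale": 29},
    "P": {"family": "UNIF", "params": [10, 15]},
    "Q": {"family": "LOGN", "params": [1.99, 1.64], "offset": 1.0},
    "R": {"family": "LOGN", "params": [3.64, 3.16], "offset": 1.0},
    "S": {"family": "ERLA", "params": [1.2, 4], "offset": 1.0},
    "T": {"family": "LOGN", "params": [4.51, 2.66], "offset": 1.0},
    "U": {"family": "UNIF", "params": [20, 30]},
    "V": None,
}

# Default staffing/capacity per station.  Room counts come from the floor
# plan; shared rooms produce the morning/afternoon splits (the ophthalmology
# room hosts height/weight before noon and a second vision/hearing lane
# after).  The CT items K and U run in the radiology department off the
# screening floor, so their capacity is not tied to a floor-plan room; K is
# staffed at 2 scanner slots.  The urology consultation T is kept open all
# day: gating it to afternoons is irreconcilable with the observed male
# throughput (see docs/methods.md).  "am"/"pm" shorthand expands to windows
# split at NOON; a plain integer is all-day.  Lunch is uncapacitated.
_CAPACITY: dict[str, int | dict] = {
    "A": 2,
    "B": 4,
    "C": 8,
    "D": {"am": 1, "pm": 0},
    "E": {"am": 1, "pm": 2},
    "F": 1,
    "G": 2,
    "H": 1,
    "I": {"am": 2, "pm": 1},
    "J": 2,
    "K": 2,
    "L": 3,
    "M": 4,
    "N": 1,
    "O": 1,
    "P": "unbounded",
    "Q": 1,
    "R": 1,
    "S": 3,
    "T": 1,
    "U": 1,
    "V": 2,
}

_SEX_RESTRICTION = {"O": "female_only", "S": "female_only", "T": "male_only"}

_ROUTES: dict[str, list[str]] = {
    "X1": list("ABCDEFGHIJKLMNOPQRSV"),
    "X2": list("ABDEFGCHILMJPKNORQSV"),
    "X3": list("AGBDFECHIJKULMPNOSRQV"),
    "Y1": list("ABCDEFGHIKJLMNPQRTV"),
    "Y2": list("ABEFGDCKHIJLMNRPQTV"),
    "Y3": list("AGBCFDEHIJKUNLMPTRQV"),
}

# (sex, age band, observed share in %) per type; shares total 100.00
_TYPES: dict[str, tuple[str, str, float]] = {
    "X1": ("female", "over55", 10.93),
    "X2": ("female", "under55", 29.89),
    "X3": ("female", "all", 1.58),
    "Y1": ("male", "over55", 20.11),
    "Y2": ("male", "under55", 34.03),
    "Y3": ("male", "all", 3.46),
}


@dataclass(frozen=True)
class CapacityWindow:
    start: float
    end: float
    capacity: float  # math.inf for an uncapacitated station

    def __post_init__(self):
        if not self.start < self.end:
            raise ConfigError(f"window start must be < end, got [{self.start}, {self.end})")
        if self.capacity < 0:
            raise ConfigError(f"window capacity must be >= 0, got {self.capacity}")


@dataclass(frozen=True)
class Station:
    code: str
    name: str
    windows: tuple[CapacityWindow, ...]
    sex_restriction: str = "none"  # none | female_only | male_only

    def admits(self, sex: Sex | str) -> bool:
        s = Sex(sex)
        if self.sex_restriction == "female_only":
            return s is Sex.FEMALE
        if self.sex_restriction == "male_only":
            return s is Sex.MALE
        return True


@dataclass(frozen=True)
class CustomerType:
    id: str
    sex: Sex
    age_band: str
    proportion: float


@dataclass(frozen=True)
class Route:
    type_id: str
    steps: tuple[str, ...]


@dataclass
class Model:
    stations: dict[str, Station]
    service: dict[str, DistributionSpec | None]
    types: dict[str, CustomerType]
    routes: dict[str, Route]

    @property
    def mix(self) -> dict[str, float]:
        return {t: ct.proportion for t, ct in self.types.items()}


def capacity_at(station: Station, t: float) -> float:
    """Capacity of the half-open window ``[start, end)`` containing ``t``."""
    if t < 0:
        raise ParameterError(f"time must be >= 0, got {t}")
    for w in station.windows:
        if w.start <= t < w.end:
            return w.capacity
    raise ParameterError(f"time {t} outside the capacity schedule of station {station.code}")


def default_config() -> dict:
    """The bundled model configuration (deep copy; safe to mutate)."""
    return copy.deepcopy(
        {
            "stations": {
                code: {
                    "name": STATION_NAMES[code],
                    "capacity": copy.deepcopy(_CAPACITY[code]),
                    "sex_restriction": _SEX_RESTRICTION.get(code, "none"),
                }
                for code in STATION_NAMES
            },
            "distributions": {c: d for c, d in _SERVICE.items() if d is not None},
            "types": {
                t: {"sex": sex, "age_band": age, "proportion": share / 100.0}
                for t, (sex, age, share) in _TYPES.items()
            },
            "routes": {t: list(steps) for t, steps in _ROUTES.items()},
        }
    )


def _expand_capacity(code: str, cap, path: str) -> tuple[CapacityWindow, ...]:
    if cap == "unbounded":
        return (CapacityWindow(0.0, INF, INF),)
    if isinstance(cap, (int, float)):
        return (CapacityWindow(0.0, INF, float(cap)),)
    if isinstance(cap, Mapping):
        if set(cap) == {"am", "pm"}:
            return (
                CapacityWindow(0.0, NOON, float(cap["am"])),
                CapacityWindow(NOON, INF, float(cap["pm"])),
            )
        if "windows" in cap:
            wins = [
                CapacityWindow(float(w["start"]), float(w.get("end", INF)), float(w["capacity"]))
                for w in cap["windows"]
            ]
            wins.sort(key=lambda w: w.start)
            if wins[0].start != 0.0 or any(
                a.end != b.start for a, b in zip(wins, wins[1:])
            ) or wins[-1].end != INF:
                raise ConfigError(f"{path}: windows must tile [0, inf) without gaps or overlap")
            return tuple(wins)
    raise ConfigError(f"{path}: malformed capacity entry {cap!r}")


def load_model(config: Mapping | str | Path | None = None) -> Model:
    """Build and validate a :class:`Model` from a config mapping or YAML path.

    ``None`` loads the bundled default model (22 stations, 6 routes).
    """
    if config is None:
        config = default_config()
    elif isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    for section in ("stations", "distributions", "types", "routes"):
        if section not in config:
            raise ConfigError(f"{section}: missing section")

    stations: dict[str, Station] = {}
    for code, entry in config["stations"].items():
        path = f"stations.{code}"
        if not (len(code) == 1 and "A" <= code <= "V"):
            raise ConfigError(f"{path}: station code must be a letter A..V")
        stations[code] = Station(
            code=code,
            name=entry.get("name", code),
            windows=_expand_capacity(code, entry.get("capacity", 1), path),
            sex_restriction=entry.get("sex_restriction", "none"),
        )

    service: dict[str, DistributionSpec | None] = {c: None for c in stations}
    for code, d in config["distributions"].items():
        if code not in stations:
            raise ConfigError(f"distributions.{code}: unknown station code")
        try:
            service[code] = DistributionSpec.from_dict(d)
        except (ParameterError, KeyError) as exc:
            raise ConfigError(f"distributions.{code}: {exc}") from exc

    types: dict[str, CustomerType] = {}
    for tid, entry in config["types"].items():
        try:
            types[tid] = CustomerType(
                id=tid,
                sex=Sex(entry["sex"]),
                age_band=entry["age_band"],
                proportion=float(entry["proportion"]),
            )
        except (KeyError, ValueError) as exc:
            raise ConfigError(f"types.{tid}: {exc}") from exc
    total = sum(ct.proportion for ct in types.values())
    if abs(total - 1.0) > 1e-6:
        raise ConfigError(f"types: proportions sum to {total}, expected 1")

    routes: dict[str, Route] = {}
    for tid, steps in config["routes"].items():
        path = f"routes.{tid}"
        if tid not in types:
            raise ConfigError(f"{path}: route for unknown customer type")
        steps = tuple(steps)
        for s in steps:
            if s not in stations:
                raise ConfigError(f"{path}: unknown station code {s!r}")
            if service[s] is None and s not in ("A", "V"):
                raise ConfigError(f"{path}: station {s!r} has no service distribution")
        route = Route(type_id=tid, steps=steps)
        problems = _structural_problems(route)
        if problems:
            raise ConfigError(f"{path}: {'; '.join(problems)}")
        sex = types[tid].sex
        for s in steps:
            if not stations[s].admits(sex):
                raise ConfigError(f"{path}: station {s} does not admit {sex.value} customers")
        routes[tid] = route
    missing = set(types) - set(routes)
    if missing:
        raise ConfigError(f"routes: no route for types {sorted(missing)}")

    return Model(stations=stations, service=service, types=types, routes=routes)


def _structural_problems(route: Route) -> list[str]:
    steps = route.steps
    out = []
    if not steps or steps[0] != "A":
        out.append("route must start with A")
    if not steps or steps[-1] != "V":
        out.append("route must end with V")
    if len(set(steps)) != len(steps):
        out.append("route contains duplicate stations")
    if "P" in steps and steps.count("P") != 1:
        out.append("lunch P must appear exactly once")
    return out


def validate_route(route: Route, constraint_set: str = "hard") -> list[str]:
    """Check clinical sequencing constraints; returns violations (empty = ok).

    ``hard``: fasting stations {G, I, L, M} precede lunch P; I precedes the
    endoscopy L; recovery M immediately follows L; A first and V last.
    ``strict`` additionally requires {G, H, I, J, K} to precede L (the full
    pre-anesthesia work-up ordering, which two observed routes relax).
    """
    if constraint_set not in ("hard", "strict"):
        raise ParameterError(f"constraint_set must be 'hard' or 'strict', got {constraint_set!r}")
    steps = route.steps
    pos = {s: i for i, s in enumerate(steps)}
    out = list(_structural_problems(route))
    if "P" in pos:
        for s in "GILM":
            if s in pos and pos[s] > pos["P"]:
                out.append(f"{s} after P")
    if "I" in pos and "L" in pos and pos["I"] > pos["L"]:
        out.append("I after L")
    if "L" in pos:
        if "M" not in pos or pos["M"] != pos["L"] + 1:
            out.append("M not immediately after L")
    if constraint_set == "strict" and "L" in pos:
        for s in "GHIJK":
            if s in pos and pos[s] > pos["L"]:
                out.append(f"{s} after L")
    return out
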