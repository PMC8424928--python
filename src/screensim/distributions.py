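"""Service-time distributions in the Arena parameter convention.

Examination-station service times are modelled as an additive offset plus a
draw from one of six families, written the way Arena prints them in input
analysis reports:

================  =============================  =========================
family            parameters                     mean
================  =============================  =========================
``UNIF(a, b)``    endpoints                      ``(a + b) / 2``
``ERLA(x, k)``    stage mean ``x = 1/lambda``,   ``k * x``
                  integer stage count ``k``
``EXPO(m)``       mean ``m``                     ``m``
``LOGN(m, s)``    *arithmetic* mean and sd of    ``m``
                  the lognormal itself
``BETA(b, a)``    shape pair, plus a scale       ``scale * b / (b + a)``
                  multiplier
``GAMM(x, k)``    scale ``x`` then shape ``k``   ``k * x``
================  =============================  =========================

The ``LOGN`` convention deserves emphasis: the two printed numbers are the
arithmetic mean and standard deviation of the lognormal variate, not the
parameters of the underlying normal.  This is the only reading under which
the printed expressions reproduce the published simulation means, and it is
how Arena specifies lognormals.  :func:`lognormal_underlying` converts to
the underlying normal ``(mu, sigma)`` when one is needed.

Fitting (:func:`fit_distribution`) performs maximum likelihood per family
with a per-family location offset, selects by the Kolmogorov-Smirnov
statistic (with a parsimony rule for near-ties), and returns a spec in the
same convention.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateDataError, InsufficientDataError, ParameterError

__all__ = [
    "Family",
    "DistributionSpec",
    "sample",
    "analytic_mean",
    "analytic_sd",
    "lognormal_underlying",
    "fit_distribution",
    "to_scipy",
]


class Family(str, Enum):
    UNIF = "UNIF"
    ERLA = "ERLA"
    EXPO = "EXPO"
    LOGN = "LOGN"
    BETA = "BETA"
    GAMM = "GAMM"


#: number of free parameters per family (used as a goodness-of-fit tie-break)
_N_PARAMS = {
    Family.UNIF: 2,
    Family.ERLA: 2,
    Family.EXPO: 1,
    Family.LOGN: 2,
    Family.BETA: 3,  # two shapes + scale multiplier
    Family.GAMM: 2,
}


@dataclass(frozen=True)
class DistributionSpec:
    """One station's service-time law: ``offset + family(params)``.

    ``scale`` is only meaningful for ``BETA`` (the multiplier in front of
    the unit beta variate, e.g. 29 for the breast-ultrasound station).
    """

    family: Family
    params: tuple
    offset: float = 0.0
    scale: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "family", Family(self.family))
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))
        object.__setattr__(self, "offset", float(self.offset))
        if self.scale is not None:
            object.__setattr__(self, "scale", float(self.scale))
        if self.offset < 0:
            raise ParameterError(f"offset must be >= 0, got {self.offset}")
        self._validate()

    def _validate(self) -> None:
        fam, p = self.family, self.params
        if fam is Family.UNIF:
            if len(p) != 2 or not p[0] < p[1]:
                raise ParameterError(f"UNIF requires a < b, got params={p}")
        elif fam is Family.ERLA:
            if len(p) != 2:
                raise ParameterError(f"ERLA requires (stage_mean, k), got {p}")
            x, k = p
            if x <= 0:
                raise ParameterError(f"ERLA stage_mean must be > 0, got {x}")
            if k < 1 or abs(k - round(k)) > 1e-9:
                raise ParameterError(f"ERLA k must be an integer >= 1, got {k}")
        elif fam is Family.EXPO:
            if len(p) != 1 or p[0] <= 0:
                raise ParameterError(f"EXPO mean must be > 0, got params={p}")
        elif fam is Family.LOGN:
            if len(p) != 2:
                raise ParameterError(f"LOGN requires (mean, sd), got {p}")
            if p[0] <= 0:
                raise ParameterError(f"LOGN mean must be > 0, got {p[0]}")
            if p[1] < 0:
                raise ParameterError(f"LOGN sd must be >= 0, got {p[1]}")
        elif fam is Family.BETA:
            if len(p) != 2 or p[0] <= 0 or p[1] <= 0:
                raise ParameterError(f"BETA shapes must be > 0, got params={p}")
            if self.scale is None or self.scale <= 0:
                raise ParameterError(f"BETA scale must be > 0, got {self.scale}")
        elif fam is Family.GAMM:
            if len(p) != 2 or p[0] <= 0 or p[1] <= 0:
                raise ParameterError(f"GAMM requires scale > 0 and shape > 0, got {p}")
        if fam is not Family.BETA and self.scale is not None:
            raise ParameterError(f"scale is only valid for BETA, got family {fam.value}")

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = {"family": self.family.value, "params": list(self.params), "offset": self.offset}
        if self.scale is not None:
            d["scale"] = self.scale
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "DistributionSpec":
        return cls(
            family=Family(d["family"]),
            params=tuple(d["params"]),
            offset=float(d.get("offset", 0.0)),
            scale=d.get("scale"),
        )


def lognormal_underlying(arith_mean: float, arith_sd: float) -> tuple[float, float]:
    """Underlying normal ``(mu, sigma)`` for a lognormal with the given
    arithmetic mean and sd.

    ``sigma^2 = ln(1 + (sd/mean)^2)``, ``mu = ln(mean) - sigma^2 / 2``.
    ``sd = 0`` degenerates to a point mass at ``mean``.
    """
    if arith_mean <= 0:
        raise ParameterError(f"lognormal arithmetic mean must be > 0, got {arith_mean}")
    if arith_sd < 0:
        raise ParameterError(f"lognormal arithmetic sd must be >= 0, got {arith_sd}")
    sigma2 = math.log1p((arith_sd / arith_mean) ** 2)
    mu = math.log(arith_mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def sample(spec: DistributionSpec, rng: np.random.Generator, size: int | None = None):
    """Draw ``offset + family(params)``; scalar when ``size`` is None."""
    fam, p = spec.family, spec.params
    if fam is Family.UNIF:
        draw = rng.uniform(p[0], p[1], size=size)
    elif fam is Family.ERLA:
        draw = rng.gamma(shape=round(p[1]), scale=p[0], size=size)
    elif fam is Family.EXPO:
        draw = rng.exponential(p[0], size=size)
    elif fam is Family.LOGN:
        if p[1] == 0:
            draw = np.full(size, p[0]) if size is not None else p[0]
        else:
            mu, sigma = lognormal_underlying(p[0], p[1])
            draw = rng.lognormal(mu, sigma, size=size)
    elif fam is Family.BETA:
        draw = spec.scale * rng.beta(p[0], p[1], size=size)
    elif fam is Family.GAMM:
        draw = rng.gamma(shape=p[1], scale=p[0], size=size)
    else:  # pragma: no cover
        raise ParameterError(f"unknown family {fam}")
    return spec.offset + draw


def analytic_mean(spec: DistributionSpec) -> float:
    """Closed-form mean, offset included."""
    fam, p = spec.family, spec.params
    if fam is Family.UNIF:
        m = (p[0] + p[1]) / 2.0
    elif fam is Family.ERLA:
        m = p[0] * round(p[1])
    elif fam is Family.EXPO:
        m = p[0]
    elif fam is Family.LOGN:
        m = p[0]
    elif fam is Family.BETA:
        m = spec.scale * p[0] / (p[0] + p[1])
    elif fam is Family.GAMM:
        m = p[0] * p[1]
    else:  # pragma: no cover
        raise ParameterError(f"unknown family {fam}")
    return spec.offset + m


def analytic_sd(spec: DistributionSpec) -> float:
    """Closed-form standard deviation (the additive offset does not enter)."""
    fam, p = spec.family, spec.params
    if fam is Family.UNIF:
        return (p[1] - p[0]) / math.sqrt(12.0)
    if fam is Family.ERLA:
        return p[0] * math.sqrt(round(p[1]))
    if fam is Family.EXPO:
        return p[0]
    if fam is Family.LOGN:
        return p[1]
    if fam is Family.BETA:
        b, a = p
        return spec.scale * math.sqrt(a * b / ((a + b) ** 2 * (a + b + 1.0)))
    if fam is Family.GAMM:
        return p[0] * math.sqrt(p[1])
    raise ParameterError(f"unknown family {fam}")  # pragma: no cover


def to_scipy(spec: DistributionSpec):
    """Frozen scipy distribution equivalent to ``spec`` (offset as ``loc``)."""
    fam, p, off = spec.family, spec.params, spec.offset
    if fam is Family.UNIF:
        return stats.uniform(loc=off + p[0], scale=p[1] - p[0])
    if fam is Family.ERLA:
        return stats.gamma(round(p[1]), loc=off, scale=p[0])
    if fam is Family.EXPO:
        return stats.expon(loc=off, scale=p[0])
    if fam is Family.LOGN:
        mu, sigma = lognormal_underlying(p[0], p[1])
        return stats.lognorm(sigma, loc=off, scale=math.exp(mu))
    if fam is Family.BETA:
        return stats.beta(p[0], p[1], loc=off, scale=spec.scale)
    if fam is Family.GAMM:
        return stats.gamma(p[1], loc=off, scale=p[0])
    raise ParameterError(f"unknown family {fam}")  # pragma: no cover


# ---------------------------------------------------------------------------
# fitting


def _lognormal_arith(sigma: float, scale: float) -> tuple[float, float]:
    m = scale * math.exp(sigma**2 / 2.0)
    return m, m * math.sqrt(math.expm1(sigma**2))


def _fit_family(fam: Family, x: np.ndarray) -> DistributionSpec | None:
    """Maximum-likelihood fit of one family, location offset included.

    The additive offset is estimated per family (three-parameter fit); a
    negative fitted location is clamped by refitting with the offset pinned
    at zero, since a service time cannot start below zero minutes.  Returns
    None when the family cannot be fitted (numerical failure).
    """
    try:
        if fam is Family.UNIF:
            # Arena-style uniforms carry no additive offset: report endpoints
            return DistributionSpec(Family.UNIF, (x.min(), x.max()))
        if fam is Family.EXPO:
            loc, scale = stats.expon.fit(x)
            if loc < 0:
                loc, scale = 0.0, float(x.mean())
            return DistributionSpec(Family.EXPO, (scale,), offset=loc)
        if fam in (Family.GAMM, Family.ERLA):
            shape, loc, scale = stats.gamma.fit(x)
            if loc < 0:
                shape, loc, scale = stats.gamma.fit(x, floc=0.0)
            if fam is Family.GAMM:
                return DistributionSpec(Family.GAMM, (scale, shape), offset=loc)
            k = max(1, int(round(shape)))
            # given integer stage count k, the stage-mean MLE is the shifted mean / k
            return DistributionSpec(Family.ERLA, (float(x.mean() - loc) / k, k), offset=loc)
        if fam is Family.LOGN:
            sigma, loc, scale = stats.lognorm.fit(x)
            if loc < 0:
                sigma, loc, scale = stats.lognorm.fit(x, floc=0.0)
            return DistributionSpec(Family.LOGN, _lognormal_arith(sigma, scale), offset=loc)
        if fam is Family.BETA:
            a, b, loc, scale = stats.beta.fit(x)
            if loc < 0:
                a, b, loc, scale = stats.beta.fit(x, floc=0.0)
            return DistributionSpec(Family.BETA, (a, b), offset=loc, scale=scale)
    except Exception:
        return None
    return None  # pragma: no cover


def fit_distribution(
    samples: Sequence[float] | np.ndarray,
    candidates: Iterable[Family | str] | None = None,
) -> tuple[DistributionSpec, dict]:
    """Fit candidate families to observed durations and pick the best.

    Each family is fitted by maximum likelihood with its own location
    offset (clamped to >= 0).  Selection is by smallest Kolmogorov-Smirnov
    statistic, with a parsimony rule for near-ties: families whose KS
    statistic is within ``1/sqrt(n)`` of the best — one noise unit of the
    statistic, below its 5% critical value ``1.36/sqrt(n)`` — count as
    equivalent fits, and the one
    with the fewest free parameters wins (so a plain uniform is preferred
    over a beta that merely mimics it).

    Returns ``(selected_spec, report)`` where ``report`` maps family name to
    ``{"spec", "ks", "pvalue"}`` for every candidate that could be fitted.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1 or len(x) < 30:
        raise InsufficientDataError(f"need at least 30 samples, got {len(np.atleast_1d(x))}")
    if not np.all(np.isfinite(x)) or np.any(x <= 0):
        raise ParameterError("samples must be finite and positive")
    if float(x.std()) == 0.0:
        raise DegenerateDataError("samples have zero variance")

    if candidates is None:
        candidates = list(Family)
    fams = [Family(c) for c in candidates]

    report: dict[str, dict] = {}
    fitted: list[tuple[float, int, str, DistributionSpec]] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy MLE emits benign RuntimeWarnings
        for fam in fams:
            spec = _fit_family(fam, x)
            if spec is None:
                continue
            ks = stats.kstest(x, to_scipy(spec).cdf)
            report[fam.value] = {
                "spec": spec,
                "ks": float(ks.statistic),
                "pvalue": float(ks.pvalue),
            }
            fitted.append((float(ks.statistic), _N_PARAMS[fam], fam.value, spec))
    if not fitted:
        raise DegenerateDataError("no candidate family could be fitted")
    fitted.sort()
    margin = 1.0 / math.sqrt(len(x))
    near = [f for f in fitted if f[0] <= fitted[0][0] + margin]
    near.sort(key=lambda f: (f[1], f[0]))
    return near[0][3], report
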