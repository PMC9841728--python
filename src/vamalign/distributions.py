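"""Parametric latent-answer distributions and their cell probabilities.

The latent quantity behind a grouped response (weekly activity duration) is
modelled with a nonnegative continuous distribution; the default family is
Gamma with shape ``alpha`` and scale ``beta`` (density
``x**(alpha-1) * exp(-x/beta) / (beta**alpha * Gamma(alpha))``, mean
``alpha * beta``).  The family registry is pluggable — anything exposing a CDF
and a mean over named positive parameters can be registered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
from scipy import stats

from .containers import ProbVector
from .scales import Interval, IntervalScale, InvalidScaleError

__all__ = [
    "Family",
    "DistributionSpec",
    "register_family",
    "get_family",
    "interval_probability",
    "cell_probabilities",
]


@dataclass(frozen=True)
class Family:
    """A parametric family: named positive parameters, a CDF and a mean."""

    name: str
    param_names: tuple[str, ...]
    cdf: Callable[[np.ndarray, Mapping[str, float]], np.ndarray]
    mean: Callable[[Mapping[str, float]], float]
    #: method-of-moments initializer: (mean, variance) -> params
    mom_init: Callable[[float, float], dict[str, float]]


def _gamma_cdf(x, params):
    return stats.gamma.cdf(x, a=params["shape"], scale=params["scale"])


def _gamma_mom(mean: float, var: float) -> dict[str, float]:
    var = max(var, 1e-6)
    mean = max(mean, 1e-6)
    return {"shape": mean * mean / var, "scale": var / mean}


def _lognorm_cdf(x, params):
    return stats.lognorm.cdf(x, s=params["sigma"], scale=params["median"])


def _lognorm_mom(mean: float, var: float) -> dict[str, float]:
    mean = max(mean, 1e-6)
    s2 = math.log1p(max(var, 1e-6) / mean**2)
    return {"sigma": math.sqrt(max(s2, 1e-6)), "median": mean * math.exp(-s2 / 2)}


_FAMILIES: dict[str, Family] = {}


def register_family(family: Family) -> None:
    _FAMILIES[family.name] = family


def get_family(name: str) -> Family:
    try:
        return _FAMILIES[name]
    except KeyError:
        raise ValueError(
            f"unsupported distribution family {name!r}; known: {sorted(_FAMILIES)}"
        ) from None


register_family(
    Family(
        name="gamma",
        param_names=("shape", "scale"),
        cdf=_gamma_cdf,
        mean=lambda p: p["shape"] * p["scale"],
        mom_init=_gamma_mom,
    )
)
register_family(
    Family(
        name="lognormal",
        param_names=("sigma", "median"),
        cdf=_lognorm_cdf,
        mean=lambda p: p["median"] * math.exp(p["sigma"] ** 2 / 2),
        mom_init=_lognorm_mom,
    )
)


@dataclass(frozen=True)
class DistributionSpec:
    """A family name plus a concrete parameter assignment."""

    family: str = "gamma"
    params: Mapping[str, float] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        fam = get_family(self.family)
        params = dict(self.params or {})
        missing = set(fam.param_names) - set(params)
        if missing:
            raise ValueError(f"{self.family} needs parameters {sorted(missing)}")
        for k, v in params.items():
            if k not in fam.param_names:
                raise ValueError(f"unknown {self.family} parameter {k!r}")
            if not v > 0:
                raise ValueError(f"parameter {k}={v} outside family support")
        object.__setattr__(self, "params", params)

    @classmethod
    def gamma(cls, shape: float, scale: float) -> "DistributionSpec":
        return cls("gamma", {"shape": shape, "scale": scale})

    def cdf(self, x) -> np.ndarray:
        return get_family(self.family).cdf(np.asarray(x, dtype=float), self.params)

    def mean(self) -> float:
        return float(get_family(self.family).mean(self.params))

    def rvs(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.family == "gamma":
            return rng.gamma(self.params["shape"], self.params["scale"], size=n)
        if self.family == "lognormal":
            return self.params["median"] * np.exp(
                rng.normal(0.0, self.params["sigma"], size=n)
            )
        raise ValueError(f"sampling not implemented for family {self.family!r}")


def interval_probability(dist: DistributionSpec, interval: Interval | None) -> float:
    """Probability mass of ``dist`` on a half-open interval; 0 for an empty one."""
    if interval is None:
        return 0.0
    hi = 1.0 if math.isinf(interval.ub) else float(dist.cdf(interval.ub))
    return float(hi - dist.cdf(interval.lb))


def cell_probabilities(dist: DistributionSpec, scale: IntervalScale) -> ProbVector:
    """Per-option probabilities ``CDF(ub_i) - CDF(lb_i)`` on a contiguous scale.

    The scale must cover ``[0, inf)`` so the cells sum to 1 (within 1e-12).
    """
    if not scale.covers_half_line:
        raise InvalidScaleError(
            f"scale {scale.version_id!r} must be contiguous over [0, inf) "
            "(smoothed, top-coded) to define cell probabilities"
        )
    edges = np.array(scale.edges())
    cdf = np.empty(len(edges))
    finite = np.isfinite(edges)
    cdf[finite] = dist.cdf(edges[finite])
    cdf[~finite] = 1.0
    return ProbVector(scale, np.diff(cdf), atol=1e-12)
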