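"""Validation machinery: bootstrap distance intervals, trend regression, error reports.

Even two probability vectors drawn from the *same* latent distribution differ
by sampling noise, so an alignment error can only be judged against the
distance distribution expected under identity.  :func:`bootstrap_distance_ci`
builds that yardstick: two independent groups of multinomial relative-frequency
vectors, all cross-group pairwise distances, and the central 95% interval of
their distribution.  :func:`trend_regression` provides the ordinary
least-squares trend check on annual means, and
:func:`estimation_error_report` the per-vector error metrics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .containers import KL_UNDEFINED, ProbVector, kl_divergence, linf
from .distributions import DistributionSpec, cell_probabilities
from .scales import IntervalScale

__all__ = [
    "DistanceCI",
    "bootstrap_distance_ci",
    "TrendFit",
    "trend_regression",
    "estimation_error_report",
]


@dataclass(frozen=True)
class DistanceCI:
    """Central 95% interval of cross-group pairwise distances."""

    metric: str
    n: int
    n_vectors: int
    lo: float
    hi: float
    seed: int
    n_pairs: int
    n_undefined: int = 0  # KL pairs excluded for zero reference cells

    def contains(self, value: float) -> bool:
        return self.lo <= value <= self.hi


def _cross_linf(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    return np.abs(g1[:, None, :] - g2[None, :, :]).max(axis=2).ravel()


def _cross_kl(g1: np.ndarray, g2: np.ndarray) -> tuple[np.ndarray, int]:
    p = g1[:, None, :]
    q = g2[None, :, :]
    undefined = ((q == 0) & (p > 0)).any(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0) / np.where(q > 0, q, 1.0)), 0.0)
    kl = terms.sum(axis=2).ravel()
    mask = ~undefined.ravel()
    return kl[mask], int(undefined.sum())


def bootstrap_distance_ci(
    dist: DistributionSpec,
    scale: IntervalScale,
    n: int,
    n_vectors: int = 1000,
    metric: Literal["linf", "kl"] = "linf",
    seed: int = 0,
    dist2: DistributionSpec | None = None,
) -> DistanceCI:
    """95% interval of distances between same-distribution probability vectors.

    Two independent groups of ``n_vectors`` relative-frequency vectors are
    generated, each from ``n`` multinomial draws over the scale's cell
    probabilities; all ``n_vectors**2`` cross-group distances are computed and
    the 2.5th/97.5th percentiles (linear interpolation between order
    statistics) returned.  ``dist2`` lets the second group come from a drifted
    distribution.  KL pairs with a zero reference cell are excluded and
    counted.
    """
    if n < 1 or n_vectors < 2:
        raise ValueError("need n >= 1 and at least 2 vectors per group")
    if metric not in ("linf", "kl"):
        raise ValueError(f"unknown metric {metric!r}")
    rng = np.random.default_rng(seed)
    cells1 = cell_probabilities(dist, scale).probs
    cells2 = cell_probabilities(dist2 or dist, scale).probs
    g1 = rng.multinomial(n, cells1, size=n_vectors) / n
    g2 = rng.multinomial(n, cells2, size=n_vectors) / n
    n_undefined = 0
    if metric == "linf":
        distances = _cross_linf(g1, g2)
    else:
        distances, n_undefined = _cross_kl(g1, g2)
    lo, hi = np.percentile(distances, [2.5, 97.5])
    return DistanceCI(
        metric=metric,
        n=n,
        n_vectors=n_vectors,
        lo=float(lo),
        hi=float(hi),
        seed=seed,
        n_pairs=len(distances),
        n_undefined=n_undefined,
    )


@dataclass(frozen=True)
class TrendFit:
    """Ordinary least-squares line through annual values."""

    slope: float
    intercept: float
    r_squared: float
    target_year: float
    prediction: float

    def summary(self) -> str:
        return (
            f"OLS trend: slope {self.slope:.5f}, intercept {self.intercept:.5f}, "
            f"R^2 {self.r_squared:.3f}; prediction at {self.target_year:g}: "
            f"{self.prediction:.5f}"
        )


def trend_regression(
    years: Sequence[float], values: Sequence[float], target_year: float
) -> TrendFit:
    """OLS of annual values on year, with an out-of-window prediction."""
    years = np.asarray(years, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(years) != len(values) or len(years) < 3:
        raise ValueError("need at least 3 (year, value) points")
    if np.ptp(years) == 0:
        raise ValueError("years must not be constant")
    res = stats.linregress(years, values)
    return TrendFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        target_year=float(target_year),
        prediction=float(res.intercept + res.slope * target_year),
    )


def estimation_error_report(
    estimate: ProbVector,
    truth: ProbVector,
    ci_linf: DistanceCI | None = None,
    ci_kl: DistanceCI | None = None,
) -> dict:
    """Distance of an estimated response distribution from the truth.

    Reports L-infinity and KL (the latter may be the undefined sentinel), and
    flags containment in supplied same-distribution bootstrap intervals.  An
    error *below* an interval's lower endpoint is closer to the truth than
    typical same-distribution sampling noise, which also counts in favour of
    the estimate.
    """
    report: dict = {"linf": linf(estimate, truth), "kl": kl_divergence(estimate, truth)}
    if ci_linf is not None:
        report["linf_in_ci"] = ci_linf.contains(report["linf"])
    if ci_kl is not None and report["kl"] is not KL_UNDEFINED:
        report["kl_in_ci"] = ci_kl.contains(report["kl"])
    return report
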