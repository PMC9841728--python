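"""Counts, probability vectors, transition matrices and paired cohort responses.

These are the in-memory containers shared by every estimator and the solver.
Probability vectors are discrete response distributions over one scale's
options; transition matrices are column-stochastic, entry ``(i, j)`` being the
probability that a respondent moves from option ``j`` to option ``i`` between
two observation times (or across a questionnaire revision).

Distances: the L-infinity distance is the maximum absolute per-option
difference; for matrices it is taken column-wise, which equals the element-wise
maximum.  KL divergence is also provided; it is undefined whenever the
reference vector has a zero cell where the first vector has mass, and that
outcome is reported with a typed sentinel rather than a NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .scales import IntervalScale

__all__ = [
    "CountVector",
    "ProbVector",
    "TransitionMatrix",
    "PairedResponses",
    "KL_UNDEFINED",
    "IncompatibleScalesError",
    "EmptySampleError",
    "linf",
    "linf_matrix",
    "kl_divergence",
    "estimate_transition_matrix",
    "apply_transition",
]


class IncompatibleScalesError(ValueError):
    """Two objects do not share the dimension/scale the operation requires."""


class EmptySampleError(ValueError):
    """An operation requiring observations received none."""


class _KLUndefined:
    """Sentinel for a KL divergence that is undefined (zero reference cell)."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "KL_UNDEFINED"


KL_UNDEFINED = _KLUndefined()

#: Default tolerance on probability normalization. Probabilities are carried at
#: full double precision; this tolerance only gates validation of inputs.
PROB_ATOL = 1e-4


@dataclass(frozen=True)
class CountVector:
    """Observed response counts per option of one scale."""

    scale: IntervalScale
    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        if c.ndim != 1 or len(c) != self.scale.d:
            raise IncompatibleScalesError(
                f"expected {self.scale.d} counts for scale {self.scale.version_id!r}, got {c.shape}"
            )
        if np.any(c < 0):
            raise ValueError("counts must be nonnegative")
        object.__setattr__(self, "counts", c)

    @property
    def n(self) -> float:
        return float(self.counts.sum())

    def to_probvector(self) -> "ProbVector":
        """Relative frequencies ``counts / n``; errors on an empty sample."""
        if self.n == 0:
            raise EmptySampleError("cannot form relative frequencies from zero observations")
        return ProbVector(self.scale, self.counts / self.n)


@dataclass(frozen=True)
class ProbVector:
    """Relative response frequencies over one scale's options.

    Entries must lie in [0, 1] and sum to 1 within ``atol``.  Printed vectors
    from published tables are rounded, so loaders may pass a looser ``atol``;
    the stored entries are never silently rescaled.
    """

    scale: IntervalScale
    probs: np.ndarray
    atol: float = field(default=PROB_ATOL, compare=False)

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 1 or len(p) != self.scale.d:
            raise IncompatibleScalesError(
                f"expected {self.scale.d} probabilities for scale "
                f"{self.scale.version_id!r}, got {p.shape}"
            )
        if np.any(p < -1e-12) or np.any(p > 1 + 1e-12):
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(p.sum() - 1.0) > self.atol:
            raise ValueError(f"probabilities sum to {p.sum():.6f}, not 1 (atol={self.atol})")
        object.__setattr__(self, "probs", p)

    @property
    def d(self) -> int:
        return len(self.probs)

    def normalized(self) -> "ProbVector":
        """Rescale to sum exactly 1 (repairs print rounding)."""
        return ProbVector(self.scale, self.probs / self.probs.sum())

    def rounded(self, decimals: int = 5) -> np.ndarray:
        """Reporting convention: probabilities rounded to 5 decimals."""
        return np.round(self.probs, decimals)


@dataclass(frozen=True)
class TransitionMatrix:
    """Column-stochastic option-to-option transition probabilities.

    Shape is ``(d_to, d_from)``: column ``j`` is the response distribution at
    the later time (or revised scale) of respondents who chose option ``j``
    before.
    """

    from_scale: IntervalScale
    to_scale: IntervalScale
    entries: np.ndarray
    atol: float = field(default=PROB_ATOL, compare=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.entries, dtype=float)
        expected = (self.to_scale.d, self.from_scale.d)
        if m.shape != expected:
            raise IncompatibleScalesError(
                f"expected a {expected} matrix, got {m.shape}"
            )
        if np.any(m < -1e-12) or np.any(m > 1 + 1e-12):
            raise ValueError("transition probabilities must lie in [0, 1]")
        colsums = m.sum(axis=0)
        if np.any(np.abs(colsums - 1.0) > self.atol):
            raise ValueError(
                f"columns must sum to 1 within {self.atol}; got sums {colsums}"
            )
        object.__setattr__(self, "entries", m)

    @property
    def shape(self) -> tuple[int, int]:
        return self.entries.shape

    def normalized(self) -> "TransitionMatrix":
        """Rescale every column to sum exactly 1 (repairs print rounding)."""
        return TransitionMatrix(
            self.from_scale, self.to_scale, self.entries / self.entries.sum(axis=0)
        )

    def column(self, j: int) -> ProbVector:
        """Column ``j`` (0-based) as a probability vector on the target scale."""
        return ProbVector(self.to_scale, self.entries[:, j], atol=self.atol)


@dataclass(frozen=True)
class PairedResponses:
    """Individual-level cohort responses at two consecutive times.

    ``records`` rows are ``(individual id, option at t1 on scale1, option at t2
    on scale2)`` with 1-based option indices.  A cohort spanning a revision has
    ``scale1 != scale2``.
    """

    scale1: IntervalScale
    scale2: IntervalScale
    ids: np.ndarray
    options_t1: np.ndarray
    options_t2: np.ndarray
    t1: str = "t1"
    t2: str = "t2"

    def __post_init__(self) -> None:
        ids = np.asarray(self.ids)
        o1 = np.asarray(self.options_t1, dtype=int)
        o2 = np.asarray(self.options_t2, dtype=int)
        if not (len(ids) == len(o1) == len(o2)):
            raise ValueError("ids and option arrays must have equal length")
        if len(np.unique(ids)) != len(ids):
            raise ValueError("individual ids must be unique")
        if len(o1) and (o1.min() < 1 or o1.max() > self.scale1.d):
            raise ValueError("t1 option index outside scale range")
        if len(o2) and (o2.min() < 1 or o2.max() > self.scale2.d):
            raise ValueError("t2 option index outside scale range")
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "options_t1", o1)
        object.__setattr__(self, "options_t2", o2)

    def __len__(self) -> int:
        return len(self.ids)

    def counts_t1(self) -> CountVector:
        return CountVector(
            self.scale1, np.bincount(self.options_t1, minlength=self.scale1.d + 1)[1:]
        )

    def counts_t2(self) -> CountVector:
        return CountVector(
            self.scale2, np.bincount(self.options_t2, minlength=self.scale2.d + 1)[1:]
        )


def _check_same_dim(p: ProbVector, q: ProbVector) -> None:
    if p.d != q.d:
        raise IncompatibleScalesError(f"dimension mismatch: {p.d} vs {q.d}")


def linf(p: ProbVector, q: ProbVector) -> float:
    """L-infinity distance: the maximum absolute per-option difference."""
    _check_same_dim(p, q)
    return float(np.max(np.abs(p.probs - q.probs)))


def linf_matrix(m: TransitionMatrix, n: TransitionMatrix) -> float:
    """Matrix L-infinity: the maximum column-wise L-infinity distance.

    Because columns partition the entries, this equals the element-wise
    maximum absolute difference.
    """
    if m.shape != n.shape:
        raise IncompatibleScalesError(f"dimension mismatch: {m.shape} vs {n.shape}")
    return float(np.max(np.abs(m.entries - n.entries)))


def kl_divergence(p: ProbVector, q: ProbVector) -> float | _KLUndefined:
    """KL divergence ``sum_i p_i ln(p_i / q_i)`` with ``0 ln 0 = 0``.

    Returns :data:`KL_UNDEFINED` when ``q`` has a zero cell where ``p`` has
    positive mass.
    """
    _check_same_dim(p, q)
    pv, qv = p.probs, q.probs
    if np.any((qv == 0) & (pv > 0)):
        return KL_UNDEFINED
    mask = pv > 0
    return float(np.sum(pv[mask] * np.log(pv[mask] / qv[mask])))


def estimate_transition_matrix(
    pairs: PairedResponses,
    empty_column: Literal["error", "uniform", "identity"] = "error",
) -> TransitionMatrix:
    """Estimate the cohort transition matrix by direct counting.

    Entry ``(i, j)`` is the fraction of individuals who chose option ``j`` at
    t1 and option ``i`` at t2, among those who chose ``j`` at t1; columns sum
    to 1 exactly (rational counting).

    A source option nobody chose leaves its column undefined; by default this
    is an error.  ``empty_column='uniform'`` fills it with the uniform
    distribution, ``'identity'`` with the unit vector on the same option
    (square scales only).
    """
    if len(pairs) == 0:
        raise EmptySampleError("no paired responses")
    d1, d2 = pairs.scale1.d, pairs.scale2.d
    joint = np.zeros((d2, d1))
    np.add.at(joint, (pairs.options_t2 - 1, pairs.options_t1 - 1), 1.0)
    col_tot = joint.sum(axis=0)
    empty = col_tot == 0
    if np.any(empty):
        missing = [int(j) + 1 for j in np.flatnonzero(empty)]
        if empty_column == "error":
            raise EmptySampleError(
                f"no t1 observations for source option(s) {missing}; "
                "choose an explicit empty-column policy to fill them"
            )
        if empty_column == "uniform":
            joint[:, empty] = 1.0 / d2
        elif empty_column == "identity":
            if d1 != d2:
                raise IncompatibleScalesError(
                    "identity fill requires equal source and target dimensions"
                )
            for j in np.flatnonzero(empty):
                joint[j, j] = 1.0
        else:  # pragma: no cover - guarded by Literal
            raise ValueError(f"unknown empty-column policy {empty_column!r}")
        col_tot = joint.sum(axis=0)
    return TransitionMatrix(pairs.scale1, pairs.scale2, joint / col_tot)


def apply_transition(t: TransitionMatrix, p: ProbVector) -> ProbVector:
    """Push a response distribution through a transition matrix: ``T @ p``.

    Total probability is conserved (to 1e-12) when the inputs are exactly
    normalized, because each column of ``t`` sums to 1.
    """
    if p.d != t.from_scale.d:
        raise IncompatibleScalesError(
            f"vector has {p.d} options but matrix expects {t.from_scale.d}"
        )
    out = t.entries @ p.probs
    # product of a tolerance-validated matrix and vector can be off 1 by up to
    # the inputs' own slack; validate with the combined tolerance
    return ProbVector(t.to_scale, out, atol=max(p.atol, t.atol) * (1 + p.d))
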