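"""Interval scales for grouped (binned) survey responses.

A grouped-data questionnaire item offers ``d`` ordered options, each standing
for a half-open numeric interval ``[lb, ub)`` of the underlying continuous
quantity (here: weekly duration in hours/week).  The top option is typically
top-coded, i.e. has ``ub = inf``.  Scales whose printed option intervals leave
gaps (respondents are assumed to pick the nearest option) are repaired with
:meth:`IntervalScale.smooth_gaps`, which splits each gap at its midpoint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

__all__ = ["Interval", "IntervalScale", "InvalidScaleError"]


class InvalidScaleError(ValueError):
    """Raised when intervals overlap, are unordered, or are otherwise unusable."""


@dataclass(frozen=True)
class Interval:
    """Half-open interval ``[lb, ub)``; ``ub`` may be ``math.inf``.

    Membership follows the half-open rule: ``lb <= x < ub``, so a value on a
    shared boundary belongs to the upper interval.
    """

    lb: float
    ub: float

    def __post_init__(self) -> None:
        if not (self.lb >= 0 and self.lb < self.ub):
            raise InvalidScaleError(
                f"invalid interval [{self.lb}, {self.ub}): need 0 <= lb < ub"
            )

    def __contains__(self, x: float) -> bool:
        return self.lb <= x < self.ub

    @property
    def width(self) -> float:
        return self.ub - self.lb

    def midpoint(self) -> float:
        """Midpoint of a finite interval; the lower bound if top-coded.

        The top-coded convention (use ``lb`` for ``[lb, inf)``) deliberately
        underestimates the open tail; see the grouped-MLE estimator for the
        model-based alternative.
        """
        if math.isinf(self.ub):
            return self.lb
        return 0.5 * (self.lb + self.ub)

    def intersect(self, other: "Interval") -> "Interval | None":
        lb = max(self.lb, other.lb)
        ub = min(self.ub, other.ub)
        if lb >= ub:
            return None
        return Interval(lb, ub)


@dataclass(frozen=True)
class IntervalScale:
    """An ordered set of disjoint half-open intervals defining one questionnaire version.

    Option indices are 1-based (option ``i`` maps to ``intervals[i-1]``),
    matching the usual coding of multiple-choice responses.
    """

    version_id: str
    intervals: tuple[Interval, ...]
    labels: tuple[str, ...] | None = field(default=None)

    def __post_init__(self) -> None:
        ivs = tuple(
            iv if isinstance(iv, Interval) else Interval(*iv) for iv in self.intervals
        )
        object.__setattr__(self, "intervals", ivs)
        if not ivs:
            raise InvalidScaleError("scale needs at least one interval")
        for a, b in zip(ivs, ivs[1:]):
            if b.lb < a.ub:
                raise InvalidScaleError(
                    f"intervals overlap or are unordered: [{a.lb},{a.ub}) then [{b.lb},{b.ub})"
                )
        if self.labels is not None:
            labels = tuple(self.labels)
            if len(labels) != len(ivs):
                raise InvalidScaleError("labels length must match interval count")
            object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def d(self) -> int:
        """Number of options."""
        return len(self.intervals)

    @property
    def is_contiguous(self) -> bool:
        """True when every pair of adjacent interval bounds meets exactly."""
        ivs = self.intervals
        return all(a.ub == b.lb for a, b in zip(ivs, ivs[1:]))

    @property
    def covers_half_line(self) -> bool:
        """True when the scale is contiguous from 0 up to a top-coded interval."""
        return (
            self.is_contiguous
            and self.intervals[0].lb == 0.0
            and math.isinf(self.intervals[-1].ub)
        )

    def edges(self) -> list[float]:
        """Bin edges ``[lb_1, ub_1, ..., ub_d]``; requires a contiguous scale."""
        if not self.is_contiguous:
            raise InvalidScaleError(
                f"scale {self.version_id!r} is not contiguous; call smooth_gaps() first"
            )
        return [iv.lb for iv in self.intervals] + [self.intervals[-1].ub]

    def smooth_gaps(self) -> "IntervalScale":
        """Return a contiguous scale, splitting every inter-option gap at its midpoint.

        Each gap ``(ub_i, lb_{i+1})`` is divided evenly between the adjacent
        options: ``ub_i`` is extended and ``lb_{i+1}`` lowered to the gap's
        midpoint.  This realizes the assumption that a respondent whose answer
        falls between two printed options picks the nearer one.  The outer
        bounds are left untouched.  Idempotent; option count preserved; every
        original interval is a subset of its smoothed version.
        """
        ivs = self.intervals
        lbs = [iv.lb for iv in ivs]
        ubs = [iv.ub for iv in ivs]
        for i in range(len(ivs) - 1):
            if ubs[i] < lbs[i + 1]:
                mid = 0.5 * (ubs[i] + lbs[i + 1])
                ubs[i] = mid
                lbs[i + 1] = mid
        smoothed = tuple(Interval(lb, ub) for lb, ub in zip(lbs, ubs))
        if smoothed == ivs:
            return self
        return IntervalScale(self.version_id, smoothed, self.labels)

    def index_of(self, x: float) -> int:
        """1-based option index of the interval containing ``x``."""
        for i, iv in enumerate(self.intervals, start=1):
            if x in iv:
                return i
        raise ValueError(f"value {x} outside the support of scale {self.version_id!r}")

    def interval_midpoints(self) -> list[float]:
        """Per-option representative values for the midpoint method.

        Finite ``[a, b)`` contributes ``(a+b)/2``; the top-coded interval
        contributes its lower bound.  An internal infinite bound is invalid.
        """
        for iv in self.intervals[:-1]:
            if math.isinf(iv.ub):
                raise InvalidScaleError("only the last interval may be top-coded")
        return [iv.midpoint() for iv in self.intervals]


def q1997_scale() -> IntervalScale:
    """The 4-option 1997 duration scale: {[0,1),[1,2),[2,3),[3,inf)}."""
    return IntervalScale(
        "Q1997", (Interval(0, 1), Interval(1, 2), Interval(2, 3), Interval(3, math.inf))
    )


def q1998_scale_raw() -> IntervalScale:
    """The 5-option 1998 duration scale as printed, with gaps between options."""
    return IntervalScale(
        "Q1998-raw",
        (
            Interval(0, 1),
            Interval(1, 2),
            Interval(3, 4),
            Interval(5, 6),
            Interval(7, math.inf),
        ),
    )


def q1998_scale() -> IntervalScale:
    """The gap-smoothed 1998 scale: {[0,1),[1,2.5),[2.5,4.5),[4.5,6.5),[6.5,inf)}."""
    return IntervalScale(
        "Q1998",
        (
            Interval(0, 1),
            Interval(1, 2.5),
            Interval(2.5, 4.5),
            Interval(4.5, 6.5),
            Interval(6.5, math.inf),
        ),
    )
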