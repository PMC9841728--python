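"""Packaged worked-example fixtures: the published vectors and matrices.

The underlying health-screening panel (weekly leisure-time physical-activity
duration, 1997-2008, with a questionnaire revision between 1997 and 1998) is
access-restricted, but the published analysis prints every vector and matrix
of its worked example.  Those printed values ship here as small CSV fixtures
for linear-algebra checks and demonstrations.  They carry 3-4 significant
digits, so probability sums are off 1 by up to ~3e-3; loaders therefore
validate with a loosened tolerance and the matrices expose a
column-renormalized form via ``.normalized()``.

Note the printed ideal revision matrix (``printed_G``) is numerically
near-identical to the printed estimated revision factor (``printed_A_hat``)
and is *not* reproduced by the conditional-probability formula for these
scales (nested source intervals force unit columns, which it lacks); both are
fixtures for downstream algebra only, never correctness targets for the
ideal-matrix construction.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .containers import ProbVector, TransitionMatrix
from .scales import IntervalScale, q1997_scale, q1998_scale

__all__ = [
    "printed_u_1997",
    "printed_v_prime_1997",
    "printed_y_1997",
    "printed_z_1997",
    "printed_v_1997",
    "printed_T_1997",
    "printed_B_1998",
    "printed_A_hat_1997",
    "printed_G",
    "annual_means",
]

#: printed probabilities are rounded to 3-4 digits; sums land within ~3e-3 of 1
PRINTED_ATOL = 5e-3


def _path(name: str):
    return resources.files("vamalign.data").joinpath(name)


def _vector(name: str, scale: IntervalScale) -> ProbVector:
    values = pd.read_csv(_path(name))["prob"].to_numpy(dtype=float)
    return ProbVector(scale, values, atol=PRINTED_ATOL)


def _matrix(name: str, from_scale: IntervalScale, to_scale: IntervalScale) -> TransitionMatrix:
    values = pd.read_csv(_path(name), header=None).to_numpy(dtype=float)
    return TransitionMatrix(from_scale, to_scale, values, atol=PRINTED_ATOL)


def printed_u_1997() -> ProbVector:
    """Cohort response distribution at 1997 on the 4-option scale."""
    return _vector("u_1997.csv", q1997_scale())


def printed_v_prime_1997() -> ProbVector:
    """Cohort response distribution at 1998 on the 5-option scale."""
    return _vector("v_prime_1997.csv", q1998_scale())


def printed_y_1997() -> ProbVector:
    """Population response distribution at 1997 on the 4-option scale."""
    return _vector("y_1997.csv", q1997_scale())


def printed_z_1997() -> ProbVector:
    """Aligned population distribution for 1997 on the 5-option scale."""
    return _vector("z_1997.csv", q1998_scale())


def printed_v_1997() -> ProbVector:
    """Aligned cohort distribution for 1997 on the 5-option scale."""
    return _vector("v_1997.csv", q1998_scale())


def printed_T_1997() -> TransitionMatrix:
    """Cohort transition matrix spanning the 1997->1998 revision (5 x 4)."""
    return _matrix("T_1997.csv", q1997_scale(), q1998_scale())


def printed_B_1998() -> TransitionMatrix:
    """Revision-free 1998->1999 cohort transition matrix (5 x 5)."""
    return _matrix("B_1998.csv", q1998_scale(), q1998_scale())


def printed_A_hat_1997() -> TransitionMatrix:
    """Published estimated revision factor (5 x 4)."""
    return _matrix("A_hat_1997.csv", q1997_scale(), q1998_scale())


def printed_G() -> TransitionMatrix:
    """Published ideal revision matrix (5 x 4); see the module note's caveat."""
    return _matrix("G_printed.csv", q1997_scale(), q1998_scale())


def annual_means() -> pd.DataFrame:
    """Published annual population sizes and mean estimates, 1997-2008.

    Columns: year, population, mean_midpoint, mean_mle, linf_vs_prev (the
    response-distribution distance from the preceding year, where defined).
    """
    return pd.read_csv(_path("table1_annual.csv"))
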