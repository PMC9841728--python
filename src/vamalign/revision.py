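"""The ideal revision matrix between two questionnaire versions.

Under the ideal survey response model a respondent's latent answer ``x`` does
not change when the questionnaire is revised — only the option grid does.  The
ideal revision matrix ``G`` therefore has entries

    G[i, j] = P(x in I2_i | x in I1_j) = Phi(I2_i ∩ I1_j) / Phi(I1_j)

where ``Phi`` is the probability mass of the fitted latent distribution on an
interval.  ``G`` is column-stochastic by construction, has exact zeros for
empty intersections, and a unit column whenever a source interval nests inside
a single target interval.  It serves as the reference for the revision factor
in the alignment solver.
"""

from __future__ import annotations

import numpy as np

from .containers import TransitionMatrix
from .distributions import DistributionSpec, interval_probability
from .scales import IntervalScale, InvalidScaleError

__all__ = ["ideal_revision_matrix", "ZeroMassColumnError", "interval_probability"]


class ZeroMassColumnError(ValueError):
    """A source interval carries no probability mass, so its column is undefined."""


def ideal_revision_matrix(
    dist: DistributionSpec,
    scale_from: IntervalScale,
    scale_to: IntervalScale,
) -> TransitionMatrix:
    """Conditional interval-to-interval probabilities under ``dist``.

    Both scales must be contiguous on ``[0, inf)`` (pass raw gapped scales
    through ``smooth_gaps`` first — the nearest-option response assumption).
    Computed exactly from the CDF.
    """
    for scale in (scale_from, scale_to):
        if not scale.is_contiguous:
            raise InvalidScaleError(
                f"scale {scale.version_id!r} must be contiguous; call smooth_gaps()"
            )
    entries = np.zeros((scale_to.d, scale_from.d))
    for j, src in enumerate(scale_from.intervals):
        mass = interval_probability(dist, src)
        if mass <= 0:
            raise ZeroMassColumnError(
                f"source interval [{src.lb}, {src.ub}) has zero probability mass"
            )
        for i, tgt in enumerate(scale_to.intervals):
            inter = src.intersect(tgt)
            if inter is not None:
                entries[i, j] = interval_probability(dist, inter) / mass
    # conditional masses over a partition of the source interval sum to 1
    entries /= entries.sum(axis=0)
    return TransitionMatrix(scale_from, scale_to, entries, atol=1e-12)
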