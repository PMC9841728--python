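import math

import numpy as np
import pytest

from vamalign import (
    DistributionSpec,
    Interval,
    IntervalScale,
    ProbVector,
    q1997_scale,
    q1998_scale,
    q1998_scale_raw,
)


@pytest.fixture
def q97():
    return q1997_scale()


@pytest.fixture
def q98():
    return q1998_scale()


@pytest.fixture
def q98_raw():
    return q1998_scale_raw()


@pytest.fixture
def exp3():
    """Gamma(1, 3) = exponential with mean 3, the simulation's latent law."""
    return DistributionSpec.gamma(1.0, 3.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


def random_probvector(rng, scale):
    p = rng.dirichlet(np.ones(scale.d))
    return ProbVector(scale, p, atol=1e-9)


def random_stochastic(rng, from_scale, to_scale):
    cols = rng.dirichlet(np.ones(to_scale.d), size=from_scale.d).T
    return cols
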