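"""Synthetic grouped-survey data spanning a questionnaire revision.

The generator reproduces the ideal survey response model: a latent weekly
duration drawn from a Gamma distribution, binned by two questionnaire
versions (the 4-option 1997 scale and the 5-option 1998 scale), a cohort
resampled from the population, and a random time-related transition matrix
that evolves the cohort's responses to the next observation time.  The
observable set handed to the alignment method (population vector, cohort
pairs, cohort transition matrix, reference time matrix, reference distance)
mirrors what a real revision-spanning panel provides, while the full latent
truth is retained for error measurement.

Default condition: Gamma(shape 1, scale 3) latent durations (mean 3 h/week),
57 000 population draws, a 20 000-strong cohort, and time matrices generated
around a revision-free reference matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .containers import (
    CountVector,
    PairedResponses,
    ProbVector,
    TransitionMatrix,
    estimate_transition_matrix,
    linf_matrix,
)
from .distributions import DistributionSpec
from .scales import IntervalScale, q1997_scale, q1998_scale

__all__ = [
    "SimConfig",
    "SimulationScenario",
    "draw_population",
    "assign_responses",
    "select_cohort",
    "generate_time_matrix",
    "evolve_responses",
    "perturbed_references",
    "build_scenario",
]


def draw_population(dist: DistributionSpec, n: int, seed: int | np.random.Generator) -> np.ndarray:
    """``n`` independent latent values from ``dist``; reproducible under ``seed``."""
    if n <= 0:
        raise ValueError("population size must be positive")
    rng = np.random.default_rng(seed)
    return dist.rvs(n, rng)


def assign_responses(samples: np.ndarray, scale: IntervalScale) -> np.ndarray:
    """Map each latent value to its 1-based option index on a contiguous scale.

    Boundaries follow the half-open rule: a value equal to a shared bound
    belongs to the upper option.
    """
    edges = np.array(scale.edges())
    samples = np.asarray(samples, dtype=float)
    if np.any(samples < edges[0]):
        raise ValueError("sample outside the scale's support")
    # right-open bins: searchsorted(side='right') puts x == edge in the upper bin
    return np.searchsorted(edges[1:-1], samples, side="right") + 1


def select_cohort(
    n_population: int, n_cohort: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Uniform random subset of individuals observed at both times."""
    if n_cohort > n_population:
        raise ValueError("cohort cannot exceed the population")
    rng = np.random.default_rng(seed)
    return rng.choice(n_population, size=n_cohort, replace=False)


def generate_time_matrix(
    references: Sequence[TransitionMatrix], seed: int | np.random.Generator
) -> TransitionMatrix:
    """Draw a random time-related transition matrix around reference matrices.

    Each diagonal entry is drawn uniformly between the minimum and maximum of
    that position across the references (per-position bounds).  Off-diagonal
    entries are a weighted average of the references' off-diagonals with
    U(0,1) weights normalized to sum 1, then rescaled per column so the
    off-diagonals sum to ``1 - diagonal``.  The result is column-stochastic by
    construction; a single reference is returned unchanged.
    """
    if not references:
        raise ValueError("need at least one reference matrix")
    shapes = {r.shape for r in references}
    if len(shapes) > 1:
        raise ValueError(f"reference matrices disagree in shape: {shapes}")
    (n, m), = shapes
    if n != m:
        raise ValueError("time matrices must be square")
    rng = np.random.default_rng(seed)
    stack = np.stack([r.entries for r in references])
    diag_lo = stack.diagonal(axis1=1, axis2=2).min(axis=0)
    diag_hi = stack.diagonal(axis1=1, axis2=2).max(axis=0)
    diag = rng.uniform(diag_lo, diag_hi)
    weights = rng.uniform(0.0, 1.0, size=len(references))
    weights /= weights.sum()
    off = np.tensordot(weights, stack, axes=1)
    np.fill_diagonal(off, 0.0)
    col_off = off.sum(axis=0)
    col_off[col_off == 0] = 1.0  # a fully diagonal column keeps its zeros
    out = off * ((1.0 - diag) / col_off)
    np.fill_diagonal(out, diag)
    ref = references[0]
    return TransitionMatrix(ref.from_scale, ref.to_scale, out, atol=1e-9)


def evolve_responses(
    responses: np.ndarray,
    B: TransitionMatrix,
    seed: int | np.random.Generator,
    mode: Literal["individual", "expected-counts"] = "individual",
) -> np.ndarray:
    """Advance per-individual options one time step through ``B``.

    ``individual`` draws each person's next option from the column of ``B``
    indexed by their current option, preserving the individual-level pairing
    needed to estimate a transition matrix.  ``expected-counts`` assigns next
    options deterministically in proportion to the column probabilities
    (largest-remainder apportionment within each current-option group), which
    reproduces the noiseless vector statement ``v' = B @ v`` up to rounding.
    """
    responses = np.asarray(responses, dtype=int)
    d = B.from_scale.d
    if responses.min() < 1 or responses.max() > d:
        raise ValueError("response index outside the matrix's source dimension")
    rng = np.random.default_rng(seed)
    out = np.empty_like(responses)
    for j in range(1, d + 1):
        idx = np.flatnonzero(responses == j)
        if idx.size == 0:
            continue
        col = B.entries[:, j - 1]
        if mode == "individual":
            out[idx] = rng.choice(np.arange(1, B.to_scale.d + 1), size=idx.size, p=col / col.sum())
        elif mode == "expected-counts":
            expected = col / col.sum() * idx.size
            counts = np.floor(expected).astype(int)
            remainder = idx.size - counts.sum()
            if remainder > 0:
                frac_order = np.argsort(-(expected - counts))
                counts[frac_order[:remainder]] += 1
            out[idx] = np.repeat(np.arange(1, B.to_scale.d + 1), counts)
        else:
            raise ValueError(f"unknown evolution mode {mode!r}")
    return out


def perturbed_references(
    base: TransitionMatrix,
    n_extra: int,
    seed: int | np.random.Generator,
    magnitude: float = 0.03,
) -> list[TransitionMatrix]:
    """A reference set: ``base`` plus ``n_extra`` perturbed column-stochastic copies.

    Additive uniform noise of half-width ``magnitude`` per entry, clipped at
    zero and column-renormalized; the default magnitude yields pairwise
    matrix distances of a few hundredths, comparable to observed year-to-year
    variation between revision-free cohort transition matrices.
    """
    rng = np.random.default_rng(seed)
    refs = [base]
    for _ in range(n_extra):
        noisy = base.entries + rng.uniform(-magnitude, magnitude, size=base.shape)
        noisy = np.clip(noisy, 1e-9, None)
        refs.append(
            TransitionMatrix(base.from_scale, base.to_scale, noisy / noisy.sum(axis=0), atol=1e-9)
        )
    return refs


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic revision-spanning panel."""

    dist: DistributionSpec = field(default_factory=lambda: DistributionSpec.gamma(1.0, 3.0))
    n_population: int = 57000
    n_cohort: int = 20000
    scale_from: IntervalScale = field(default_factory=q1997_scale)
    scale_to: IntervalScale = field(default_factory=q1998_scale)
    reference_matrices: tuple[TransitionMatrix, ...] | None = None
    n_time_matrices: int = 3
    evolution_mode: Literal["individual", "expected-counts"] = "individual"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cohort > self.n_population:
            raise ValueError("cohort cannot exceed the population")
        if self.n_time_matrices < 2:
            raise ValueError("need at least B1 and B2")


@dataclass(frozen=True)
class SimulationScenario:
    """Observables handed to the alignment method, plus retained ground truth."""

    config: SimConfig
    # observables
    y1: ProbVector  # population responses on the source scale at t1
    cohort_pairs: PairedResponses  # U1 -> V'1 spanning the revision
    T1: TransitionMatrix  # estimated cohort transition matrix
    B_ref: TransitionMatrix  # = B2, revision-free reference
    beta_reference: float  # average pairwise distance among generated matrices
    # ground truth
    latent: np.ndarray = field(repr=False)
    cohort_index: np.ndarray = field(repr=False)
    z1_true: ProbVector = field(repr=False)  # population binned by the target scale at t1
    v1_true: ProbVector = field(repr=False)  # cohort binned by the target scale at t1
    B1_true: TransitionMatrix = field(repr=False)
    time_matrices: tuple[TransitionMatrix, ...] = field(repr=False)

    @property
    def population_mean(self) -> float:
        return float(self.latent.mean())

    @property
    def cohort_mean(self) -> float:
        return float(self.latent[self.cohort_index].mean())


def _probvector(options: np.ndarray, scale: IntervalScale) -> ProbVector:
    counts = np.bincount(options, minlength=scale.d + 1)[1:]
    return CountVector(scale, counts).to_probvector()


def build_scenario(config: SimConfig | None = None) -> SimulationScenario:
    """One full generative pass; byte-identical under a fixed config seed.

    Population draws -> source-scale and target-scale binnings at t1 ->
    cohort selection -> random time matrices -> per-individual cohort
    evolution to t2 -> cohort transition-matrix estimation.
    """
    config = config or SimConfig()
    root = np.random.default_rng(config.seed)
    seeds = root.spawn(4)
    scale_from = config.scale_from.smooth_gaps()
    scale_to = config.scale_to.smooth_gaps()

    latent = draw_population(config.dist, config.n_population, seeds[0])
    y_options = assign_responses(latent, scale_from)
    z_options = assign_responses(latent, scale_to)

    cohort_index = select_cohort(config.n_population, config.n_cohort, seeds[1])
    u_options = y_options[cohort_index]
    v_options = z_options[cohort_index]

    references = config.reference_matrices
    if references is None:
        from .datasets import printed_B_1998

        references = tuple(perturbed_references(printed_B_1998().normalized(), 2, seeds[2]))
    time_matrices = tuple(
        generate_time_matrix(references, child)
        for child in np.random.default_rng(seeds[2]).spawn(config.n_time_matrices)
    )
    B1, B2 = time_matrices[0], time_matrices[1]
    pairs_dist = [
        linf_matrix(a, b)
        for i, a in enumerate(time_matrices)
        for b in time_matrices[i + 1 :]
    ]
    beta_reference = float(np.mean(pairs_dist))

    vprime_options = evolve_responses(v_options, B1, seeds[3], mode=config.evolution_mode)
    cohort_pairs = PairedResponses(
        scale1=scale_from,
        scale2=scale_to,
        ids=cohort_index,
        options_t1=u_options,
        options_t2=vprime_options,
        t1="t1",
        t2="t2",
    )
    T1 = estimate_transition_matrix(cohort_pairs)

    return SimulationScenario(
        config=config,
        y1=_probvector(y_options, scale_from),
        cohort_pairs=cohort_pairs,
        T1=T1,
        B_ref=B2,
        beta_reference=beta_reference,
        latent=latent,
        cohort_index=cohort_index,
        z1_true=_probvector(z_options, scale_to),
        v1_true=_probvector(v_options, scale_to),
        B1_true=B1,
        time_matrices=time_matrices,
    )
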