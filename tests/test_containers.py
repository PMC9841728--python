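"""Probability vectors, transition matrices, distances, cohort counting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vamalign import (
    KL_UNDEFINED,
    CountVector,
    EmptySampleError,
    IncompatibleScalesError,
    IntervalScale,
    PairedResponses,
    ProbVector,
    TransitionMatrix,
    apply_transition,
    estimate_transition_matrix,
    kl_divergence,
    linf,
    linf_matrix,
    q1997_scale,
    q1998_scale,
)
from vamalign import datasets as ds

from conftest import random_probvector


def _scale(d):
    edges = list(range(d)) + [math.inf]
    return IntervalScale(f"d{d}", tuple((edges[i], edges[i + 1]) for i in range(d)))


S3 = _scale(3)
S2 = _scale(2)


def pv(*probs, scale=None):
    return ProbVector(scale or _scale(len(probs)), np.array(probs), atol=1e-9)


class TestProbVector:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ([10, 30, 60], [0.1, 0.3, 0.6]),
            ([1, 0, 0], [1, 0, 0]),
            ([2, 1, 1], [0.5, 0.25, 0.25]),
        ],
    )
    def test_relative_frequencies(self, counts, expected):
        p = CountVector(S3, np.array(counts)).to_probvector()
        np.testing.assert_allclose(p.probs, expected)

    def test_empty_sample_rejected(self):
        with pytest.raises(EmptySampleError):
            CountVector(S3, np.zeros(3)).to_probvector()

    def test_normalization_tolerance(self):
        with pytest.raises(ValueError):
            ProbVector(S3, np.array([0.5, 0.3, 0.1]))  # sums to 0.9
        loose = ProbVector(S3, np.array([0.5, 0.3, 0.199]), atol=1e-2)
        np.testing.assert_allclose(loose.normalized().probs.sum(), 1.0, atol=1e-15)


class TestLinf:
    @pytest.mark.parametrize(
        "p, q, expected",
        [
            ([0.2, 0.3, 0.5], [0.2, 0.3, 0.5], 0.0),
            ([1, 0], [0, 1], 1.0),
            ([0.5, 0.3, 0.2], [0.4, 0.4, 0.2], 0.1),
        ],
    )
    def test_examples(self, p, q, expected):
        assert linf(pv(*p), pv(*q)) == pytest.approx(expected)

    def test_dimension_mismatch(self):
        with pytest.raises(IncompatibleScalesError):
            linf(pv(0.5, 0.5), pv(0.2, 0.3, 0.5))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_metric_properties(self, seed):
        rng = np.random.default_rng(seed)
        p, q, r = (random_probvector(rng, S3) for _ in range(3))
        assert linf(p, q) == pytest.approx(linf(q, p))
        assert linf(p, p) == 0.0
        assert linf(p, r) <= linf(p, q) + linf(q, r) + 1e-12
        assert 0.0 <= linf(p, q) <= 1.0


class TestLinfMatrix:
    def test_identity_and_example(self):
        eye = TransitionMatrix(S2, S2, np.eye(2))
        other = TransitionMatrix(S2, S2, np.array([[0.9, 0.2], [0.1, 0.8]]))
        assert linf_matrix(eye, eye) == 0.0
        assert linf_matrix(eye, other) == pytest.approx(0.2)

    def test_matches_bruteforce_over_entries(self, rng):
        from conftest import random_stochastic

        for _ in range(20):
            m = TransitionMatrix(S3, S2, random_stochastic(rng, S3, S2), atol=1e-9)
            n = TransitionMatrix(S3, S2, random_stochastic(rng, S3, S2), atol=1e-9)
            brute = max(
                abs(m.entries[i, j] - n.entries[i, j])
                for i in range(2)
                for j in range(3)
            )
            assert linf_matrix(m, n) == pytest.approx(brute)

    def test_column_swap(self, rng):
        from conftest import random_stochastic

        e = random_stochastic(rng, S3, S3)
        m = TransitionMatrix(S3, S3, e, atol=1e-9)
        swapped = e.copy()
        swapped[:, [0, 1]] = swapped[:, [1, 0]]
        n = TransitionMatrix(S3, S3, swapped, atol=1e-9)
        expected = max(
            np.max(np.abs(e[:, 0] - swapped[:, 0])), np.max(np.abs(e[:, 1] - swapped[:, 1]))
        )
        assert linf_matrix(m, n) == pytest.approx(expected)

    def test_dimension_mismatch(self):
        with pytest.raises(IncompatibleScalesError):
            linf_matrix(
                TransitionMatrix(S2, S2, np.eye(2)), TransitionMatrix(S3, S3, np.eye(3))
            )


class TestKL:
    def test_identity_is_zero(self):
        p = pv(0.5, 0.3, 0.2)
        assert kl_divergence(p, p) == pytest.approx(0.0)

    def test_zero_reference_cell_gives_sentinel(self):
        assert kl_divergence(pv(0.5, 0.5), pv(1.0, 0.0)) is KL_UNDEFINED

    def test_zero_in_p_contributes_nothing(self):
        assert kl_divergence(pv(1.0, 0.0), pv(0.5, 0.5)) == pytest.approx(math.log(2))

    def test_closed_form(self):
        expected = 0.5 * math.log(2) + 0.5 * math.log(2 / 3)
        assert kl_divergence(pv(0.5, 0.5), pv(0.25, 0.75)) == pytest.approx(expected)
        assert expected == pytest.approx(0.14384, abs=1e-5)


class TestEstimateTransitionMatrix:
    def make_pairs(self, o1, o2, s1=S2, s2=S2):
        return PairedResponses(
            scale1=s1,
            scale2=s2,
            ids=np.arange(len(o1)),
            options_t1=np.array(o1),
            options_t2=np.array(o2),
        )

    def test_identity_when_everyone_stays(self):
        pairs = self.make_pairs([1, 2, 1, 2], [1, 2, 1, 2])
        t = estimate_transition_matrix(pairs)
        np.testing.assert_allclose(t.entries, np.eye(2))

    def test_direct_counting(self):
        pairs = self.make_pairs([1, 1, 2], [1, 2, 2])
        t = estimate_transition_matrix(pairs)
        np.testing.assert_allclose(t.entries, [[0.5, 0.0], [0.5, 1.0]])

    def test_columns_sum_exactly_to_one(self, rng):
        o1 = rng.integers(1, 3, size=200)
        o2 = rng.integers(1, 3, size=200)
        t = estimate_transition_matrix(self.make_pairs(o1, o2))
        np.testing.assert_array_equal(t.entries.sum(axis=0), np.ones(2))

    def test_recovers_known_matrix_from_sampled_cohort(self, rng):
        # binomial sampling error at n=20000 keeps every entry within 0.03
        b = np.array([[0.7, 0.2, 0.1], [0.2, 0.5, 0.3], [0.1, 0.3, 0.6]])
        o1 = rng.integers(1, 4, size=20000)
        o2 = np.array([rng.choice([1, 2, 3], p=b[:, j - 1]) for j in o1])
        t = estimate_transition_matrix(self.make_pairs(o1, o2, S3, S3))
        assert np.max(np.abs(t.entries - b)) <= 0.03

    def test_empty_source_column_policies(self):
        pairs = self.make_pairs([1, 1], [1, 2])  # option 2 never chosen at t1
        with pytest.raises(EmptySampleError):
            estimate_transition_matrix(pairs)
        uniform = estimate_transition_matrix(pairs, empty_column="uniform")
        np.testing.assert_allclose(uniform.entries[:, 1], [0.5, 0.5])
        ident = estimate_transition_matrix(pairs, empty_column="identity")
        np.testing.assert_allclose(ident.entries[:, 1], [0.0, 1.0])


class TestApplyTransition:
    def test_identity(self):
        p = pv(0.4, 0.6)
        eye = TransitionMatrix(S2, S2, np.eye(2))
        np.testing.assert_allclose(apply_transition(eye, p).probs, p.probs)

    def test_arithmetic(self):
        t = TransitionMatrix(S2, S2, np.array([[0.5, 0.0], [0.5, 1.0]]))
        out = apply_transition(t, pv(0.4, 0.6))
        np.testing.assert_allclose(out.probs, [0.2, 0.8])

    def test_published_revision_product_first_entry(self):
        # column-renormalized published revision factor applied to the
        # published cohort vector reproduces the published aligned vector
        a = ds.printed_A_hat_1997().normalized()
        u = ds.printed_u_1997()
        out = apply_transition(a, u)
        assert out.probs[0] == pytest.approx(0.469, abs=5e-4)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_conserves_total_probability(self, seed):
        from conftest import random_stochastic

        rng = np.random.default_rng(seed)
        t = TransitionMatrix(S3, S2, random_stochastic(rng, S3, S2), atol=1e-12)
        p = random_probvector(rng, S3)
        out = apply_transition(t, p)
        assert abs(out.probs.sum() - 1.0) <= 1e-10

    def test_dimension_mismatch(self):
        t = TransitionMatrix(S3, S2, np.full((2, 3), 1 / 2))
        with pytest.raises(IncompatibleScalesError):
            apply_transition(t, pv(0.5, 0.5))
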