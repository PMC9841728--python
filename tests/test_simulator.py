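"""Synthetic revision-spanning panels: generative steps and invariants."""

import math

import numpy as np
import pytest

from vamalign import (
    DistributionSpec,
    SimConfig,
    TransitionMatrix,
    assign_responses,
    build_scenario,
    draw_population,
    estimate_transition_matrix,
    evolve_responses,
    generate_time_matrix,
    linf_matrix,
    midpoint_mean,
    select_cohort,
    q1998_scale,
)
from vamalign.simulate import perturbed_references

from conftest import random_stochastic


class TestDrawPopulation:
    def test_sample_mean_near_truth(self, exp3):
        x = draw_population(exp3, 57000, seed=3)
        assert abs(x.mean() - 3.0) <= 3 * 3.0 / math.sqrt(57000)

    def test_deterministic_under_seed(self, exp3):
        np.testing.assert_array_equal(
            draw_population(exp3, 100, seed=7), draw_population(exp3, 100, seed=7)
        )

    def test_single_draw_in_support(self, exp3):
        assert draw_population(exp3, 1, seed=0)[0] >= 0


class TestAssignResponses:
    def test_half_open_boundaries(self, q98):
        np.testing.assert_array_equal(
            assign_responses(np.array([0.0, 2.5, 1.0, 100.0]), q98), [1, 3, 2, 5]
        )

    def test_outside_support_rejected(self):
        from vamalign import IntervalScale

        finite = IntervalScale("fin", ((0, 1), (1, 2)))
        with pytest.raises(ValueError):
            assign_responses(np.array([-0.5]), finite)

    def test_frequencies_match_cell_probabilities(self, exp3, q97, rng):
        x = rng.gamma(1.0, 3.0, size=1_000_000)
        opts = assign_responses(x, q97)
        freq = np.bincount(opts, minlength=5)[1:] / len(x)
        expected = [0.28347, 0.20312, 0.14553, 0.36788]
        np.testing.assert_allclose(freq, expected, atol=0.002)


class TestSelectCohort:
    def test_size_and_uniqueness(self):
        idx = select_cohort(1000, 400, seed=0)
        assert len(idx) == 400 and len(set(idx)) == 400

    def test_full_subset(self):
        assert sorted(select_cohort(50, 50, seed=1)) == list(range(50))

    def test_oversized_cohort_rejected(self):
        with pytest.raises(ValueError):
            select_cohort(10, 11, seed=0)

    def test_overlap_matches_hypergeometric_expectation(self):
        n, k = 2000, 800
        a = set(select_cohort(n, k, seed=1))
        b = set(select_cohort(n, k, seed=2))
        expected = k * k / n  # E|A ∩ B| for two independent uniform subsets
        sd = math.sqrt(k * (k / n) * (1 - k / n))  # binomial approximation
        assert abs(len(a & b) - expected) <= 4 * sd


class TestGenerateTimeMatrix:
    def test_single_reference_returned_exactly(self, q98, rng):
        ref = TransitionMatrix(q98, q98, random_stochastic(rng, q98, q98), atol=1e-9)
        out = generate_time_matrix([ref], seed=5)
        np.testing.assert_allclose(out.entries, ref.entries, atol=1e-12)

    def test_column_stochastic_for_any_seed(self, q98, rng):
        refs = [
            TransitionMatrix(q98, q98, random_stochastic(rng, q98, q98), atol=1e-9)
            for _ in range(3)
        ]
        for seed in range(30):
            out = generate_time_matrix(refs, seed=seed)
            np.testing.assert_allclose(out.entries.sum(axis=0), 1.0, atol=1e-12)
            assert np.all(out.entries >= 0)

    def test_diagonal_within_reference_bounds(self, q98, rng):
        refs = [
            TransitionMatrix(q98, q98, random_stochastic(rng, q98, q98), atol=1e-9)
            for _ in range(2)
        ]
        stack = np.stack([r.entries for r in refs])
        lo = stack.diagonal(axis1=1, axis2=2).min(axis=0)
        hi = stack.diagonal(axis1=1, axis2=2).max(axis=0)
        for seed in range(200):
            d = np.diag(generate_time_matrix(refs, seed=seed).entries)
            assert np.all(d >= lo - 1e-12) and np.all(d <= hi + 1e-12)


class TestEvolveResponses:
    def test_identity_matrix_keeps_responses(self, q98):
        eye = TransitionMatrix(q98, q98, np.eye(5))
        resp = np.array([1, 2, 3, 4, 5, 3, 2])
        np.testing.assert_array_equal(evolve_responses(resp, eye, seed=0), resp)

    def test_empirical_transitions_recover_matrix(self, q98, rng):
        b = TransitionMatrix(q98, q98, random_stochastic(rng, q98, q98), atol=1e-9)
        resp = rng.integers(1, 6, size=20000)
        evolved = evolve_responses(resp, b, seed=9)
        from vamalign import PairedResponses

        pairs = PairedResponses(
            scale1=q98, scale2=q98, ids=np.arange(len(resp)),
            options_t1=resp, options_t2=evolved,
        )
        t = estimate_transition_matrix(pairs)
        assert linf_matrix(t, b) <= 0.03

    def test_expected_counts_mode_matches_vector_product(self, q98, rng):
        b = TransitionMatrix(q98, q98, random_stochastic(rng, q98, q98), atol=1e-9)
        resp = rng.integers(1, 6, size=10000)
        evolved = evolve_responses(resp, b, seed=0, mode="expected-counts")
        freq_in = np.bincount(resp, minlength=6)[1:] / len(resp)
        freq_out = np.bincount(evolved, minlength=6)[1:] / len(resp)
        np.testing.assert_allclose(freq_out, b.entries @ freq_in, atol=5e-4)


class TestBuildScenario:
    def test_reproducible_under_seed(self):
        cfg = SimConfig(n_population=5000, n_cohort=2000, seed=11)
        a, b = build_scenario(cfg), build_scenario(cfg)
        np.testing.assert_array_equal(a.latent, b.latent)
        np.testing.assert_array_equal(a.cohort_pairs.options_t2, b.cohort_pairs.options_t2)
        np.testing.assert_array_equal(a.T1.entries, b.T1.entries)
        np.testing.assert_array_equal(a.B_ref.entries, b.B_ref.entries)

    def test_latent_consistent_with_binnings(self):
        sc = build_scenario(SimConfig(n_population=3000, n_cohort=1000, seed=2))
        scale_to = sc.config.scale_to.smooth_gaps()
        v1 = assign_responses(sc.latent[sc.cohort_index], scale_to)
        # each individual's target-scale interval contains their latent value
        for opt, x in zip(v1[:200], sc.latent[sc.cohort_index][:200]):
            iv = scale_to.intervals[opt - 1]
            assert iv.lb <= x < iv.ub

    def test_true_revision_transitions_have_unit_columns_for_nested_intervals(self):
        sc = build_scenario(SimConfig(n_population=20000, n_cohort=8000, seed=4))
        from vamalign import PairedResponses

        u1 = sc.cohort_pairs.options_t1
        v1 = assign_responses(sc.latent[sc.cohort_index], sc.config.scale_to.smooth_gaps())
        pairs = PairedResponses(
            scale1=sc.config.scale_from, scale2=sc.config.scale_to,
            ids=sc.cohort_index, options_t1=u1, options_t2=v1,
        )
        a_true = estimate_transition_matrix(pairs)
        # source options [0,1) and [1,2) nest inside target options 1 and 2
        np.testing.assert_allclose(a_true.entries[:, 0], [1, 0, 0, 0, 0], atol=0)
        np.testing.assert_allclose(a_true.entries[:, 1], [0, 1, 0, 0, 0], atol=0)

    def test_midpoint_estimate_matches_analytic_expectation(self):
        # E[midpoint estimate] = 1.91385 under the default latent law and source scale
        sc = build_scenario(SimConfig(seed=8))
        est = midpoint_mean(sc.y1).mean
        assert abs(est - 1.91385) <= 3 * 0.0044

    def test_beta_reference_is_average_pairwise_distance(self):
        sc = build_scenario(SimConfig(n_population=2000, n_cohort=500, seed=3))
        ms = sc.time_matrices
        dists = [
            linf_matrix(a, b) for i, a in enumerate(ms) for b in ms[i + 1 :]
        ]
        assert sc.beta_reference == pytest.approx(float(np.mean(dists)))


class TestPerturbedReferences:
    def test_stochastic_and_near_base(self, q98, rng):
        base = TransitionMatrix(q98, q98, random_stochastic(rng, q98, q98), atol=1e-9)
        refs = perturbed_references(base, 3, seed=2)
        assert len(refs) == 4
        for r in refs[1:]:
            np.testing.assert_allclose(r.entries.sum(axis=0), 1.0, atol=1e-12)
            assert 0 < linf_matrix(r, base) < 0.1
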