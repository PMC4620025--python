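"""Unit and property tests for the topographic sparse coding core."""

import math

import numpy as np
import pytest

from topocode.synthetic import SynthTscConfig, generate_tsc_instance
from topocode.tsc import (
    TscConfig,
    build_grouping_matrix,
    encode,
    grad_codes,
    grad_dictionary,
    init_codes,
    learn,
    match_atoms,
    objective,
    project_codes,
    smoothed_group_penalty,
)

from conftest import brute_force_penalty, finite_difference_grad


class TestGroupingMatrix:
    def test_wraparound_square_grid_has_one_group_per_atom(self):
        V = build_grouping_matrix(4, 4, 3, wraparound=True)
        assert V.values.shape == (16, 16)
        # every group holds 9 atoms; every atom belongs to 9 groups
        assert np.all(V.values.sum(axis=1) == 9)
        assert np.all(V.values.sum(axis=0) == 9)

    def test_group_size_three_covers_a_contiguous_window(self):
        # the group anchored at row 0, column 1 of a 3x4 grid spans the
        # 3x3 block of columns 1..3 across all rows
        V = build_grouping_matrix(3, 4, 3, wraparound=False)
        members = np.flatnonzero(V.values[1])
        expected = [r * 4 + c for r in range(3) for c in (1, 2, 3)]
        assert sorted(members) == expected

    def test_singleton_groups_give_identity(self):
        V = build_grouping_matrix(3, 3, 1, wraparound=True)
        assert np.array_equal(V.values, np.eye(9))

    def test_no_wraparound_counts_fitting_windows_only(self):
        V = build_grouping_matrix(4, 5, 3, wraparound=False)
        assert V.values.shape == ((4 - 2) * (5 - 2), 20)

    def test_oversized_group_rejected(self):
        with pytest.raises(ValueError):
            build_grouping_matrix(2, 2, 3, wraparound=True)


class TestPenalty:
    def test_zero_codes_closed_form(self, grouping_3x3):
        s = np.zeros((9, 5))
        eps = 0.04
        assert smoothed_group_penalty(s, grouping_3x3, eps) == pytest.approx(
            9 * 5 * math.sqrt(eps), abs=1e-14
        )

    def test_identity_grouping_zero_eps_is_l1(self, rng):
        s = rng.standard_normal((7, 6))
        V = np.eye(7)
        assert smoothed_group_penalty(s, V, 0.0) == pytest.approx(
            np.sum(np.abs(s)), rel=1e-14
        )

    @pytest.mark.parametrize("shape,grid", [((9, 4), (3, 3)), ((16, 7), (4, 4))])
    def test_matches_brute_force_triple_loop(self, rng, shape, grid):
        s = rng.standard_normal(shape)
        V = build_grouping_matrix(grid[0], grid[1], 3, wraparound=True)
        got = smoothed_group_penalty(s, V, 0.01)
        want = brute_force_penalty(s, V.values, 0.01)
        assert got == pytest.approx(want, abs=1e-12 * max(1.0, abs(want)))

    def test_smoothing_limit_singleton_groups(self, rng):
        # |penalty(eps) - ||s||_1| <= k*N*sqrt(eps) since sqrt(t^2+e)-|t| <= sqrt(e)
        k, N, eps = 11, 9, 1e-4
        s = 10.0 * rng.standard_normal((k, N))
        V = np.eye(k)
        gap = abs(smoothed_group_penalty(s, V, eps) - np.sum(np.abs(s)))
        assert gap <= k * N * math.sqrt(eps)

    def test_dimension_mismatch_rejected(self, grouping_3x3):
        with pytest.raises(ValueError):
            smoothed_group_penalty(np.zeros((8, 2)), grouping_3x3, 0.01)


class TestObjective:
    def test_zero_data_closed_form(self, rng, grouping_3x3):
        cfg = TscConfig(k=9, group_size=3)
        A = rng.standard_normal((6, 9))
        s = np.zeros((9, 4))
        x = np.zeros((6, 4))
        terms = objective(A, s, x, grouping_3x3, cfg)
        want = cfg.lambda_ * 9 * 4 * math.sqrt(cfg.epsilon) + cfg.gamma * np.sum(A * A)
        assert terms.J == pytest.approx(want, rel=1e-12)

    def test_perfect_reconstruction_zero_weights(self, rng, grouping_3x3):
        cfg = TscConfig(k=9, group_size=3, lambda_=0.0, gamma=0.0)
        A = rng.standard_normal((6, 9))
        s = rng.standard_normal((9, 4))
        x = A @ s
        assert objective(A, s, x, grouping_3x3, cfg).J == pytest.approx(0.0, abs=1e-18)

    def test_terms_sum_to_J(self, rng, grouping_3x3):
        cfg = TscConfig(k=9, group_size=3)
        A = rng.standard_normal((6, 9))
        s = rng.standard_normal((9, 4))
        x = rng.standard_normal((6, 4))
        t = objective(A, s, x, grouping_3x3, cfg)
        assert t.J == pytest.approx(
            t.sse + cfg.lambda_ * t.penalty + cfg.gamma * t.decay, rel=1e-12
        )
        np.testing.assert_allclose(t.recon.reconstruction + t.recon.residual, x)

    def test_shape_mismatch_rejected(self, rng, grouping_3x3):
        cfg = TscConfig(k=9, group_size=3)
        with pytest.raises(ValueError):
            objective(
                rng.standard_normal((6, 8)),
                rng.standard_normal((9, 4)),
                rng.standard_normal((6, 4)),
                grouping_3x3,
                cfg,
            )


class TestGradients:
    @pytest.mark.parametrize("lam", [0.0, 0.1, 1.0])
    @pytest.mark.parametrize("eps", [1e-4, 1e-2])
    def test_grad_codes_matches_finite_differences(self, rng, grouping_3x3, lam, eps):
        cfg = TscConfig(k=9, group_size=3, lambda_=lam, epsilon=eps)
        A = rng.standard_normal((6, 9))
        s = rng.standard_normal((9, 4))
        x = rng.standard_normal((6, 4))
        g = grad_codes(A, s, x, grouping_3x3, cfg)
        num = finite_difference_grad(
            lambda S: objective(A, S, x, grouping_3x3, cfg).J, s
        )
        assert np.max(np.abs(g - num)) <= 1e-4 * max(1.0, np.max(np.abs(num)))

    @pytest.mark.parametrize("gam", [0.0, 0.1, 1.0])
    def test_grad_dictionary_matches_finite_differences(self, rng, grouping_3x3, gam):
        cfg = TscConfig(k=9, group_size=3, gamma=gam)
        A = rng.standard_normal((5, 9))
        s = rng.standard_normal((9, 3))
        x = rng.standard_normal((5, 3))
        g = grad_dictionary(A, s, x, cfg)
        num = finite_difference_grad(
            lambda B: objective(B, s, x, grouping_3x3, cfg).J, A
        )
        assert np.max(np.abs(g - num)) <= 1e-4 * max(1.0, np.max(np.abs(num)))

    def test_penalty_gradient_vanishes_at_origin(self, rng, grouping_3x3):
        cfg = TscConfig(k=9, group_size=3)
        A = rng.standard_normal((6, 9))
        x = rng.standard_normal((6, 4))
        s = np.zeros((9, 4))
        np.testing.assert_allclose(
            grad_codes(A, s, x, grouping_3x3, cfg), -2 * A.T @ x, rtol=1e-12
        )

    def test_decay_only_dictionary_gradient(self, rng):
        cfg = TscConfig(k=9, group_size=3, gamma=0.7)
        A = rng.standard_normal((6, 9))
        s = np.zeros((9, 4))
        x = np.zeros((6, 4))
        np.testing.assert_allclose(grad_dictionary(A, s, x, cfg), 2 * 0.7 * A)

    def test_unsmoothed_gradient_refused(self, rng, grouping_3x3):
        cfg = TscConfig(k=9, group_size=3, epsilon=0.0)
        with pytest.raises(ValueError):
            grad_codes(
                rng.standard_normal((6, 9)),
                rng.standard_normal((9, 4)),
                rng.standard_normal((6, 4)),
                grouping_3x3,
                cfg,
            )


class TestInitCodes:
    def test_unit_norm_dictionary_leaves_product_unscaled(self, rng):
        A = rng.standard_normal((8, 5))
        A /= np.linalg.norm(A, axis=0)
        x = rng.standard_normal((8, 3))
        np.testing.assert_allclose(init_codes(A, x), A.T @ x)

    def test_orthonormal_dictionary_picks_out_basis_vector(self):
        A = np.linalg.qr(np.random.default_rng(0).standard_normal((6, 6)))[0]
        x = A[:, [2]]
        s = init_codes(A, x)
        np.testing.assert_allclose(s.ravel(), np.eye(6)[2], atol=1e-12)

    def test_matches_entrywise_loop(self, rng):
        A = rng.standard_normal((6, 4))
        x = rng.standard_normal((6, 3))
        s = init_codes(A, x)
        for r in range(4):
            for c in range(3):
                want = float(A[:, r] @ x[:, c]) / np.linalg.norm(A[:, r])
                assert s[r, c] == pytest.approx(want, rel=1e-12)

    def test_zero_norm_atom_rejected(self, rng):
        A = rng.standard_normal((6, 4))
        A[:, 1] = 0.0
        with pytest.raises(ValueError):
            init_codes(A, rng.standard_normal((6, 2)))


class TestEncode:
    def test_orthonormal_no_penalty_recovers_least_squares(self, rng, grouping_3x3):
        cfg = TscConfig(k=9, group_size=3, C=math.inf, lambda_=0.0)
        A = np.linalg.qr(rng.standard_normal((9, 9)))[0]
        x = rng.standard_normal((9, 4))
        s, _ = encode(A, x, grouping_3x3, cfg)
        np.testing.assert_allclose(s, A.T @ x, atol=1e-8)

    def test_objective_sequence_non_increasing(self, rng, grouping_3x3):
        cfg = TscConfig(k=9, group_size=3)
        A = rng.standard_normal((6, 9))
        A /= np.linalg.norm(A, axis=0)
        x = rng.standard_normal((6, 8))
        _, trace = encode(A, x, grouping_3x3, cfg)
        J = trace.objectives
        assert len(J) > 1
        assert np.all(np.diff(J) <= 1e-12)

    def test_code_norm_constraint_enforced(self, rng, grouping_3x3):
        cfg = TscConfig(k=9, group_size=3, C=0.01)
        A = rng.standard_normal((6, 9))
        A /= np.linalg.norm(A, axis=0)
        x = 5.0 * rng.standard_normal((6, 10))
        s, _ = encode(A, x, grouping_3x3, cfg)
        assert np.all(np.sum(s * s, axis=0) <= 0.01 + 1e-12)

    def test_convexity_restarts_agree(self, rng, grouping_3x3):
        # the code subproblem is convex, so random restarts must agree
        cfg = TscConfig(k=9, group_size=3, tol_rel=1e-12, max_inner_iters=3000)
        A = rng.standard_normal((6, 9))
        A /= np.linalg.norm(A, axis=0)
        x = rng.standard_normal((6, 5))
        finals = []
        for _ in range(5):
            s0 = rng.standard_normal((9, 5))
            s, _ = encode(A, x, grouping_3x3, cfg, s0=s0)
            finals.append(objective(A, s, x, grouping_3x3, cfg).J)
        spread = (max(finals) - min(finals)) / max(abs(min(finals)), 1e-12)
        assert spread <= 1e-4

    def test_projection_is_identity_inside_ball(self, rng):
        s = 0.01 * rng.standard_normal((4, 3))
        np.testing.assert_array_equal(project_codes(s, 1.0), s)


class TestLearn:
    def test_full_batch_descent_without_refresh(self, tiny_tsc_instance):
        _, _, x = tiny_tsc_instance
        cfg = TscConfig(
            k=16, group_size=3, batch_size=10_000, max_outer_iters=15,
            atom_refresh_every=0, seed=0,
        )
        _, _, trace = learn(x, cfg)
        J = trace.objectives
        assert np.all(np.diff(J) <= 1e-9 * np.abs(J[:-1]))

    def test_same_seed_reproduces_everything(self, tiny_tsc_instance):
        _, _, x = tiny_tsc_instance
        cfg = TscConfig(k=16, group_size=3, batch_size=64, max_outer_iters=10, seed=5)
        A1, s1, t1 = learn(x, cfg)
        A2, s2, t2 = learn(x, cfg)
        np.testing.assert_array_equal(A1, A2)
        np.testing.assert_array_equal(s1, s2)
        assert t1.objectives.tolist() == t2.objectives.tolist()

    def test_learned_atoms_unit_norm(self, tiny_tsc_instance):
        _, _, x = tiny_tsc_instance
        cfg = TscConfig(k=16, group_size=3, batch_size=64, max_outer_iters=5, seed=5)
        A, _, _ = learn(x, cfg)
        np.testing.assert_allclose(np.linalg.norm(A, axis=0), 1.0, rtol=1e-9)

    def test_recovers_dictionary_on_small_instance(self):
        cfg_data = SynthTscConfig(
            d=16, k=16, N=600, atoms_active_per_sample=3,
            noise_sd=0.01, topographic=True, seed=7,
        )
        A0, _, x = generate_tsc_instance(cfg_data)
        cfg = TscConfig(
            k=16, group_size=3, C=math.inf, batch_size=256,
            max_outer_iters=250, seed=8,
        )
        A, _, _ = learn(x, cfg)
        _, mean_cos = match_atoms(A, A0)
        assert mean_cos >= 0.8  # deep recovery is checked at larger N


def test_match_atoms_identity_permutation(rng):
    A = rng.standard_normal((8, 6))
    A /= np.linalg.norm(A, axis=0)
    perm = [3, 1, 5, 0, 2, 4]
    signs = np.array([1, -1, 1, -1, 1, 1.0])
    pairs, score = match_atoms(A[:, perm] * signs, A)
    assert score == pytest.approx(1.0, abs=1e-12)
    assert sorted(p[1] for p in pairs) == list(range(6))
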