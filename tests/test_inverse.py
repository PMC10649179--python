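"""WMNE/LORETA operators, regularization and localization behaviour."""

import numpy as np
import pytest

from mieeg.headmodel import SourceSpace
from mieeg.inverse import (
    InverseModel,
    average_reference_operator,
    choose_lambda,
    column_norm_weights,
    solve_loreta,
    solve_wmne,
    source_graph_laplacian,
)
from mieeg.validation import localization_study


class TestAverageReference:
    def test_n2_closed_form(self):
        np.testing.assert_allclose(
            average_reference_operator(2),
            [[0.5, -0.5], [-0.5, 0.5]])

    def test_annihilates_constants_and_idempotent(self):
        H = average_reference_operator(14)
        np.testing.assert_allclose(H @ np.ones(14), 0, atol=1e-14)
        np.testing.assert_allclose(H @ H, H, atol=1e-12)
        np.testing.assert_allclose(H, H.T, atol=1e-15)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            average_reference_operator(1)


class TestColumnNormWeights:
    def test_orthonormal_columns_give_identity(self):
        K, _ = np.linalg.qr(np.random.default_rng(0).normal(size=(10, 6)))
        np.testing.assert_allclose(column_norm_weights(K), 1.0, atol=1e-12)

    def test_scaling_homogeneity(self):
        K = np.random.default_rng(1).normal(size=(5, 7))
        w0 = column_norm_weights(K)
        K2 = K.copy()
        K2[:, 3] *= 3.0
        w1 = column_norm_weights(K2)
        assert w1[3] == pytest.approx(3 * w0[3])

    def test_zero_column_names_index(self):
        K = np.ones((4, 3))
        K[:, 1] = 0
        with pytest.raises(ValueError, match="1"):
            column_norm_weights(K)

    def test_depth_bias_on_fixture(self, bundle):
        # genuinely deeper sources (smaller shell radius) have weaker
        # gain columns, which is what the weighting compensates
        from mieeg.headmodel import lead_field
        from mieeg.pipeline import make_dome_source_space

        norms = {}
        for r in (0.072, 0.05):
            src = make_dome_source_space(r, subdivisions=2)
            lf = lead_field(bundle.solver, src, bundle.electrodes)
            norms[r] = column_norm_weights(lf.K).mean()
        assert norms[0.05] < norms[0.072]


class TestLaplacian:
    def test_triangle_graph_closed_form(self):
        L = source_graph_laplacian(np.array([[0, 1], [1, 2], [2, 0]]),
                                   n_vertices=3)
        np.testing.assert_allclose(L, [[2, -1, -1], [-1, 2, -1],
                                       [-1, -1, 2]])

    def test_constant_in_null_space(self, bundle):
        L = source_graph_laplacian(bundle.source_space)
        np.testing.assert_allclose(L @ np.ones(len(L)), 0, atol=1e-9)

    def test_positive_semidefinite_on_fixture(self, bundle):
        L = source_graph_laplacian(bundle.source_space)
        eig = np.linalg.eigvalsh(L)
        assert eig.min() > -1e-9


def _random_inverse(seed=0, n=10, m=24):
    rng = np.random.default_rng(seed)
    K = rng.normal(size=(n, m))
    return InverseModel(K=K, W=np.ones(m), L=np.eye(m), lam=0.0)


class TestWmne:
    def test_zero_data_zero_estimate(self):
        inv = _random_inverse()
        np.testing.assert_allclose(solve_wmne(inv, np.zeros(10)), 0)

    def test_matches_least_squares_min_norm_oracle(self):
        inv = _random_inverse(3)
        u = np.random.default_rng(4).normal(size=10)
        J = solve_wmne(inv, u)
        J_oracle = np.linalg.lstsq(inv.G, inv.H @ u, rcond=None)[0]
        np.testing.assert_allclose(J, J_oracle, atol=1e-8)

    def test_minimum_norm_among_consistent_solutions(self):
        inv = _random_inverse(5)
        u = np.random.default_rng(6).normal(size=10)
        J = solve_wmne(inv, u)
        resid = np.linalg.norm(inv.G @ J - inv.H @ u)
        rng = np.random.default_rng(7)
        # perturb within the null space of G: residual unchanged, norm up
        _, _, Vt = np.linalg.svd(inv.G)
        null = Vt[np.linalg.matrix_rank(inv.G):]
        for _ in range(200):
            delta = rng.normal(size=null.shape[0]) @ null
            J2 = J + 0.1 * delta
            assert np.linalg.norm(inv.G @ J2 - inv.H @ u) \
                <= resid + 1e-9 + resid * 1e-9
            assert np.linalg.norm(J2) >= np.linalg.norm(J) - 1e-12

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            solve_wmne(_random_inverse(), np.zeros(7))


class TestLoreta:
    def test_reduces_to_wmne_at_identity_weights(self):
        inv = _random_inverse(8)
        u = np.random.default_rng(9).normal(size=10)
        J_w = solve_wmne(inv, u)
        J_l = solve_loreta(inv, u)
        np.testing.assert_allclose(J_l, J_w, atol=1e-8 * np.abs(J_w).max())

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            InverseModel(K=np.eye(4), W=np.ones(4), L=np.eye(4), lam=-0.1)

    def test_penalty_shrinks_with_lambda(self, bundle):
        lf = bundle.lead_field
        inv = InverseModel.from_lead_field(lf)
        u = lf.K[:, 42] * 1e-8
        norms = []
        scale = np.trace(inv.G @ inv.G.T)
        for lam in np.logspace(-8, 2, 10) * scale:
            J = solve_loreta(
                InverseModel(K=inv.K, W=inv.W, L=inv.L, lam=lam), u)
            norms.append(np.linalg.norm(inv.L @ (inv.W * J)))
        assert all(b <= a * (1 + 1e-9)
                   for a, b in zip(norms, norms[1:]))

    def test_reference_invariance(self, bundle):
        inv = InverseModel.from_lead_field(bundle.lead_field, lam=1e-3)
        u = np.random.default_rng(11).normal(size=14)
        J1 = solve_loreta(inv, u)
        J2 = solve_loreta(inv, u + 7.5)
        np.testing.assert_allclose(J1, J2, atol=1e-10 * np.abs(J1).max())

    def test_linearity_in_data(self, bundle):
        inv = InverseModel.from_lead_field(bundle.lead_field, lam=1e-3)
        rng = np.random.default_rng(12)
        u1, u2 = rng.normal(size=(2, 14))
        J = solve_loreta(inv, 2.0 * u1 - 0.5 * u2)
        np.testing.assert_allclose(
            J, 2.0 * solve_loreta(inv, u1) - 0.5 * solve_loreta(inv, u2),
            atol=1e-10 * np.abs(J).max())


class TestChooseLambda:
    def test_noiseless_selects_smallest(self, bundle):
        inv = InverseModel.from_lead_field(bundle.lead_field)
        u = bundle.lead_field.K[:, 10] * 1e-8
        grid = np.array([1e-6, 1e-3, 1.0])
        lam = choose_lambda(inv, u, grid)
        # smallest grid entry wins (relative scaling is monotone)
        assert lam == pytest.approx(choose_lambda(inv, u, grid[:1]))

    def test_pure_null_space_noise_selects_largest(self):
        # rank-1 gain: anything orthogonal to its range is pure noise
        K = np.outer(np.array([1.0, -1.0, 0.5, -0.5]), np.ones(6))
        inv = InverseModel(K=K, W=np.ones(6), L=np.eye(6))
        u_null = np.array([0.5, 0.5, -0.5, -0.5])
        u_null -= u_null @ inv.G[:, 0] * inv.G[:, 0] \
            / (inv.G[:, 0] @ inv.G[:, 0])
        grid = np.array([1e-6, 1e-2, 1.0])
        lam = choose_lambda(inv, u_null, grid)
        assert lam == pytest.approx(choose_lambda(inv, u_null, grid[-1:]))

    def test_singleton_grid(self, bundle):
        inv = InverseModel.from_lead_field(bundle.lead_field)
        u = np.random.default_rng(13).normal(size=14)
        lam = choose_lambda(inv, u, np.array([0.01]))
        assert lam > 0

    def test_empty_grid_rejected(self, bundle):
        inv = InverseModel.from_lead_field(bundle.lead_field)
        with pytest.raises(ValueError):
            choose_lambda(inv, np.zeros(14), np.array([]))


class TestLocalization:
    def test_error_monotone_in_snr(self, level3_lead_field):
        res = localization_study(level3_lead_field,
                                 snrs_db=(0.0, 10.0, 20.0, None),
                                 n_trials=50, seed=1)
        med = [res.median_error_cm[k] for k in ("0", "10", "20", "inf")]
        # peak localization is quantized to the source grid, so medians
        # closer than half a vertex spacing are indistinguishable
        src = level3_lead_field.source_space
        e = src.edges()
        tol = 0.5 * 100 * np.linalg.norm(
            src.vertices[e[:, 0]] - src.vertices[e[:, 1]], axis=1).mean()
        assert med[0] >= med[1] - tol
        assert med[1] >= med[2] - tol
        assert med[2] >= med[3] - tol
        assert res.median_error_cm["20"] <= 2.5
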