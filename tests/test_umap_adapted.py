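"""Adapted-UMAP core: distance computation, smooth-kNN calibration,
affinities, kernel fit, normalized-Q cost and its gradient, and the
end-to-end embedding contracts.

The central correctness oracle is the finite-difference check of the
analytic cross-entropy gradient; the calibration and kernel-fit oracles
are an independent scalar root-finder and a grid-search least squares.
"""

import math

import numpy as np
import pytest
from scipy.optimize import brentq
from sklearn.metrics import adjusted_rand_score

from vizclust import umap_adapted as ua
from vizclust.clustering import leiden_on_embedding
from vizclust.types import ValidationError


class TestPairwiseSqEuclidean:
    def test_three_four_five(self):
        D = ua.pairwise_sq_euclidean(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert D[0, 1] == pytest.approx(25.0)
        assert D[1, 0] == pytest.approx(25.0)

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 5))
        D = ua.pairwise_sq_euclidean(X)
        naive = np.zeros((10, 10))
        for i in range(10):
            for j in range(10):
                naive[i, j] = ((X[i] - X[j]) ** 2).sum()
        assert np.abs(D - naive).max() < 1e-9
        assert np.array_equal(np.diag(D), np.zeros(10))
        assert np.array_equal(D, D.T)

    def test_rejects_non_finite(self):
        with pytest.raises(ValidationError, match="finite"):
            ua.pairwise_sq_euclidean(np.array([[0.0], [np.nan]]))


class TestCalibration:
    def test_uniform_neighborhood_closed_form(self):
        # all 15 neighbors at offset 1: 15 exp(-1/sigma) = log2(15)
        target = math.log2(15)
        sigma = ua.solve_sigma(np.ones(15), target, tol=1e-9, max_iter=200)
        closed = 1.0 / math.log(15.0 / math.log2(15.0))
        assert sigma == pytest.approx(closed, abs=1e-4)
        # independent oracle: scipy root-finder on the same equation
        root = brentq(lambda s: 15 * math.exp(-1.0 / s) - target, 1e-6, 100)
        assert sigma == pytest.approx(root, abs=1e-4)

    def test_residual_below_contract_on_random_data(self):
        rng = np.random.default_rng(1)
        D = ua.pairwise_sq_euclidean(rng.normal(size=(50, 6)))
        rho, sigma = ua.calibrate_local_scales(D, 15)
        target = math.log2(15)
        nn = ua._knn_indices(D, 15)
        for i in range(50):
            mass = np.exp(
                -np.maximum(0.0, D[i, nn[i]] - rho[i]) / sigma[i]
            ).sum()
            assert abs(mass - target) < 1e-4
        assert (sigma > 0).all()
        assert np.allclose(rho, D[np.arange(50), nn[:, 0]])

    def test_duplicate_points_hit_sigma_floor_without_error(self):
        X = np.zeros((20, 3))  # every pairwise distance is 0
        D = ua.pairwise_sq_euclidean(X)
        rho, sigma = ua.calibrate_local_scales(D, 15)
        assert np.allclose(sigma, ua.SIGMA_FLOOR)
        assert np.allclose(rho, 0.0)

    def test_k_local_bound(self):
        with pytest.raises(ValidationError, match="k_local"):
            ua.calibrate_local_scales(np.zeros((5, 5)), 5)


@pytest.fixture(scope="module")
def graph():
    rng = np.random.default_rng(2)
    D = ua.pairwise_sq_euclidean(rng.normal(size=(40, 4)))
    rho, sigma = ua.calibrate_local_scales(D, 10)
    P = ua.build_affinities(D, rho, sigma, 20)
    return D, P


class TestAffinities:
    def test_nearest_neighbor_gets_probability_one(self, graph):
        D, P = graph
        nn = ua._knn_indices(D, 1)[:, 0]
        assert np.allclose(P[np.arange(40), nn], 1.0)

    def test_sparse_outside_k_graph(self, graph):
        _, P = graph
        assert ((P > 0).sum(axis=1) <= 20).all()
        assert ((P >= 0) & (P <= 1)).all()

    def test_rows_non_increasing_in_distance(self, graph):
        D, P = graph
        for i in range(40):
            nz = np.flatnonzero(P[i])
            order = nz[np.argsort(D[i, nz])]
            assert (np.diff(P[i, order]) <= 1e-12).all()


class TestSymmetrize:
    def test_half_sum_rule(self):
        Pd = np.array([[0.0, 1.0], [0.0, 0.0]])
        P = ua.symmetrize_half_sum(Pd)
        assert P[0, 1] == P[1, 0] == pytest.approx(0.5)

    def test_symmetric_input_is_fixed_point(self):
        rng = np.random.default_rng(3)
        M = rng.random((6, 6))
        M = (M + M.T) / 2
        assert np.allclose(ua.symmetrize_half_sum(M), M)

    def test_output_stays_in_unit_interval(self):
        rng = np.random.default_rng(4)
        Pd = rng.random((8, 8))
        P = ua.symmetrize_half_sum(Pd)
        assert ((P >= 0) & (P <= 1)).all()
        assert np.array_equal(P, P.T)


class TestKernelFit:
    def test_w_at_zero_is_one_and_strictly_decreasing(self, kernel):
        assert kernel.a > 0 and kernel.b > 0
        d = np.linspace(0.0, 3.0, 500)
        w = 1.0 / (1.0 + kernel.a * d ** (2 * kernel.b))
        assert w[0] == pytest.approx(1.0)
        assert (np.diff(w) < 0).all()

    def test_rms_residual_beats_grid_search_oracle(self, kernel):
        # independent oracle: brute-force least squares over an (a, b) grid
        d = np.linspace(0.0, 3.0, 300)
        psi = np.where(d <= 0.25, 1.0, np.exp(-(d - 0.25)))
        best = np.inf
        for a in np.linspace(0.5, 2.5, 60):
            for b in np.linspace(0.5, 2.0, 60):
                w = 1.0 / (1.0 + a * np.maximum(d, 1e-12) ** (2 * b))
                best = min(best, np.sqrt(((w - psi) ** 2).mean()))
        assert kernel.rms_residual < 0.03
        assert kernel.rms_residual <= best + 1e-6


class TestNormalizedQ:
    def test_two_points_sum_to_one(self, kernel):
        Q = ua.normalized_q(np.array([[0.0, 0.0], [5.0, 1.0]]), kernel)
        assert Q[0, 1] + Q[1, 0] == pytest.approx(1.0)

    def test_equilateral_triangle_is_uniform(self, kernel):
        Y = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, math.sqrt(3) / 2]])
        Q = ua.normalized_q(Y, kernel)
        off = Q[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 1.0 / 6.0)

    def test_sums_to_one_with_zero_diagonal(self, kernel):
        rng = np.random.default_rng(5)
        Q = ua.normalized_q(rng.normal(size=(30, 2)), kernel)
        assert Q.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.array_equal(np.diag(Q), np.zeros(30))


def _random_p(rng, n):
    P = rng.random((n, n))
    P = (P + P.T) / 2.0
    np.fill_diagonal(P, 0.0)
    return P


class TestCrossEntropy:
    def test_minimum_is_entropy_when_q_equals_p(self, kernel):
        rng = np.random.default_rng(6)
        Y = rng.normal(size=(12, 2))
        Q = ua.normalized_q(Y, kernel)
        c = ua.cross_entropy_cost(Q, Q)
        mask = ~np.eye(12, dtype=bool)
        entropy = -(Q[mask] * np.log(Q[mask] + 1e-12)).sum()
        assert c == pytest.approx(entropy, rel=1e-10)

    def test_gibbs_inequality_on_random_inputs(self, kernel):
        rng = np.random.default_rng(7)
        for _ in range(10):
            n = int(rng.integers(4, 15))
            P = _random_p(rng, n)
            P_hat = P / P.sum()
            Q = ua.normalized_q(rng.normal(size=(n, 2)), kernel)
            mask = ~np.eye(n, dtype=bool)
            entropy = -(P_hat[mask] * np.log(P_hat[mask] + 1e-12)).sum()
            assert ua.cross_entropy_cost(P, Q) >= entropy - 1e-9

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="shape"):
            ua.cross_entropy_cost(np.ones((3, 3)), np.ones((4, 4)))

    def test_analytic_gradient_matches_finite_differences(self, kernel):
        # the module's central correctness oracle
        rng = np.random.default_rng(8)
        h = 1e-6
        for _ in range(5):
            n = int(rng.integers(5, 11))
            Y = rng.normal(size=(n, 2))
            P = _random_p(rng, n)
            grad = ua.cross_entropy_grad(P, Y, kernel)
            fd = np.zeros_like(Y)
            for i in range(n):
                for d in range(2):
                    Yp, Ym = Y.copy(), Y.copy()
                    Yp[i, d] += h
                    Ym[i, d] -= h
                    fd[i, d] = (
                        ua.cross_entropy_cost(P, ua.normalized_q(Yp, kernel))
                        - ua.cross_entropy_cost(P, ua.normalized_q(Ym, kernel))
                    ) / (2 * h)
            rel = np.abs(grad - fd).max() / np.abs(fd).max()
            assert rel < 1e-4


class TestGradientDescent:
    def test_two_points_have_flat_cost(self, kernel):
        # with a single pair, Q is constant in the coordinates
        P = np.array([[0.0, 0.3], [0.3, 0.0]])
        Y0 = np.array([[0.0, 0.0], [1.0, 2.0]])
        emb = ua.gradient_descent_embed(
            P, kernel, ua.UmapParams(n_iter=50), Y_init=Y0
        )
        assert np.allclose(emb.coords, Y0, atol=1e-9)

    def test_cost_trace_decreases(self, kernel):
        rng = np.random.default_rng(9)
        n = 40
        P = _random_p(rng, n)
        emb = ua.gradient_descent_embed(P, kernel, ua.UmapParams(seed=3))
        assert emb.history[-1] < emb.history[0]

    def test_asymmetric_p_rejected(self, kernel):
        P = np.array([[0.0, 1.0], [0.5, 0.0]])
        with pytest.raises(ValidationError, match="symmetric"):
            ua.gradient_descent_embed(P, kernel, ua.UmapParams())


class TestEndToEnd:
    def test_deterministic_under_fixed_seed(self, small_log10p1):
        X = small_log10p1[:, :60]
        p = ua.UmapParams(seed=11, n_iter=60)
        e1 = ua.umap_adapted_embed(X, p)
        e2 = ua.umap_adapted_embed(X, p)
        assert np.array_equal(e1.coords, e2.coords)

    def test_small_cohort_caps_k_graph_at_25(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(50, 40))  # 40 samples < 50
        emb = ua.umap_adapted_embed(X, ua.UmapParams(n_iter=20))
        assert emb.provenance["params"]["k_graph_effective"] == 25
        assert emb.provenance["method"] == "UMAP (adapted)"

    def test_permutation_equivariance_with_tied_init(self, kernel):
        rng = np.random.default_rng(12)
        n = 20
        X = rng.normal(size=(n, 6))
        D = ua.pairwise_sq_euclidean(X)
        rho, sigma = ua.calibrate_local_scales(D, 5)
        P = ua.symmetrize_half_sum(ua.build_affinities(D, rho, sigma, 10))
        Y0 = rng.normal(scale=1e-2, size=(n, 2))
        perm = rng.permutation(n)
        params = ua.UmapParams(k_local=5, k_graph=10, n_iter=40)
        base = ua.gradient_descent_embed(P, kernel, params, Y_init=Y0)
        permuted = ua.gradient_descent_embed(
            P[np.ix_(perm, perm)], kernel, params, Y_init=Y0[perm]
        )
        assert np.allclose(permuted.coords, base.coords[perm], atol=1e-6)

    def test_recovers_planted_subgroups(self, small_cohort, small_log10p1):
        _, _, truth = small_cohort
        emb = ua.umap_adapted_embed(
            small_log10p1, ua.UmapParams(seed=2), transform="log10p1"
        )
        clusters = leiden_on_embedding(emb, n_neighbors=15, resolution=0.05,
                                       seed=0)
        assert adjusted_rand_score(truth, clusters.labels) >= 0.9
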