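import numpy as np
import pytest
import scipy.sparse as sp

import velofate as vf
from velofate.kernels import (
    VelocityMoments,
    _sampled_row,
    hessian_diag_row,
    propagate_uncertainty,
    softmax_correlation_row,
)


class TestCorrelations:
    @pytest.mark.parametrize(
        "v, s, expected",
        [
            ((1, 0, -1), (2, 0, -2), 1.0),     # parallel
            ((1, 0, -1), (-2, 0, 2), -1.0),    # antiparallel
            ((1, 0, -1), (0, 1, -1), 0.5),     # hand-computed Pearson
        ],
    )
    def test_hand_computed_values(self, v, s, expected):
        x = np.zeros(3)
        c = vf.velocity_correlations(
            x, np.array(v, float), np.array([s], float)
        )
        assert c[0] == pytest.approx(expected)

    def test_constant_state_change_gets_zero(self):
        c = vf.velocity_correlations(
            np.zeros(3), np.array([1.0, 0, -1]), np.ones((1, 3))
        )
        assert c[0] == 0.0

    def test_constant_velocity_is_undefined(self):
        c = vf.velocity_correlations(
            np.zeros(3), np.ones(3), np.array([[1.0, 2, 3]])
        )
        assert np.isnan(c).all()


class TestSoftmax:
    def test_symmetry(self):
        assert np.allclose(
            vf.softmax_transform(np.zeros(2), sigma=5.0), [0.5, 0.5]
        )

    def test_hand_computed(self):
        p = vf.softmax_transform(np.array([1.0, -1.0]), sigma=1.0)
        e2 = np.exp(2.0)
        assert p == pytest.approx([e2 / (1 + e2), 1 / (1 + e2)])
        assert p[0] == pytest.approx(0.8808, abs=1e-4)

    def test_large_sigma_concentrates_on_argmax(self):
        p = vf.softmax_transform(np.array([1.0, -1.0]), sigma=100.0)
        assert p[0] > 0.9999

    def test_stability_at_extreme_sigma(self):
        p = vf.softmax_transform(np.array([1.0, 0.5, -1.0]), sigma=5000.0)
        assert np.isfinite(p).all() and p.sum() == pytest.approx(1.0)


class TestSigmaHeuristic:
    def test_constant_magnitude(self):
        assert vf.estimate_sigma(np.full(10, 0.5)) == pytest.approx(2.0)

    def test_median_of_multiset(self):
        assert vf.estimate_sigma(
            np.array([0.2, -0.4, 0.6, -0.8])
        ) == pytest.approx(2.0)

    def test_identity_after_scaling(self, rng):
        c = rng.uniform(-1, 1, size=101)
        sigma = vf.estimate_sigma(c)
        assert np.median(sigma * np.abs(c)) == pytest.approx(1.0)

    def test_zero_median_falls_back_with_warning(self):
        with pytest.warns(UserWarning):
            assert vf.estimate_sigma(np.zeros(5)) == 1.0


class TestMoments:
    def test_constant_neighborhood(self, small_field):
        graph = vf.build_graph(small_field.expr, K=5, L=5)
        vel = vf.VelocityField(
            values=np.ones_like(small_field.vel.values),
            cell_ids=small_field.vel.cell_ids,
            gene_ids=small_field.vel.gene_ids,
        )
        mom = vf.estimate_velocity_moments(vel, graph)
        assert np.allclose(mom.mu, 1.0)
        assert np.allclose(mom.var, 0.0)

    def test_two_point_hand_computed(self):
        # cell 0 and its sole neighbor 1 with velocities (0,0) and (2,2)
        expr = vf.ExpressionMatrix(
            values=np.array([[0.0, 0], [1, 1]]),
            cell_ids=["a", "b"], gene_ids=["g0", "g1"],
        )
        vel = vf.VelocityField(
            values=np.array([[0.0, 0], [2, 2]]),
            cell_ids=["a", "b"], gene_ids=["g0", "g1"],
        )
        graph = vf.build_graph(expr, K=1, L=1)
        mom = vf.estimate_velocity_moments(vel, graph)
        assert np.allclose(mom.mu, 1.0)
        assert np.allclose(mom.var, 1.0)

    def test_variance_non_negative(self, small_field):
        graph = vf.build_graph(small_field.expr, K=10, L=10)
        mom = vf.estimate_velocity_moments(small_field.vel, graph)
        assert (mom.var >= 0).all()


class TestUncertaintyPropagation:
    def test_zero_variance_equals_deterministic(self, rng):
        S = rng.normal(size=(6, 10))
        v = rng.normal(size=10)
        det = softmax_correlation_row(v, S, 2.0)
        prop = propagate_uncertainty(v, S, 2.0, np.zeros(10))
        assert np.array_equal(det, prop)

    def test_hessian_matches_central_finite_differences(self, rng):
        sigma = 1.7
        for _ in range(3):
            K, G = 5, 12
            S = rng.normal(size=(K, G))
            v = rng.normal(size=G)
            H_an = hessian_diag_row(v, S, sigma)
            delta = 1e-3
            H_fd = np.empty_like(H_an)
            for j in range(G):
                e = np.zeros(G)
                e[j] = delta
                H_fd[:, j] = (
                    softmax_correlation_row(v + e, S, sigma)
                    - 2 * softmax_correlation_row(v, S, sigma)
                    + softmax_correlation_row(v - e, S, sigma)
                ) / delta**2
            scale = np.abs(H_fd).max()
            assert np.abs(H_an - H_fd).max() / scale < 1e-6

    def test_expectation_matches_mc_sampling_mean(self):
        rng = np.random.default_rng(3)
        K, G = 5, 10
        S = rng.normal(size=(K, G))
        v = rng.normal(size=G)
        var = rng.uniform(0.01, 0.05, size=G)
        sigma = 2.0
        analytic = propagate_uncertainty(v, S, sigma, var)
        n = 50_000
        draws = rng.normal(v, np.sqrt(var), size=(n, G))
        rows = np.empty((n, K))
        for i, d in enumerate(draws):
            rows[i] = softmax_correlation_row(d, S, sigma)
        se = rows.std(axis=0) / np.sqrt(n)
        assert (np.abs(analytic - rows.mean(axis=0)) <= 3 * se).all()


class TestVelocityKernel:
    def make_tiny(self):
        expr = vf.ExpressionMatrix(
            values=np.array([[0.0, 0], [1, 0], [0, 1]]),
            cell_ids=list("abc"), gene_ids=["g0", "g1"],
        )
        vel = vf.VelocityField(
            values=np.array([[1.0, 0], [0, 0], [0, 0]]),
            cell_ids=list("abc"), gene_ids=["g0", "g1"],
        )
        graph = vf.build_graph(expr, K=2, L=2)
        return expr, vel, graph

    def test_three_cell_worked_example(self):
        # c = (1, -1) against the two neighbors, median |c| = 1 => sigma = 1,
        # softmax gives (0.8808, 0.1192); zero-velocity rows fall to uniform
        expr, vel, graph = self.make_tiny()
        with pytest.warns(UserWarning, match="uniform"):
            P = vf.velocity_kernel(expr, vel, graph)
        row0 = P.probs[0].toarray().ravel()
        assert row0[1] == pytest.approx(0.8808, abs=1e-4)
        assert row0[2] == pytest.approx(0.1192, abs=1e-4)

    def test_stochastic_with_zero_variance_equals_deterministic(self, rng):
        field = vf.simulate_branching_field(
            n_cells=60, n_genes=8, noise_sd=0.0, seed=2
        )
        graph = vf.build_graph(field.expr, K=5, L=5)
        det = vf.velocity_kernel(
            field.expr, field.vel, graph,
            vf.KernelParams(mode="deterministic"),
        )
        # constant velocity across the neighborhood => zero variance
        vel_const = vf.VelocityField(
            values=np.tile(field.vel.values[0], (60, 1)),
            cell_ids=field.vel.cell_ids, gene_ids=field.vel.gene_ids,
        )
        det_c = vf.velocity_kernel(
            field.expr, vel_const, graph, vf.KernelParams(mode="deterministic")
        )
        sto_c = vf.velocity_kernel(
            field.expr, vel_const, graph, vf.KernelParams(mode="stochastic")
        )
        assert (det_c.probs != sto_c.probs).nnz == 0
        assert det.probs.shape == det_c.probs.shape

    def test_sampling_mode_approaches_stochastic_mode(self):
        # constant-speed line field: velocity uncertainty is small relative
        # to the mean everywhere, so the second-order expectation and the
        # Monte-Carlo mean must agree closely
        rng = np.random.default_rng(0)
        n, G = 100, 10
        t = np.sort(rng.uniform(0, 1, n))
        direction = rng.normal(size=G)
        direction /= np.linalg.norm(direction)
        X = np.outer(t * 5, direction) + rng.normal(0, 0.05, (n, G))
        V = np.tile(direction, (n, 1)) + rng.normal(0, 0.05, (n, G))
        ids = [f"c{i}" for i in range(n)]
        gids = [f"g{j}" for j in range(G)]
        expr = vf.ExpressionMatrix(X, ids, gids)
        vel = vf.VelocityField(V, ids, gids)
        graph = vf.build_graph(expr, K=8, L=8)
        sto = vf.velocity_kernel(
            expr, vel, graph, vf.KernelParams(mode="stochastic")
        )
        sam = vf.velocity_kernel(
            expr, vel, graph,
            vf.KernelParams(mode="sampling", n_samples=10_000, seed=11),
        )
        assert np.abs(sto.probs - sam.probs).max() < 0.01

    def test_backward_twice_is_forward(self, small_field):
        graph = vf.build_graph(small_field.expr, K=6, L=6)
        fwd = vf.velocity_kernel(small_field.expr, small_field.vel, graph)
        neg = vf.VelocityField(
            values=-small_field.vel.values,
            cell_ids=small_field.vel.cell_ids,
            gene_ids=small_field.vel.gene_ids,
        )
        back_of_neg = vf.velocity_kernel(
            small_field.expr, neg, graph, vf.KernelParams(backward=True)
        )
        assert np.abs(fwd.probs - back_of_neg.probs).max() < 1e-12

    def test_rows_are_stochastic(self, small_field):
        graph = vf.build_graph(small_field.expr, K=6, L=6)
        P = vf.velocity_kernel(small_field.expr, small_field.vel, graph)
        rs = np.asarray(P.probs.sum(axis=1)).ravel()
        assert np.abs(rs - 1).max() < 1e-10
        assert P.probs.data.min() >= 0


class TestConnectivityAndCombination:
    def test_row_normalization_examples(self):
        A = sp.csr_matrix(np.array([[0.0, 1, 3], [1, 0, 0], [3, 0, 0]]))
        g = vf.NeighborGraph(distances=A.copy(), adjacency=A, K=1)
        P = vf.connectivity_kernel(g)
        assert np.allclose(
            P.probs[0].toarray().ravel(), [0, 0.25, 0.75]
        )

    def test_two_cell_swap(self):
        A = sp.csr_matrix(np.array([[0.0, 2], [2, 0]]))
        g = vf.NeighborGraph(distances=A.copy(), adjacency=A, K=1)
        P = vf.connectivity_kernel(g)
        assert np.allclose(P.probs.toarray(), [[0, 1], [1, 0]])

    def test_isolated_cell_gets_self_loop(self):
        A = sp.csr_matrix(np.array([[0.0, 1, 0], [1, 0, 0], [0, 0, 0]]))
        g = vf.NeighborGraph(distances=A.copy(), adjacency=A, K=1)
        with pytest.warns(UserWarning, match="isolated"):
            P = vf.connectivity_kernel(g)
        assert P.probs[2, 2] == 1.0

    @pytest.mark.parametrize("weights", [(1.0, 0.0), (0.0, 1.0), (0.5, 0.5)])
    def test_combination_weights(self, weights):
        P1 = vf.TransitionMatrix(sp.csr_matrix(np.array([[1.0, 0], [1, 0]])))
        P2 = vf.TransitionMatrix(sp.csr_matrix(np.array([[0.0, 1], [0, 1]])))
        combo = vf.combine_kernels([P1, P2], list(weights))
        expected = weights[0] * P1.probs.toarray() + weights[1] * P2.probs.toarray()
        assert np.allclose(combo.probs.toarray(), expected)

    def test_direction_mismatch_rejected(self):
        P1 = vf.TransitionMatrix(sp.identity(2, format="csr"))
        P2 = vf.TransitionMatrix(sp.identity(2, format="csr"), backward=True)
        with pytest.raises(vf.ValidationError, match="forward and backward"):
            vf.combine_kernels([P1, P2], [0.5, 0.5])


class TestDensityNormalize:
    def test_regular_graph_uniform_rescale(self):
        A = sp.csr_matrix(np.array([[0.0, 1, 1], [1, 0, 1], [1, 1, 0]]))
        W = vf.density_normalize(A)
        assert np.allclose(W.toarray(), A.toarray() / 4.0)

    def test_star_graph_downweights_hub(self):
        # 4-node star: hub 0 with leaves 1..3
        A = np.zeros((4, 4))
        A[0, 1:] = A[1:, 0] = 1.0
        W = vf.density_normalize(sp.csr_matrix(A)).toarray()
        # hub-leaf similarity gets divided by deg(hub)=3 * deg(leaf)=1
        assert W[0, 1] == pytest.approx(1 / 3)
        assert np.abs(W - W.T).max() < 1e-15

    def test_zero_degree_node_raises(self):
        A = sp.csr_matrix(np.array([[0.0, 1, 0], [1, 0, 0], [0, 0, 0]]))
        with pytest.raises(vf.ValidationError, match="zero-degree"):
            vf.density_normalize(A)
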