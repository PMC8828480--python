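import numpy as np
import pytest

import velofate as vf


class TestCircularProjection:
    def test_one_hot_rows_land_on_vertices(self):
        F = np.eye(3)
        emb = vf.circular_projection(F)
        for i in range(3):
            a = emb.angles[i]
            assert np.allclose(emb.coords[i], [np.cos(a), np.sin(a)])

    def test_uniform_row_lands_at_origin(self):
        F = np.vstack([np.full(4, 0.25), np.eye(4)])
        emb = vf.circular_projection(F)
        assert np.allclose(emb.coords[0], [0.0, 0.0], atol=1e-12)

    def test_two_lineage_hand_computed(self):
        F = np.array([[0.7, 0.3]])
        emb = vf.circular_projection(F)
        # angles 0 and pi: x = 0.7 - 0.3 = 0.4
        assert np.allclose(sorted(emb.angles), [0.0, np.pi])
        assert emb.coords[0, 0] == pytest.approx(0.4 * np.cos(emb.angles[0]))
        assert emb.coords[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_coords_stay_in_unit_disk(self, rng):
        F = rng.dirichlet(np.ones(5), size=200)
        emb = vf.circular_projection(F)
        assert (np.linalg.norm(emb.coords, axis=1) <= 1 + 1e-12).all()

    def test_angles_evenly_spaced(self, rng):
        F = rng.dirichlet(np.ones(4), size=50)
        emb = vf.circular_projection(F)
        gaps = np.diff(np.sort(emb.angles))
        assert np.allclose(gaps, np.pi / 2)

    def test_similar_lineages_are_adjacent(self, rng):
        # lineages 0 and 1 share their fate support; 2 is independent, so
        # the ordering must place 0 and 1 next to each other
        base = rng.dirichlet(np.ones(2), size=300)
        F = np.column_stack([
            base[:, 0] * 0.55, base[:, 0] * 0.45, base[:, 1]
        ])
        F /= F.sum(axis=1, keepdims=True)
        emb = vf.circular_projection(F)
        pos = {l: emb.ordering.index(l) for l in range(3)}
        assert abs(pos[0] - pos[1]) in (1, 2)  # adjacent on a 3-cycle

    def test_single_lineage_rejected(self):
        with pytest.raises(vf.ValidationError):
            vf.circular_projection(np.ones((5, 1)))


class TestPriming:
    def test_entropy_values(self):
        F = np.array([[0.5, 0.5], [1.0, 0.0], [0.25, 0.75]])
        S = vf.priming_entropy(F)
        assert S[0] == pytest.approx(np.log(2))
        assert S[1] == 0.0
        assert S[2] == pytest.approx(0.5623, abs=1e-4)

    def test_kl_of_mean_row_is_zero(self):
        F = np.tile([0.3, 0.7], (10, 1))
        scores = vf.priming_kl(F)
        assert np.allclose(scores.kl, 0.0)

    def test_kl_hand_computed(self):
        F = np.array([[1.0, 0.0], [0.0, 1.0]])
        scores = vf.priming_kl(F)  # mean fate (0.5, 0.5)
        assert np.allclose(scores.kl, np.log(2))

    def test_kl_non_negative(self, rng):
        F = rng.dirichlet(np.ones(4), size=100)
        assert (vf.priming_kl(F).kl >= 0).all()

    def test_lineage_permutation_equivariance(self, rng):
        F = rng.dirichlet(np.ones(4), size=50)
        perm = rng.permutation(4)
        assert np.allclose(
            vf.priming_entropy(F), vf.priming_entropy(F[:, perm])
        )
        assert np.allclose(
            vf.priming_kl(F).kl, vf.priming_kl(F[:, perm]).kl
        )


class TestDrivers:
    def make_expr(self, X):
        return vf.ExpressionMatrix(
            values=X,
            cell_ids=[f"c{i}" for i in range(X.shape[0])],
            gene_ids=[f"g{j}" for j in range(X.shape[1])],
        )

    def test_gene_equal_to_fate_column_ranks_first(self, rng):
        fate = rng.uniform(size=30)
        X = np.column_stack([rng.normal(size=30), fate, -fate])
        ranking = vf.rank_drivers(self.make_expr(X), fate)
        assert ranking.order[0] == 1
        assert ranking.correlations[1] == pytest.approx(1.0)
        assert ranking.correlations[2] == pytest.approx(-1.0)
        # negated gene is the last defined rank
        assert ranking.order[-1] == 2

    def test_constant_gene_flagged_undefined_and_last(self, rng):
        fate = rng.uniform(size=20)
        X = np.column_stack([fate, np.full(20, 3.0)])
        ranking = vf.rank_drivers(self.make_expr(X), fate)
        assert np.isnan(ranking.correlations[1])
        assert ranking.order[-1] == 1

    def test_cluster_restriction(self, rng):
        fate = np.concatenate([rng.uniform(size=20), np.zeros(20)])
        gene = fate.copy()
        gene[20:] = rng.normal(size=20)  # uncorrelated outside the cluster
        X = gene[:, None]
        ranking = vf.rank_drivers(
            self.make_expr(X), fate, restrict_to=np.arange(20)
        )
        assert ranking.correlations[0] == pytest.approx(1.0)

    def test_too_small_restriction_raises(self, rng):
        X = rng.normal(size=(10, 2))
        with pytest.raises(vf.ValidationError):
            vf.rank_drivers(self.make_expr(X), rng.uniform(size=10),
                            restrict_to=np.array([1, 2]))


class TestWeightClipping:
    def test_values_below_threshold_raised(self):
        w = vf.clip_weights(np.array([0.001, 0.5]), threshold=0.01)
        assert np.allclose(w, [0.01, 0.5])

    def test_zero_threshold_is_identity(self, rng):
        f = rng.uniform(size=20)
        assert np.array_equal(vf.clip_weights(f, threshold=0.0), f)


class TestTrendFitting:
    def test_noiseless_linear_recovered_exactly(self, rng):
        tau = np.sort(rng.uniform(0, 1, 200))
        y = 2.0 * tau
        fit = vf.fit_trend(y, tau, np.ones_like(tau))
        assert np.abs(fit.fitted - 2.0 * fit.test_grid).max() < 1e-6

    def test_one_hot_weights_equal_subset_fit(self, rng):
        tau = np.sort(rng.uniform(0, 1, 100))
        y = np.sin(2 * tau) + rng.normal(0, 0.05, 100)
        w = np.zeros(100)
        subset = np.arange(0, 100, 2)
        w[subset] = 1.0
        full = vf.fit_trend(y, tau, w)
        sub = vf.fit_trend(y[subset], tau[subset], np.ones(len(subset)))
        assert np.abs(full.fitted - sub.fitted).max() < 1e-10

    def test_sine_recovery_under_noise(self):
        rng = np.random.default_rng(12)
        n = 500
        tau = np.sort(rng.uniform(0, 2 * np.pi, n))
        y = np.sin(tau) + rng.normal(0, 0.1, n)
        fit = vf.fit_trend(y, tau, np.ones(n))
        rmse = np.sqrt(np.mean((fit.fitted - np.sin(fit.test_grid)) ** 2))
        assert rmse < 0.05

    def test_affine_equivariance(self, rng):
        tau = np.sort(rng.uniform(0, 1, 150))
        y = np.cos(3 * tau) + rng.normal(0, 0.1, 150)
        w = rng.uniform(0.1, 1, 150)
        base = vf.fit_trend(y, tau, w)
        scaled = vf.fit_trend(2.5 * y - 1.0, tau, w)
        assert np.abs(scaled.fitted - (2.5 * base.fitted - 1.0)).max() < 1e-8

    def test_degenerate_pseudotime_raises(self):
        with pytest.raises(vf.ValidationError):
            vf.fit_trend(np.ones(10), np.ones(10), np.ones(10))


class TestTrendBand:
    def test_worked_three_point_example(self):
        # residuals (1, -1, 0) at tau (0, 1, 2), n = 3 test points,
        # evaluated at tau_p = 1 = tau_bar: sqrt(2) * sqrt(4/3) = sqrt(8/3)
        band = vf.trend_band(
            np.array([1.0, -1.0, 0.0]),
            np.array([0.0, 1.0, 2.0]),
            np.array([0.0, 1.0, 2.0]),
        )
        assert band[1] == pytest.approx(np.sqrt(8 / 3))
        assert band[1] == pytest.approx(1.6330, abs=1e-4)

    def test_zero_residuals_give_zero_band(self):
        band = vf.trend_band(
            np.zeros(5), np.linspace(0, 1, 5), np.linspace(0, 1, 7)
        )
        assert np.allclose(band, 0.0)

    def test_band_minimized_at_mean_pseudotime(self):
        tau = np.linspace(0, 1, 20)
        grid = np.linspace(0, 1, 101)
        band = vf.trend_band(np.ones(20), tau, grid)
        assert np.argmin(band) == 50
        assert np.allclose(band, band[::-1])

    def test_too_few_test_points_raise(self):
        with pytest.raises(vf.ValidationError):
            vf.trend_band(np.ones(3), np.arange(3.0), np.arange(2.0))


class TestTrendClustering:
    def test_two_planted_families_separated(self):
        Y, tau, labels, truth = vf.simulate_trend_families(
            n_genes_per_family=50, shapes=("linear", "peak"),
            noise_sd=0.05, seed=0,
        )
        # smooth each gene, then cluster the smoothed trends
        trends = np.vstack([
            vf.fit_trend(Y[:, g], tau, np.ones(len(tau))).fitted
            for g in range(Y.shape[1])
        ])
        pred, summaries = vf.cluster_trends(trends, resolution=0.2, seed=0)
        assert len(np.unique(pred)) == 2
        # cluster labels match planted families up to renaming
        agree = max(
            (pred == labels).mean(), (pred == 1 - labels).mean()
        )
        assert agree >= 0.95

    def test_identical_trends_collapse_to_one_cluster(self):
        T = np.tile(np.sin(np.linspace(0, 3, 200)), (10, 1))
        pred, _ = vf.cluster_trends(T, resolution=0.2, seed=0)
        assert len(np.unique(pred)) == 1

    def test_z_transform_inside_clustering(self, rng):
        T = rng.normal(size=(20, 50)) * 3 + 5
        mean = T.mean(axis=1, keepdims=True)
        sd = T.std(axis=1, keepdims=True)
        Z = (T - mean) / sd
        assert np.allclose(Z.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(Z.std(axis=1), 1)


class TestSmoothing:
    def test_zero_steps_is_identity(self, small_field):
        graph = vf.build_graph(small_field.expr, K=5, L=5)
        out = vf.smooth_expression(small_field.expr, graph, steps=0)
        assert out is small_field.expr

    def test_constant_gene_unchanged(self, small_field):
        graph = vf.build_graph(small_field.expr, K=5, L=5)
        expr = vf.ExpressionMatrix(
            values=np.ones_like(small_field.expr.values),
            cell_ids=small_field.expr.cell_ids,
            gene_ids=small_field.expr.gene_ids,
        )
        out = vf.smooth_expression(expr, graph, steps=3)
        assert np.allclose(out.values, 1.0)

    def test_smoothing_reduces_variance(self, rng, small_field):
        graph = vf.build_graph(small_field.expr, K=5, L=5)
        noisy = vf.ExpressionMatrix(
            values=rng.normal(size=small_field.expr.values.shape),
            cell_ids=small_field.expr.cell_ids,
            gene_ids=small_field.expr.gene_ids,
        )
        out = vf.smooth_expression(noisy, graph, steps=1)
        assert (out.values.var(axis=0) < noisy.values.var(axis=0)).all()
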