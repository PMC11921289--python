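import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from trifase.kernel import SpatialKernel, build_kernel
from trifase.model import (
    CoclusterModel,
    Indicator,
    count_nonempty,
    loss,
    penalized_loss,
    row_assignment_probabilities,
    update_centroids,
    update_cols_approx,
    update_cols_exact,
    update_cols_stochastic,
    update_rows_classification,
    update_rows_stochastic,
    update_tau,
)

from conftest import random_instance, whitened_loss_oracle


class TestIndicator:
    def test_dense_is_one_hot(self):
        ind = Indicator(np.array([2, 0, 1, 2]), 3)
        dense = ind.dense
        assert dense.shape == (4, 3)
        assert np.all(dense.sum(axis=1) == 1)
        assert set(np.unique(dense)) <= {0.0, 1.0}
        assert np.array_equal(Indicator.from_dense(dense).labels, ind.labels)

    def test_invalid_labels_rejected(self):
        with pytest.raises(ValueError):
            Indicator(np.array([0, 3]), 3)
        with pytest.raises(ValueError):
            Indicator(np.array([-1, 0]), 2)

    @pytest.mark.parametrize(
        "labels, C, expected",
        [(np.zeros(9, dtype=int), 5, 1), (np.arange(4), 4, 4), (np.array([1, 1, 3]), 8, 2)],
    )
    def test_count_nonempty(self, labels, C, expected):
        assert count_nonempty(Indicator(labels, C)) == expected

    def test_count_nonempty_matches_set_cardinality(self, rng):
        labels = rng.integers(0, 8, 20)
        assert count_nonempty(Indicator(labels, 8)) == len(set(labels.tolist()))


class TestLoss:
    def test_exact_factorization_gives_zero(self, rng):
        _, _, kernel, model = random_instance(rng)
        X = model.predicted()
        assert loss(X, model, kernel) == pytest.approx(0.0, abs=1e-18)

    def test_identity_kernel_reduces_to_frobenius(self, rng):
        X, _, _, model = random_instance(rng, spatial=False)
        kernel = SpatialKernel.identity(X.shape[1])
        plain = np.linalg.norm(X - model.predicted(), "fro") ** 2
        assert loss(X, model, kernel) == pytest.approx(plain, rel=1e-12)

    def test_whitened_form_agrees_with_trace_form(self, rng):
        for _ in range(10):
            X, _, kernel, model = random_instance(rng, n=6, p=8)
            residual = X - model.predicted()
            sigma = kernel.tau * kernel.correlation
            trace_form = float(np.trace(residual @ np.linalg.solve(sigma, residual.T)))
            assert loss(X, model, kernel) == pytest.approx(trace_form, rel=1e-8)

    def test_penalty_vanishes_for_identity_covariance(self, rng):
        X, _, _, model = random_instance(rng, spatial=False)
        kernel = SpatialKernel.identity(X.shape[1], tau=1.0)
        assert penalized_loss(X, model, kernel) == pytest.approx(loss(X, model, kernel))

    def test_penalty_closed_form_scalar_covariance(self, rng):
        X, _, _, model = random_instance(rng, n=2, p=3, spatial=False, tau=4.0)
        kernel = SpatialKernel.identity(3, tau=4.0)
        expected = loss(X, model, kernel) + 2 * np.log(4.0**3)
        assert penalized_loss(X, model, kernel) == pytest.approx(expected, rel=1e-12)


class TestCentroidUpdate:
    def test_identity_kernel_gives_block_means(self, rng):
        X, _, _, model = random_instance(rng, n=7, p=9, K=3, R=2, spatial=False)
        kernel = SpatialKernel.identity(9)
        mu = update_centroids(X, model.rows, model.cols, kernel)
        for k in range(3):
            for r in range(2):
                block = X[np.ix_(model.rows.labels == k, model.cols.labels == r)]
                if block.size:
                    assert mu[k, r] == pytest.approx(block.mean(), rel=1e-10)

    def test_single_cocluster_is_grand_mean(self, rng):
        X = rng.standard_normal((5, 6))
        rows, cols = Indicator(np.zeros(5, dtype=int), 1), Indicator(np.zeros(6, dtype=int), 1)
        mu = update_centroids(X, rows, cols, SpatialKernel.identity(6))
        assert mu[0, 0] == pytest.approx(X.mean(), rel=1e-12)

    def test_update_never_increases_loss_and_is_stationary(self, rng):
        X, _, kernel, model = random_instance(rng, n=6, p=7, K=2, R=2)
        before = loss(X, model, kernel)
        mu = update_centroids(X, model.rows, model.cols, kernel, prev=model.mu)
        updated = CoclusterModel(model.rows, model.cols, mu, model.tau, model.phi)
        after = loss(X, updated, kernel)
        assert after <= before + 1e-10
        # numeric gradient of the loss in mu vanishes at the update
        eps = 1e-6
        for k in range(2):
            for r in range(2):
                bumped = mu.copy()
                bumped[k, r] += eps
                up = loss(X, CoclusterModel(model.rows, model.cols, bumped, model.tau, model.phi), kernel)
                bumped[k, r] -= 2 * eps
                down = loss(X, CoclusterModel(model.rows, model.cols, bumped, model.tau, model.phi), kernel)
                assert (up - down) / (2 * eps) == pytest.approx(0.0, abs=1e-4)

    def test_empty_cluster_keeps_previous_centroid(self, rng):
        X = rng.standard_normal((5, 6))
        rows = Indicator(np.array([0, 0, 2, 2, 2]), 3)  # cluster 1 empty
        cols = Indicator(rng.integers(0, 2, 6), 2)
        prev = np.full((3, 2), 7.5)
        mu = update_centroids(X, rows, cols, SpatialKernel.identity(6), prev=prev)
        assert np.all(mu[1] == 7.5)
        assert not np.any(mu[[0, 2]] == 7.5)


class TestRowSteps:
    def test_single_cluster_assigns_everything(self, rng):
        X, _, kernel, model = random_instance(rng, K=1)
        out = update_rows_classification(X, model.mu[:1], model.cols, kernel)
        assert np.all(out.labels == 0)

    def test_matches_per_row_brute_force_of_full_loss(self, rng):
        for _ in range(5):
            X, _, kernel, model = random_instance(rng, n=5, p=6, K=3, R=2)
            out = update_rows_classification(X, model.mu, model.cols, kernel)
            for i in range(5):
                losses = []
                for k in range(3):
                    labels = out.labels.copy()
                    labels[i] = k
                    cand = CoclusterModel(Indicator(labels, 3), model.cols, model.mu, model.tau, model.phi)
                    losses.append(whitened_loss_oracle(X, cand, kernel))
                assert out.labels[i] == int(np.argmin(losses))

    def test_stochastic_step_is_deterministic_under_seed(self, rng):
        X, _, kernel, model = random_instance(rng, n=8, p=6, K=3, R=2)
        a = update_rows_stochastic(X, model.mu, model.cols, kernel, np.random.default_rng(5))
        b = update_rows_stochastic(X, model.mu, model.cols, kernel, np.random.default_rng(5))
        assert np.array_equal(a.labels, b.labels)

    def test_degenerate_softmax_picks_dominant_cluster(self, rng):
        # one centroid fits a row exactly, others are absurdly far
        p, K = 6, 3
        cols = Indicator(np.array([0, 0, 1, 1, 1, 0]), 2)
        mu = np.array([[0.5, -0.2], [500.0, 400.0], [-300.0, 250.0]])
        X = mu[np.zeros(4, dtype=int)][:, cols.labels]
        kernel = SpatialKernel.identity(p)
        out = update_rows_stochastic(X, mu, cols, kernel, np.random.default_rng(0))
        assert np.all(out.labels == 0)

    def test_probabilities_normalise_and_equal_criteria_draw_uniformly(self):
        # all centroids identical -> equal criteria -> empirical freqs ~ 1/3
        p, K, n = 4, 3, 10_000
        cols = Indicator(np.array([0, 1, 0, 1]), 2)
        mu = np.tile(np.array([[1.0, -1.0]]), (K, 1))
        rng = np.random.default_rng(11)
        X = rng.standard_normal((n, p))
        kernel = SpatialKernel.identity(p)
        probs = row_assignment_probabilities(X, mu, cols, kernel)
        assert np.allclose(probs.sum(axis=1), 1.0)
        assert np.allclose(probs, 1.0 / K)
        out = update_rows_stochastic(X, mu, cols, kernel, rng)
        freqs = np.bincount(out.labels, minlength=K) / n
        assert np.allclose(freqs, 1.0 / K, atol=0.02)


class TestColumnSteps:
    def test_single_column_cluster_is_unchanged(self, rng):
        X, _, kernel, model = random_instance(rng, R=1)
        out = update_cols_exact(X, model.rows, model.mu[:, :1], model.cols, kernel)
        assert np.all(out.labels == 0)

    def test_exact_sweep_matches_sequential_brute_force(self, rng):
        for spatial in (False, True):
            X, _, kernel, model = random_instance(rng, n=4, p=6, K=2, R=2, spatial=spatial)
            out = update_cols_exact(X, model.rows, model.mu, model.cols, kernel)
            labels = model.cols.labels.copy()
            for j in range(6):
                losses = []
                for r in range(2):
                    cand_labels = labels.copy()
                    cand_labels[j] = r
                    cand = CoclusterModel(model.rows, Indicator(cand_labels, 2), model.mu, model.tau, model.phi)
                    losses.append(whitened_loss_oracle(X, cand, kernel))
                labels[j] = int(np.argmin(losses))
            assert np.array_equal(out.labels, labels)

    def test_approx_assigns_exactly_fitting_column(self, rng):
        X, _, _, model = random_instance(rng, n=5, p=6, K=2, R=3)
        comp = model.mu[model.rows.labels]
        X[:, 2] = comp[:, 1]
        out = update_cols_approx(X, model.rows, model.mu)
        assert out.labels[2] == 1

    def test_approx_matches_per_column_brute_force(self, rng):
        X, _, _, model = random_instance(rng, n=6, p=5, K=2, R=3)
        out = update_cols_approx(X, model.rows, model.mu)
        comp = model.mu[model.rows.labels]
        for j in range(5):
            d = [np.sum((X[:, j] - comp[:, r]) ** 2) for r in range(3)]
            assert out.labels[j] == int(np.argmin(d))

    def test_exact_and_approx_agree_under_identity_kernel(self, rng):
        X, _, _, model = random_instance(rng, n=5, p=7, K=2, R=3, spatial=False)
        kernel = SpatialKernel.identity(7)
        exact = update_cols_exact(X, model.rows, model.mu, model.cols, kernel)
        approx = update_cols_approx(X, model.rows, model.mu)
        assert np.array_equal(exact.labels, approx.labels)

    def test_stochastic_degenerate_and_deterministic(self, rng):
        X, _, kernel, model = random_instance(rng, n=4, p=5, K=2, R=2)
        a = update_cols_stochastic(X, model.rows, model.mu, model.cols, kernel, np.random.default_rng(3))
        b = update_cols_stochastic(X, model.rows, model.mu, model.cols, kernel, np.random.default_rng(3))
        assert np.array_equal(a.labels, b.labels)
        # exact-fit data: the generating labels dominate the softmax
        X0 = model.predicted() * 50.0
        mu = model.mu * 50.0
        out = update_cols_stochastic(X0, model.rows, mu, model.cols, kernel, np.random.default_rng(4))
        assert np.array_equal(out.labels, model.cols.labels)

    def test_stochastic_uniform_when_all_candidates_tie(self):
        # identical centroid columns -> every relabelling gives the same loss
        n, p, R = 3, 40, 4
        rng = np.random.default_rng(9)
        rows = Indicator(np.zeros(n, dtype=int), 1)
        mu = np.tile(np.array([[0.7]]), (1, R))
        X = rng.standard_normal((n, p))
        cols = Indicator(rng.integers(0, R, p), R)
        kernel = SpatialKernel.identity(p)
        draws = []
        for s in range(250):
            out = update_cols_stochastic(X, rows, mu, cols, kernel, np.random.default_rng(s))
            draws.append(out.labels)
        freqs = np.bincount(np.concatenate(draws), minlength=R) / (250 * p)
        assert np.allclose(freqs, 1.0 / R, atol=0.02)


class TestTauUpdate:
    def test_zero_residual_clamps_with_warning(self, rng):
        _, _, kernel, model = random_instance(rng)
        X = model.predicted()
        with pytest.warns(RuntimeWarning, match="degenerate"):
            tau = update_tau(X, model.rows, model.mu, model.cols, kernel)
        assert tau == pytest.approx(1e-12)

    def test_scalar_case_returns_squared_residual(self):
        X = np.array([[3.0]])
        rows, cols = Indicator(np.array([0]), 1), Indicator(np.array([0]), 1)
        mu = np.array([[1.0]])
        tau = update_tau(X, rows, mu, cols, SpatialKernel.identity(1))
        assert tau == pytest.approx(4.0)

    def test_matches_grid_scan_of_penalized_loss(self, rng):
        for _ in range(5):
            X, _, kernel, model = random_instance(rng, n=5, p=6, K=2, R=2)
            tau_hat = update_tau(X, model.rows, model.mu, model.cols, kernel)

            def objective(log_tau):
                k = kernel.with_tau(np.exp(log_tau))
                return penalized_loss(X, model, k)

            res = minimize_scalar(objective, bounds=(np.log(tau_hat) - 3, np.log(tau_hat) + 3), method="bounded")
            assert tau_hat == pytest.approx(np.exp(res.x), rel=1e-4)
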