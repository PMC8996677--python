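"""Graphical lasso, density matching, partial correlations, bootstrap."""

import warnings

import numpy as np
import pytest

import oracles
from metconn import sice, synthetic


class TestSampleCovariance:
    def test_perfectly_correlated_columns(self):
        x = np.arange(10.0)
        X = np.column_stack([x, 2 * x + 1])
        S = sice.sample_covariance(X)
        assert S[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_standardized_unit_diagonal(self, rng):
        X = rng.normal(size=(50, 6)) * [1, 10, 0.1, 5, 2, 3]
        S = sice.sample_covariance(X)
        assert np.allclose(np.diag(S), 1.0, atol=1e-12)

    def test_independent_columns_small_offdiag(self, rng):
        n = 2000
        X = rng.normal(size=(n, 5))
        S = sice.sample_covariance(X)
        assert np.abs(S[np.triu_indices(5, 1)]).max() < 4 / np.sqrt(n)

    def test_zero_variance_column_rejected(self):
        X = np.column_stack([np.arange(5.0), np.ones(5)])
        with pytest.raises(ValueError, match="zero-variance"):
            sice.sample_covariance(X)


class TestGraphicalLasso:
    def test_lambda_zero_is_inverse(self, rng):
        X = rng.normal(size=(100, 6))
        S = sice.sample_covariance(X)
        pm = sice.graphical_lasso(S, 0.0)
        assert np.abs(pm.theta - np.linalg.inv(S)).max() < 1e-6

    def test_large_lambda_diagonal(self, rng):
        X = rng.normal(size=(40, 8))
        S = sice.sample_covariance(X)
        lam = np.abs(S - np.diag(np.diag(S))).max() + 0.01
        pm = sice.graphical_lasso(S, lam)
        assert pm.adjacency().sum() == 0

    @pytest.mark.parametrize(
        "s01,lam", [(0.6, 0.2), (0.6, 0.05), (-0.4, 0.1), (0.8, 0.3), (0.3, 0.35)]
    )
    def test_2x2_matches_brute_force_maximizer(self, s01, lam):
        S = np.array([[1.0, s01], [s01, 1.0]])
        pm = sice.graphical_lasso(S, lam, tol=1e-8, max_iter=500)
        theta_bf = oracles.glasso_2x2_bf([[1.0, s01], [s01, 1.0]], lam)
        assert np.abs(pm.theta - theta_bf).max() < 1e-4
        # and the solver's objective is no worse than the grid optimum
        obj_bf = sice._objective(S, theta_bf, lam)
        assert pm.objective >= obj_bf - 1e-5

    def test_every_return_passes_cholesky_and_kkt(self, rng):
        for _ in range(10):
            X = rng.normal(size=(60, 8))
            S = sice.sample_covariance(X)
            lam = rng.uniform(0.02, 0.4)
            pm = sice.graphical_lasso(S, lam, tol=1e-6)
            np.linalg.cholesky(pm.theta)  # raises if not SPD
            assert sice.kkt_residual(S, pm) < 1e-2

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            sice.graphical_lasso(np.array([[1.0, 0.5], [0.2, 1.0]]), 0.1)


class TestLambdaForDensity:
    def test_target_zero_empties_graph(self, rng):
        S = sice.sample_covariance(rng.normal(size=(30, 6)))
        lam = sice.lambda_for_density(S, 0.0)
        assert sice.graphical_lasso(S, lam).adjacency().sum() == 0

    def test_density_monotone_in_lambda(self):
        rng = np.random.default_rng(0)
        for _ in range(8):
            S = sice.sample_covariance(rng.normal(size=(40, 10)))
            lams = np.linspace(0.02, 0.6, 8)
            dens = [sice.graphical_lasso(S, l).density() for l in lams]
            assert all(a >= b - 1e-12 for a, b in zip(dens, dens[1:]))

    def test_planted_fixture_hits_target(self):
        spec = synthetic.make_sparse_precision(20, 0.1, 2, seed=1)
        X = synthetic.sample_suvr_matrix(spec, 400, seed=2)
        S = sice.sample_covariance(X)
        lam = sice.lambda_for_density(S, 0.10)
        d = sice.graphical_lasso(S, lam).density()
        assert 0.08 <= d <= 0.12


class TestAdjacencySeries:
    def test_identity_precision_estimates_empty(self):
        spec = synthetic.make_sparse_precision(10, 0.0, 0, seed=0)
        X = synthetic.sample_suvr_matrix(spec, 500, seed=1)
        S = sice.sample_covariance(X)
        # any noticeable penalty kills the (nearly zero) sample correlations
        pm = sice.graphical_lasso(S, 0.15)
        assert pm.adjacency().sum() == 0

    def test_support_f1_on_planted_network(self):
        spec = synthetic.make_sparse_precision(20, 0.1, 2, seed=3)
        X = synthetic.sample_suvr_matrix(spec, 400, seed=4)
        ser = sice.build_adjacency_series(X, [0.1])
        assert sice.support_f1(ser.adjacency[0], spec.support) >= 0.8

    def test_partial_correlation_sign_identity(self, rng):
        X = rng.normal(size=(80, 8))
        S = sice.sample_covariance(X)
        pm = sice.graphical_lasso(S, 0.05)
        W = pm.partial_correlations()
        off = ~np.eye(8, dtype=bool)
        active = off & (np.abs(pm.theta) > sice.ZERO_FLOOR)
        assert np.all(np.sign(W[active]) == -np.sign(pm.theta[active]))

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(100, 10))
        perm = rng.permutation(10)
        ser1 = sice.build_adjacency_series(X, [0.2])
        ser2 = sice.build_adjacency_series(X[:, perm], [0.2])
        assert np.array_equal(ser1.adjacency[0][np.ix_(perm, perm)], ser2.adjacency[0])
        assert np.allclose(
            ser1.weights[0][np.ix_(perm, perm)], ser2.weights[0], atol=1e-4
        )

    def test_support_recovery_improves_with_n(self):
        f1 = {n: [] for n in (100, 800)}
        for seed in range(10):
            spec = synthetic.make_sparse_precision(20, 0.1, 2, seed=seed)
            for n in f1:
                X = synthetic.sample_suvr_matrix(spec, n, seed=1000 + seed)
                ser = sice.build_adjacency_series(X, [0.1])
                f1[n].append(sice.support_f1(ser.adjacency[0], spec.support))
        assert np.mean(f1[800]) >= np.mean(f1[100])


class TestBootstrap:
    def _sample_pair(self, seed, n=60, p=10, density=0.15):
        spec = synthetic.make_sparse_precision(p, density, 1, seed=seed)
        Xa = synthetic.sample_suvr_matrix(spec, n, "A", seed=seed + 1)
        Xb = synthetic.sample_suvr_matrix(spec, n, "B", seed=seed + 2)
        return Xa, Xb

    def test_null_false_positive_rate(self):
        """Same generating network in both groups: few CIs exclude 0."""
        fracs = []
        for seed in range(3):
            Xa, Xb = self._sample_pair(seed)
            tab = sice.bootstrap_edges(Xa, Xb, density=0.15, B=200, seed=seed)
            fracs.append((tab.label != "ns").mean())
        assert np.mean(fracs) <= 0.07

    def test_deterministic_under_seed(self):
        Xa, Xb = self._sample_pair(7)
        t1 = sice.bootstrap_edges(Xa, Xb, density=0.15, B=100, seed=3)
        t2 = sice.bootstrap_edges(Xa, Xb, density=0.15, B=100, seed=3)
        assert t1.equals(t2)

    def test_group_size_floor(self):
        Xa, Xb = self._sample_pair(1, n=2)
        with pytest.raises(ValueError):
            sice.bootstrap_edges(Xa, Xb, density=0.15, B=100, seed=0)

    def test_planted_strengthened_edge_flagged(self):
        """A conditional dependency present only in group B (partial
        correlation ~ +0.3 on top of a shared sparse background) is labeled
        enhanced in >= 90% of seeds."""
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            p = 10
            base = synthetic.make_sparse_precision(p, 0.15, 0, seed=seed)
            theta_b = base.theta.copy()
            if theta_b[0, 1] == 0:
                theta_b[0, 1] = theta_b[1, 0] = -0.35
            w = np.linalg.eigvalsh(theta_b)[0]
            if w < synthetic.MIN_EIGENVALUE:
                theta_b[np.diag_indices(p)] += synthetic.MIN_EIGENVALUE - w + 0.05
            spec_b = synthetic.PrecisionSpec(p, theta_b, base.support | {(0, 1)}, (), seed)
            Xa = synthetic.sample_suvr_matrix(base, 200, "A", seed=seed)
            Xb = synthetic.sample_suvr_matrix(spec_b, 200, "B", seed=seed + 500)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                tab = sice.bootstrap_edges(Xa, Xb, density=0.4, B=200, seed=seed)
            row = tab[(tab.roi_i == 1) & (tab.roi_j == 2)].iloc[0]
            hits += row.label == "enhanced"
        assert hits >= 0.9 * n_seeds
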