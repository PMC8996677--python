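"""Order selection, whitening, Infomax recovery, thresholding, templates."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from metconn import ica, synthetic


def matched_abs_corr(recovered, truth):
    """Mean |correlation| after optimal component matching (Hungarian)."""
    k = truth.shape[0]
    C = np.zeros((k, recovered.shape[0]))
    for i in range(k):
        for j in range(recovered.shape[0]):
            C[i, j] = abs(np.corrcoef(truth[i], recovered[j])[0, 1])
    ri, ci = linear_sum_assignment(-C)
    return C[ri, ci].mean()


def _flat_data(dims, n_subjects, n_sources, noise_sd, seed):
    vols, mixing, maps, _ = synthetic.make_volume_dataset(
        dims, n_subjects, n_sources, noise_sd, seed
    )
    return np.stack([v.data.ravel() for v in vols]), mixing, maps


class TestOrderSelection:
    def test_noiseless_rank_two(self):
        X, _, _ = _flat_data((10, 10, 6), 10, 2, 0.0, seed=0)
        assert ica.estimate_n_components(X) == 2

    @pytest.mark.parametrize("seed", range(10))
    def test_three_sources_with_noise(self, seed):
        X, _, _ = _flat_data((12, 12, 8), 30, 3, 0.1, seed=seed)
        assert ica.estimate_n_components(X) == 3

    def test_pure_noise_small_order(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(20, 500))
            hits += ica.estimate_n_components(X) <= 2
        assert hits >= 8

    def test_degenerate_data_rejected(self):
        with pytest.raises(ValueError):
            ica.estimate_n_components(np.zeros((10, 50)))


class TestWhitening:
    def test_identity_covariance(self, rng):
        X = rng.normal(size=(12, 300))
        Y, _, _, _ = ica.pca_whiten(X, 5)
        C = Y @ Y.T / Y.shape[1]
        assert np.abs(C - np.eye(5)).max() < 1e-8

    def test_full_rank_reconstruction(self, rng):
        X = rng.normal(size=(8, 100))
        k = 7  # centering across subjects leaves rank n - 1
        Y, _, dewhiten, mu = ica.pca_whiten(X, k)
        assert np.abs(dewhiten @ Y + mu - X).max() < 1e-8

    def test_matches_svd_rank_k_reconstruction(self, rng):
        X = rng.normal(size=(10, 200))
        k = 4
        Y, _, dewhiten, mu = ica.pca_whiten(X, k)
        Xc = X - X.mean(axis=0, keepdims=True)
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        Xk = U[:, :k] @ np.diag(s[:k]) @ Vt[:k]
        assert np.abs(dewhiten @ Y - Xk).max() < 1e-8

    def test_k_too_large(self, rng):
        with pytest.raises(ValueError):
            ica.pca_whiten(rng.normal(size=(5, 50)), 6)


class TestInfomax:
    def test_noiseless_two_source_recovery(self):
        X, _, maps = _flat_data((10, 10, 6), 10, 2, 0.0, seed=1)
        res = ica.run_ica(X, n_components=2, seed=0)
        assert matched_abs_corr(res.maps, maps) >= 0.99

    def test_noisy_three_source_recovery(self):
        X, _, maps = _flat_data((12, 12, 8), 30, 3, 0.1, seed=2)
        res = ica.run_ica(X, n_components=3, seed=0)
        assert matched_abs_corr(res.maps, maps) >= 0.9

    def test_bit_identical_under_seed(self):
        X, _, _ = _flat_data((10, 10, 6), 12, 2, 0.05, seed=3)
        r1 = ica.run_ica(X, n_components=2, seed=4)
        r2 = ica.run_ica(X, n_components=2, seed=4)
        assert np.array_equal(r1.maps, r2.maps)
        assert np.array_equal(r1.mixing, r2.mixing)

    def test_mixing_times_maps_reconstructs_rank_k(self):
        X, _, _ = _flat_data((10, 10, 6), 10, 2, 0.0, seed=5)
        res = ica.run_ica(X, n_components=2, seed=0)
        Xc = X - X.mean(axis=0, keepdims=True)
        _, _, dewhiten, _ = ica.pca_whiten(X, 2)
        assert np.abs(res.mixing @ res.maps - Xc).max() < 1e-6

    def test_z_maps_standardized(self):
        X, _, _ = _flat_data((10, 10, 6), 12, 2, 0.05, seed=6)
        res = ica.run_ica(X, n_components=2, seed=0)
        assert np.abs(res.z_maps.mean(axis=1)).max() < 1e-6
        assert np.abs(res.z_maps.std(axis=1) - 1).max() < 1e-6

    def test_agrees_with_fastica_cross_check(self):
        # independent algorithm, same model: recovered subspaces must agree
        from sklearn.decomposition import FastICA

        X, _, maps = _flat_data((10, 10, 6), 12, 2, 0.01, seed=7)
        res = ica.run_ica(X, n_components=2, seed=0)
        Xc = X - X.mean(axis=0, keepdims=True)  # same centering as run_ica
        fi = FastICA(n_components=2, random_state=0, whiten="unit-variance")
        S_fast = fi.fit_transform(Xc.T).T
        assert matched_abs_corr(res.maps, S_fast) >= 0.98


class TestThreshold:
    def test_strict_positive_tail(self):
        mask = ica.threshold_z(np.array([1.0, 2.0, 2.5]))
        assert list(mask) == [False, True, True]

    def test_all_negative_empty(self):
        assert not ica.threshold_z(-np.abs(np.random.default_rng(0).normal(size=20))).any()

    def test_minus_inf_cut_all_true(self):
        assert ica.threshold_z(np.zeros(5), z_cut=-np.inf).all()

    def test_nested_in_cut(self, rng):
        z = rng.normal(size=200)
        loose, tight = ica.threshold_z(z, 1.0), ica.threshold_z(z, 2.5)
        assert not (tight & ~loose).any()


class TestTemplates:
    def test_exact_match_correlation_one(self):
        rng = np.random.default_rng(0)
        mask = rng.random(100) < 0.2
        z = (mask.astype(float) - mask.mean()) / mask.std()
        tset = ica.TemplateSet(masks={"dmn": mask})
        out = ica.match_templates(z[None, :], tset)
        assert out.loc[0, "component"] == 0
        assert out.loc[0, "correlation"] == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_blobs_correct_assignment(self):
        X, _, maps = _flat_data((10, 10, 6), 12, 2, 0.02, seed=8)
        res = ica.run_ica(X, n_components=2, seed=0)
        templates = ica.TemplateSet(
            masks={"net_a": maps[0] > 0.5, "net_b": maps[1] > 0.5}
        )
        out = ica.match_templates(res.z_maps, templates).set_index("template")
        assert out.loc["net_a", "component"] != out.loc["net_b", "component"]
        for name, truth in (("net_a", maps[0]), ("net_b", maps[1])):
            comp = int(out.loc[name, "component"])
            assert abs(np.corrcoef(np.abs(res.z_maps[comp]), truth)[0, 1]) > 0.7

    def test_tie_breaks_to_lowest_component(self):
        z = np.vstack([np.ones(10), np.ones(10)])
        z[:, :3] = 5.0  # identical maps -> identical correlations
        tset = ica.TemplateSet(masks={"t": np.arange(10) < 3})
        out = ica.match_templates(z, tset)
        assert out.loc[0, "component"] == 0

    def test_too_many_templates(self):
        with pytest.raises(ValueError):
            ica.match_templates(
                np.random.default_rng(0).normal(size=(1, 50)),
                ica.TemplateSet(masks={"a": np.ones(50, bool), "b": np.ones(50, bool)}),
            )


class TestCompareNetwork:
    def _groups(self, seed, strengthen=False):
        p = 12
        base = synthetic.make_sparse_precision(p, 0.15, 0, seed=seed)
        theta_b = base.theta.copy()
        support_b = set(base.support)
        if strengthen:
            theta_b[0, 1] = theta_b[1, 0] = -0.5
            support_b.add((0, 1))
            w = np.linalg.eigvalsh(theta_b)[0]
            if w < synthetic.MIN_EIGENVALUE:
                theta_b[np.diag_indices(p)] += synthetic.MIN_EIGENVALUE - w + 0.05
        spec_b = synthetic.PrecisionSpec(p, theta_b, support_b, (), seed)
        Xa = synthetic.sample_suvr_matrix(base, 60, "A", seed=seed)
        Xb = synthetic.sample_suvr_matrix(spec_b, 60, "B", seed=seed + 900)
        return Xa, Xb

    def test_null_few_flags(self):
        fracs = []
        for seed in range(3):
            Xa, Xb = self._groups(seed)
            edges, _ = ica.compare_network(
                Xa, Xb, network_rois=list(range(1, 7)), density=0.3,
                n_perm=200, seed=seed,
            )
            fracs.append((edges.label != "ns").mean())
        assert np.mean(fracs) <= 0.07

    def test_planted_strengthening_flagged_increased(self):
        hits = 0
        for seed in range(5):
            Xa, Xb = self._groups(seed, strengthen=True)
            edges, _ = ica.compare_network(
                Xa, Xb, network_rois=list(range(1, 7)), density=0.3,
                n_perm=200, seed=seed,
            )
            row = edges[(edges.roi_i == 1) & (edges.roi_j == 2)].iloc[0]
            hits += row.label == "increased"
        assert hits >= 4

    def test_deterministic_tables(self):
        Xa, Xb = self._groups(11)
        e1, n1 = ica.compare_network(Xa, Xb, list(range(1, 7)), n_perm=100, seed=2)
        e2, n2 = ica.compare_network(Xa, Xb, list(range(1, 7)), n_perm=100, seed=2)
        assert e1.equals(e2) and n1.equals(n2)

    def test_too_few_rois(self):
        Xa, Xb = self._groups(0)
        with pytest.raises(ValueError):
            ica.compare_network(Xa, Xb, network_rois=[1, 2], n_perm=100, seed=0)
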