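import numpy as np
import pytest
from scipy import ndimage

from radfit.fpca import FPCScores
from radfit.io import LabelVolume, SchemaError, ValidationError
from radfit.segment import (
    MRFConfig,
    baseline_cluster,
    kmeans_init,
    radfit_segment,
)


def _grid_scores(field, mask=None):
    """Pack a (nx,ny,nz,m) score field into FPCScores + mask."""
    if mask is None:
        mask = np.ones(field.shape[:3], dtype=bool)
    coords = np.argwhere(mask)
    return FPCScores(scores=field[mask], coords=coords), mask


def _two_block_field(shape=(8, 8, 4), gap=4.0, m=2, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    field = rng.normal(0, 1.0, size=shape + (m,)) * noise
    field[: shape[0] // 2] += 0.0
    field[shape[0] // 2:] += gap
    truth = np.zeros(shape, dtype=int)
    truth[shape[0] // 2:] = 1
    return field, truth


class TestKMeansInit:
    def test_separated_point_masses_partition_exactly(self):
        X = np.vstack([np.zeros((10, 2)), np.full((15, 2), 5.0)])
        s = FPCScores(scores=X, coords=np.argwhere(np.ones((25, 1, 1), bool)))
        lab, means, sds = kmeans_init(s, 2, seed=0)
        assert len(np.unique(lab[:10])) == 1 and len(np.unique(lab[10:])) == 1
        assert lab[0] != lab[-1]
        np.testing.assert_allclose(np.sort(means[:, 0]), [0.0, 5.0])
        np.testing.assert_allclose(sds, 0.0, atol=1e-12)

    def test_k_equals_n_gives_singletons(self):
        X = np.arange(5, dtype=float)[:, None] * 3
        s = FPCScores(scores=X, coords=np.argwhere(np.ones((5, 1, 1), bool)))
        lab, means, sds = kmeans_init(s, 5, seed=0)
        assert len(np.unique(lab)) == 5
        np.testing.assert_allclose(sds, 0.0, atol=1e-12)

    def test_k_above_distinct_vectors_rejected(self):
        X = np.zeros((6, 2))
        s = FPCScores(scores=X, coords=np.argwhere(np.ones((6, 1, 1), bool)))
        with pytest.raises(ValidationError):
            kmeans_init(s, 3)

    def test_reproducible_with_seed(self):
        rng = np.random.default_rng(1)
        X = rng.random((40, 3))
        s = FPCScores(scores=X, coords=np.argwhere(np.ones((40, 1, 1), bool)))
        a = kmeans_init(s, 3, seed=7)[0]
        b = kmeans_init(s, 3, seed=7)[0]
        np.testing.assert_array_equal(a, b)


class TestRadfitSegment:
    def test_noiseless_two_region_perfect(self):
        field, truth = _two_block_field(noise=0.0)
        scores, mask = _grid_scores(field)
        res = radfit_segment(scores, mask, MRFConfig(k=2, seed=0))
        pred = res.labels.labels - 1
        agree = max(np.mean(pred == truth), np.mean(pred == 1 - truth))
        assert agree == 1.0

    def test_spatial_prior_cleans_salt_and_pepper(self):
        # corrupting 5% of score vectors: beta=1 must mislabel strictly
        # fewer voxels than beta=0, summed over 10 seeds
        errs = {0.0: 0, 1.0: 0}
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            field, truth = _two_block_field(gap=3.0, noise=1.0, seed=seed)
            flat = field.reshape(-1, field.shape[-1])
            idx = rng.choice(flat.shape[0], size=int(0.05 * flat.shape[0]),
                             replace=False)
            flat[idx] = rng.normal(1.5, 3.0, size=(idx.size, field.shape[-1]))
            scores, mask = _grid_scores(field)
            for beta in errs:
                res = radfit_segment(scores, mask,
                                     MRFConfig(k=2, beta=beta, seed=0))
                pred = res.labels.labels - 1
                errs[beta] += min(np.sum(pred != truth),
                                  np.sum(pred != 1 - truth))
        assert errs[1.0] < errs[0.0]

    def test_energy_monotone_within_em_cycle(self):
        field, _ = _two_block_field(gap=2.0, noise=1.0, seed=3)
        scores, mask = _grid_scores(field)
        res = radfit_segment(scores, mask, MRFConfig(k=2, beta=1.0, seed=0))
        for trace in res.energy_trace:
            assert np.all(np.diff(trace) <= 1e-9)

    def test_permuting_init_labels_permutes_output(self):
        field, _ = _two_block_field(gap=3.0, noise=0.8, seed=4)
        scores, mask = _grid_scores(field)
        init = (field[..., 0] > 1.5).astype(int)[mask]
        cfg = MRFConfig(k=2, beta=1.0, seed=0)
        a = radfit_segment(scores, mask, cfg, init_labels=init)
        b = radfit_segment(scores, mask, cfg, init_labels=1 - init)
        np.testing.assert_array_equal(a.labels.labels, 3 - b.labels.labels)
        np.testing.assert_allclose(a.means, b.means[::-1], atol=1e-10)

    def test_large_beta_yields_connected_regions(self):
        field, truth = _two_block_field(gap=4.0, noise=0.0)
        scores, mask = _grid_scores(field)
        res = radfit_segment(scores, mask, MRFConfig(k=2, beta=5.0, seed=0))
        struct = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
        for lab in (1, 2):
            _, ncomp = ndimage.label(res.labels.labels == lab, structure=struct)
            assert ncomp == 1

    def test_counts_cover_mask(self):
        field, _ = _two_block_field(gap=1.0, noise=1.0, seed=5)
        scores, mask = _grid_scores(field)
        res = radfit_segment(scores, mask, MRFConfig(k=3, seed=1))
        assert res.counts.sum() == mask.sum()
        assert np.all(res.counts > 0)
        inside = res.labels.labels[mask]
        assert inside.min() >= 1 and inside.max() <= 3

    def test_score_mask_mismatch_rejected(self):
        field, _ = _two_block_field()
        scores, mask = _grid_scores(field)
        bad = mask.copy()
        bad[0, 0, 0] = False
        with pytest.raises(SchemaError):
            radfit_segment(scores, bad, MRFConfig(k=2))

    def test_config_validation(self):
        with pytest.raises(ValidationError):
            MRFConfig(k=1)
        with pytest.raises(ValidationError):
            MRFConfig(k=2, beta=-0.5)
        with pytest.raises(ValidationError):
            MRFConfig(k=2, tol=1.5)


class TestGMMEquivalence:
    """With beta = 0 the segmenter must match plain Gaussian-mixture EM."""

    @staticmethod
    def _gmm_em(X, init, k, n_iter, mode):
        """Independent textbook GMM-EM (no mixing weights, matching the
        emission model), returning argmax labels."""
        n, m = X.shape
        resp = np.zeros((n, k))
        resp[np.arange(n), init] = 1.0
        for _ in range(n_iter):
            w = resp.sum(axis=0)
            means = (resp.T @ X) / np.clip(w, 1e-12, None)[:, None]
            if mode == "tied":
                covs = np.zeros((m, m))
                for j in range(k):
                    d = X - means[j]
                    covs += (resp[:, j][:, None] * d).T @ d
                covs = covs / n + 1e-8 * np.trace(covs / n) / m * np.eye(m)
                covs = np.repeat(covs[None], k, axis=0)
            else:
                covs = np.empty((k, m, m))
                for j in range(k):
                    d = X - means[j]
                    c = (resp[:, j][:, None] * d).T @ d / max(w[j], 1e-12)
                    covs[j] = c + 1e-8 * max(np.trace(c) / m, 1e-12) * np.eye(m)
            logp = np.empty((n, k))
            for j in range(k):
                d = X - means[j]
                iS = np.linalg.inv(covs[j])
                _, ld = np.linalg.slogdet(covs[j])
                logp[:, j] = -0.5 * (np.einsum("ni,ij,nj->n", d, iS, d) + ld)
            logp -= logp.max(axis=1, keepdims=True)
            resp = np.exp(logp)
            resp /= resp.sum(axis=1, keepdims=True)
        return np.argmax(resp, axis=1)

    @pytest.mark.parametrize("mode", ["tied", "full"])
    def test_beta_zero_matches_gmm_em(self, mode):
        agree_total, n_total = 0, 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            shape = (10, 10, 2)
            centers = rng.normal(0, 3.0, size=(3, 2))
            assign = rng.integers(0, 3, size=200)
            X = centers[assign] + rng.normal(0, 1.0, size=(200, 2))
            coords = np.argwhere(np.ones(shape, bool))
            scores = FPCScores(scores=X, coords=coords)
            init = rng.integers(0, 3, size=200)
            cfg = MRFConfig(k=3, beta=0.0, em_iter=15, tol=1e-9,
                            covariance=mode, seed=0)
            res = radfit_segment(scores, np.ones(shape, bool), cfg,
                                 init_labels=init)
            ours = res.labels.labels[tuple(coords.T)] - 1
            ref = self._gmm_em(X, init, 3, res.iterations, mode)
            agree_total += int(np.sum(ours == ref))
            n_total += 200
        assert agree_total / n_total >= 0.95


class TestBaselines:
    def test_all_methods_agree_on_separated_clouds(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.1, (30, 2)),
                       rng.normal(8, 0.1, (30, 2))])
        coords = np.argwhere(np.ones((60, 1, 1), bool))
        s = FPCScores(scores=X, coords=coords)
        parts = []
        for method in ("kmeans", "hierarchical", "spectral"):
            lab = baseline_cluster(s, method, 2, seed=0,
                                   mask_shape=(60, 1, 1)).labels.ravel()
            part = lab == lab[0]
            parts.append(part if part[0] else ~part)
        assert np.array_equal(parts[0], parts[1])
        assert np.array_equal(parts[0], parts[2])

    def test_hierarchical_splits_hand_placed_points(self):
        X = np.array([0.0, 1.0, 2.0, 10.0, 11.0, 12.0])[:, None]
        coords = np.argwhere(np.ones((6, 1, 1), bool))
        lab = baseline_cluster(FPCScores(scores=X, coords=coords),
                               "hierarchical", 2,
                               mask_shape=(6, 1, 1)).labels.ravel()
        assert len(set(lab[:3])) == 1 and len(set(lab[3:])) == 1
        assert lab[0] != lab[3]

    def test_kmeans_reproducible(self):
        rng = np.random.default_rng(2)
        X = rng.random((50, 3))
        coords = np.argwhere(np.ones((50, 1, 1), bool))
        s = FPCScores(scores=X, coords=coords)
        a = baseline_cluster(s, "kmeans", 4, seed=3, mask_shape=(50, 1, 1))
        b = baseline_cluster(s, "kmeans", 4, seed=3, mask_shape=(50, 1, 1))
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_unknown_method_rejected(self):
        s = FPCScores(scores=np.zeros((4, 1)),
                      coords=np.argwhere(np.ones((4, 1, 1), bool)))
        with pytest.raises(ValidationError):
            baseline_cluster(s, "dbscan", 2)
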