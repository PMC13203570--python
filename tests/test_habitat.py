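"""Superpixel segmentation, descriptors, population embedding/clustering
and habitat-map construction."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score, silhouette_score

from habitatmsi.habitat import (
    HabitatModel,
    SuperpixelFeatures,
    SuperpixelMap,
    assign_habitats,
    build_habitat_map,
    choose_superpixel_count,
    evaluate_habitat_k,
    fit_habitat_model,
    select_habitat_k,
    slic_segment,
    superpixel_features,
)
from habitatmsi.preprocess import FusedImage, RegionMask


def fused_from(values, mask):
    return FusedImage(values=np.where(mask, np.asarray(values, float), 0.0))


class TestChooseCount:
    def test_clamped_to_lower_bound(self):
        assert choose_superpixel_count(10, 300) == 30

    def test_clamped_to_upper_bound(self):
        assert choose_superpixel_count(10**6, 300) == 100

    def test_mid_range_arithmetic(self):
        assert choose_superpixel_count(15000, 300) == 50

    def test_rejects_empty_roi(self):
        with pytest.raises(ValueError):
            choose_superpixel_count(0)


class TestSlic:
    def test_homogeneous_roi_near_equal_tiles(self):
        mask = np.zeros((24, 24, 24), dtype=bool)
        mask[3:21, 3:21, 3:21] = True
        fused = fused_from(np.ones((24, 24, 24)), mask)
        spm = slic_segment(fused, RegionMask(mask), 30)
        assert 15 <= spm.n_sp <= 45  # within +-50% of request
        _, counts = np.unique(spm.labels[mask], return_counts=True)
        assert counts.std() / counts.mean() < 0.5
        assert np.all(spm.labels[mask] > 0)
        assert np.all(spm.labels[~mask] == 0)

    def test_intensity_step_tracked(self):
        """Half/half two-intensity ROI with n_sp=2: the boundary between
        superpixels should follow the step."""
        mask = np.zeros((16, 12, 12), dtype=bool)
        mask[2:14, 2:10, 2:10] = True
        vals = np.zeros((16, 12, 12))
        vals[8:] = 5.0
        fused = fused_from(vals, mask)
        spm = slic_segment(fused, RegionMask(mask), 2)
        low = spm.labels[2:8, 2:10, 2:10].ravel()
        high = spm.labels[8:14, 2:10, 2:10].ravel()
        # dominant label on each side differs and covers >=90% of voxels
        la = np.bincount(low).argmax()
        lb = np.bincount(high).argmax()
        assert la != lb
        assert (low == la).mean() >= 0.9
        assert (high == lb).mean() >= 0.9

    def test_saturation_one_voxel_per_superpixel(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[1:3, 1:3, 1:3] = True
        fused = fused_from(np.random.default_rng(0).normal(size=(5, 5, 5)), mask)
        with pytest.warns(UserWarning, match="one voxel"):
            spm = slic_segment(fused, RegionMask(mask), 8)
        assert spm.n_sp == 8
        _, counts = np.unique(spm.labels[mask], return_counts=True)
        assert np.all(counts == 1)


class TestDescriptors:
    def test_constant_superpixel(self):
        mask = np.ones((2, 2, 2), dtype=bool)
        fused = fused_from(np.full((2, 2, 2), 3.5), mask)
        spm = SuperpixelMap(labels=np.ones((2, 2, 2), dtype=np.int32), n_sp=1)
        f = superpixel_features(fused, spm)
        np.testing.assert_allclose(
            f.matrix[0], [3.5, 0, 3.5, 3.5, 3.5, 0, 0, 0]
        )

    def test_two_value_superpixel_hand_stats(self):
        """Values {0,0,1,1}: mean .5, population SD .5, median .5,
        entropy 1 bit."""
        vals = np.array([0.0, 0.0, 1.0, 1.0]).reshape(4, 1, 1)
        spm = SuperpixelMap(
            labels=np.ones((4, 1, 1), dtype=np.int32), n_sp=1
        )
        f = superpixel_features(FusedImage(values=vals), spm)
        mean, sd, median, vmin, vmax, skew, kurt, ent = f.matrix[0]
        assert (mean, sd, median) == (0.5, 0.5, 0.5)
        assert (vmin, vmax) == (0.0, 1.0)
        assert ent == pytest.approx(1.0)

    def test_no_nans_and_one_row_per_superpixel(self, rng):
        mask = np.zeros((20, 20, 20), dtype=bool)
        mask[2:18, 2:18, 2:18] = True
        fused = fused_from(rng.normal(size=(20, 20, 20)), mask)
        spm = slic_segment(fused, RegionMask(mask), 20)
        f = superpixel_features(fused, spm)
        assert f.matrix.shape == (spm.n_sp, 8)
        assert np.all(np.isfinite(f.matrix))


def planted_blobs(k, n_per, d=8, scale=8.0, seed=0):
    rng = np.random.default_rng(seed)
    centers = rng.normal(scale=scale, size=(k, d))
    X = np.vstack([c + rng.normal(size=(n_per, d)) for c in centers])
    labels = np.repeat(np.arange(k), n_per)
    return SuperpixelFeatures(matrix=X), labels


class TestHabitatModel:
    def test_two_blob_silhouette(self):
        feats, _ = planted_blobs(2, 200, scale=10.0)
        model = fit_habitat_model(feats, k=2, seed=0)
        sil = silhouette_score(feats.matrix, model.train_labels)
        assert sil > 0.7

    def test_deterministic_for_fixed_seed(self):
        feats, _ = planted_blobs(3, 60)
        m1 = fit_habitat_model(feats, k=3, seed=5)
        m2 = fit_habitat_model(feats, k=3, seed=5)
        np.testing.assert_array_equal(m1.train_labels, m2.train_labels)
        np.testing.assert_allclose(m1.embedding, m2.embedding)

    def test_saturated_k_zero_within_ss(self):
        feats, _ = planted_blobs(2, 15)
        n = feats.matrix.shape[0]
        with pytest.warns(UserWarning, match="perplexity"):
            model = fit_habitat_model(feats, k=n, seed=0)
        assert len(np.unique(model.train_labels)) == n

    def test_perplexity_lowered_for_small_input(self):
        feats, _ = planted_blobs(2, 20)
        with pytest.warns(UserWarning, match="perplexity"):
            fit_habitat_model(feats, k=2, seed=0)

    def test_planted_six_blob_selection_and_recovery(self):
        """Six well-separated descriptor blobs: evaluate_habitat_k
        selects k=6 and the labels match the planted classes exactly."""
        feats, truth = planted_blobs(6, 120, scale=8.0, seed=1)
        model = fit_habitat_model(feats, k=6, seed=0)
        metrics, labels_by_k = evaluate_habitat_k(
            model.embedding, (4, 6, 8), seed=0
        )
        assert select_habitat_k(metrics) == 6
        assert adjusted_rand_score(truth, labels_by_k[6]) > 0.95


class TestAssign:
    def test_training_rows_keep_their_labels(self):
        feats, _ = planted_blobs(3, 60)
        model = fit_habitat_model(feats, k=3, seed=0)
        out = assign_habitats(model, feats)
        np.testing.assert_array_equal(out, model.train_labels)

    def test_midpoint_tie_goes_to_lower_label(self):
        train = SuperpixelFeatures(matrix=np.array([[0.0] * 8, [2.0] * 8]))
        model = HabitatModel(
            k=2,
            scaler_mean=np.zeros(8),
            scaler_sd=np.ones(8),
            embedding=np.zeros((2, 2)),
            centers=np.zeros((2, 2)),
            train_labels=np.array([2, 1], dtype=np.int32),
            train_features_std=train.matrix,
            random_seed=0,
        )
        new = SuperpixelFeatures(matrix=np.array([[1.0] * 8]))
        assert assign_habitats(model, new)[0] == 1  # tie -> lower label

    def test_dimension_mismatch_raises(self):
        feats, _ = planted_blobs(2, 40)
        model = fit_habitat_model(feats, k=2, seed=0)
        with pytest.raises(ValueError):
            assign_habitats(model, SuperpixelFeatures(matrix=np.zeros((1, 5))))


class TestBuildMap:
    def _spmap(self):
        labels = np.zeros((4, 4, 1), dtype=np.int32)
        labels[0:2, :, 0] = 1
        labels[2:4, 0:2, 0] = 2
        labels[2:4, 2:4, 0] = 3
        return SuperpixelMap(labels=labels, n_sp=3)

    def test_uniform_labels_give_uniform_map(self):
        hm = build_habitat_map(self._spmap(), np.array([1, 1, 1]), k=2)
        assert set(np.unique(hm.labels)) == {1}

    def test_volume_conservation(self):
        spm = self._spmap()
        hm = build_habitat_map(spm, np.array([2, 1, 2]), k=2)
        vol2 = (hm.labels == 2).sum()
        assert vol2 == (spm.labels == 1).sum() + (spm.labels == 3).sum()

    def test_permutation_equivariance(self):
        spm = self._spmap()
        a = build_habitat_map(spm, np.array([1, 2, 2]), k=2)
        b = build_habitat_map(spm, np.array([2, 1, 1]), k=2)
        swap = np.array([0, 2, 1])
        np.testing.assert_array_equal(swap[a.labels], b.labels)

    def test_missing_label_raises(self):
        with pytest.raises(ValueError):
            build_habitat_map(self._spmap(), np.array([1, 2]), k=2)


class TestEvaluateK:
    def test_ch_matches_brute_force_on_six_points(self):
        """CH = (between-SS/(k-1)) / (within-SS/(n-k)), checked against
        explicit sums on a 6-point 2D example."""
        emb = np.array(
            [[0, 0], [0, 1], [1, 0], [10, 10], [10, 11], [11, 10]],
            dtype=float,
        )
        labels = np.array([0, 0, 0, 1, 1, 1])
        grand = emb.mean(axis=0)
        ss_within = ss_between = 0.0
        for c in (0, 1):
            pts = emb[labels == c]
            mu = pts.mean(axis=0)
            ss_within += ((pts - mu) ** 2).sum()
            ss_between += len(pts) * ((mu - grand) ** 2).sum()
        expected = (ss_between / 1) / (ss_within / 4)
        from sklearn.metrics import calinski_harabasz_score

        assert calinski_harabasz_score(emb, labels) == pytest.approx(expected)
        metrics, labels_by_k = evaluate_habitat_k(emb, (2,), seed=0)
        assert metrics.loc[0, "ch_score"] == pytest.approx(expected)
        assert adjusted_rand_score(labels, labels_by_k[2]) == 1.0

    def test_selection_prefers_higher_silhouette_then_ch(self):
        t = pd.DataFrame(
            {"k": [4, 6, 8], "silhouette": [0.4, 0.6, 0.6], "ch_score": [9, 5, 7]}
        )
        assert select_habitat_k(t) == 8
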