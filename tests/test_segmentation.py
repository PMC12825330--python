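"""Pixel-classifier segmentation of the transduced volume."""

import numpy as np
import pytest
from scipy import ndimage

from helpers import flood_fill_component_sizes
from shellcount import (
    IntensityVolume,
    ProbabilityVolume,
    SparseAnnotation,
    VoxelGeometry,
    denoise,
    extract_features,
    segment_transduced,
    train_pixel_classifier,
)
from shellcount.segmentation import annotation_from_paint_volume


class TestDenoise:
    def test_constant_volume_unchanged(self, unit_geometry):
        vol = IntensityVolume(np.full((8, 8, 8), 42.0), unit_geometry)
        out = denoise(vol, gaussian_diameter_um=2.0)
        assert np.allclose(out.data, 42.0, atol=1e-4)

    def test_impulse_mass_preserved(self, unit_geometry):
        data = np.zeros((15, 15, 15), dtype=np.float32)
        data[7, 7, 7] = 1000.0
        out = denoise(IntensityVolume(data, unit_geometry), gaussian_diameter_um=2.0)
        assert out.data.sum() == pytest.approx(1000.0, rel=1e-3)
        assert out.data.max() < 1000.0

    def test_physical_sigma_conversion(self):
        # 0.829 µm diameter at spacings (z 0.25, xy 0.206) → sigmas ≈ (1.658, 2.012, 2.012)
        g = VoxelGeometry(dx=0.206, dy=0.206, dz=0.25)
        rng = np.random.default_rng(0)
        data = rng.random((12, 12, 12)).astype(np.float32)
        out = denoise(IntensityVolume(data, g), gaussian_diameter_um=0.829)
        expected = ndimage.gaussian_filter(data, sigma=(1.658, 2.0121, 2.0121))
        np.testing.assert_allclose(out.data, expected, atol=1e-4)

    def test_rejects_non_positive_diameter(self, unit_geometry):
        with pytest.raises(ValueError):
            denoise(IntensityVolume(np.zeros((4, 4, 4)), unit_geometry), 0.0)


class TestFeatures:
    def test_feature_count_is_three_per_scale(self, unit_geometry):
        vol = IntensityVolume(np.zeros((6, 6, 6)), unit_geometry)
        feats = extract_features(vol, scales_um=(1.0, 2.0))
        assert feats.shape == (6, 6, 6, 6)

    def test_constant_volume_has_flat_derivative_features(self, unit_geometry):
        vol = IntensityVolume(np.full((8, 8, 8), 5.0), unit_geometry)
        feats = extract_features(vol, scales_um=(1.0,))
        # float32 filtering leaves ~1e-3 residue on a value-5 background
        assert np.allclose(feats[..., 1], 0.0, atol=0.01)  # gradient magnitude
        assert np.allclose(feats[..., 2], 0.0, atol=0.01)  # Laplacian

    def test_gradient_peaks_at_bright_plane_faces(self, unit_geometry):
        data = np.zeros((9, 5, 5), dtype=np.float32)
        data[4] = 100.0
        feats = extract_features(IntensityVolume(data, unit_geometry), scales_um=(1.0,))
        grad = feats[:, 2, 2, 1]
        # steepest intensity change sits beside the plane, not on it or far away
        assert np.argmax(grad) in (3, 5)
        assert grad[3] > grad[0] and grad[5] > grad[8]

    def test_sub_voxel_scale_warns_and_clamps(self, unit_geometry):
        vol = IntensityVolume(np.zeros((6, 6, 6)), unit_geometry)
        with pytest.warns(UserWarning, match="clamping"):
            feats = extract_features(vol, scales_um=(0.1,))
        assert feats.shape[-1] == 3

    def test_requires_at_least_one_scale(self, unit_geometry):
        with pytest.raises(ValueError):
            extract_features(IntensityVolume(np.zeros((4, 4, 4)), unit_geometry), ())


def _two_intensity_volume(unit_geometry, lo=10.0, hi=200.0):
    data = np.full((8, 8, 8), lo, dtype=np.float32)
    data[:, :4, :] = hi
    vol = IntensityVolume(data, unit_geometry)
    pos = [(z, y, x) for z in range(8) for y in range(4) for x in range(0, 8, 2)]
    neg = [(z, y, x) for z in range(8) for y in range(4, 8) for x in range(0, 8, 2)]
    ann = SparseAnnotation(
        coordinates=np.array(pos + neg),
        labels=np.array([1] * len(pos) + [0] * len(neg)),
    )
    return vol, ann


class TestClassifier:
    def test_separable_volume_trains_to_perfect_accuracy(self, unit_geometry):
        vol, ann = _two_intensity_volume(unit_geometry)
        feats = extract_features(vol, scales_um=(1.0,))
        clf = train_pixel_classifier(feats, ann, seed=0)
        assert clf.training_accuracy == pytest.approx(1.0)

    def test_dim_and_bright_transduced_both_recovered(self, unit_geometry):
        # two transduced slabs of very different brightness over a dark background
        data = np.full((9, 9, 9), 20.0, dtype=np.float32)
        data[:, 0:3, :] = 80.0  # dim transduced
        data[:, 3:6, :] = 2000.0  # bright transduced
        vol = IntensityVolume(data, unit_geometry)
        pos = [(z, y, x) for z in range(9) for y in range(6) for x in range(0, 9, 2)]
        neg = [(z, y, x) for z in range(9) for y in range(6, 9) for x in range(0, 9, 2)]
        ann = SparseAnnotation(np.array(pos + neg), np.array([1] * len(pos) + [0] * len(neg)))
        feats = extract_features(vol, scales_um=(1.0,))
        clf = train_pixel_classifier(feats, ann, seed=0)
        probs = clf.predict_volume(feats)
        z, y, x = np.array(pos).T
        assert (probs[z, y, x] > 0.5).all()

    def test_uninformative_features_give_half_probability(self, unit_geometry):
        vol = IntensityVolume(np.full((8, 8, 8), 50.0, dtype=np.float32), unit_geometry)
        coords = [(z, y, x) for z in range(8) for y in range(8) for x in (0, 4)]
        labels = np.tile([1, 0], len(coords) // 2)
        ann = SparseAnnotation(np.array(coords), labels)
        feats = extract_features(vol, scales_um=(1.0,))
        clf = train_pixel_classifier(feats, ann, seed=0)
        probs = clf.predict_volume(feats)
        assert np.allclose(probs, 0.5, atol=0.15)

    def test_one_class_annotation_rejected(self, unit_geometry):
        vol, ann = _two_intensity_volume(unit_geometry)
        feats = extract_features(vol, scales_um=(1.0,))
        bad = SparseAnnotation(ann.coordinates[:20], np.ones(20, dtype=int))
        with pytest.raises(ValueError):
            train_pixel_classifier(feats, bad, seed=0)

    def test_same_seed_reproduces_probabilities(self, unit_geometry):
        vol, ann = _two_intensity_volume(unit_geometry)
        feats = extract_features(vol, scales_um=(1.0,))
        p1 = train_pixel_classifier(feats, ann, seed=7).predict_volume(feats)
        p2 = train_pixel_classifier(feats, ann, seed=7).predict_volume(feats)
        np.testing.assert_array_equal(p1, p2)

    def test_paint_volume_annotation(self, unit_geometry):
        paint = np.zeros((4, 4, 4), dtype=np.uint8)
        paint[0, 0, 0] = 2
        paint[1, 1, 1] = 1
        ann = annotation_from_paint_volume(paint, unit_geometry)
        assert len(ann.labels) == 2
        assert set(ann.labels) == {0, 1}


class TestSegmentTransduced:
    def test_zero_probability_gives_empty_mask(self, unit_geometry):
        prob = ProbabilityVolume(np.zeros((6, 6, 6)), unit_geometry)
        mask = segment_transduced(prob, unit_geometry)
        assert not mask.data.any()

    def test_small_object_removed_large_kept(self, unit_geometry):
        # one 5-voxel (5 µm³) and one 50-voxel (50 µm³) blob at unit voxels
        prob = np.zeros((10, 10, 10))
        prob[0, 0, :5] = 1.0
        prob[5:7, 2:7, 2:7] = 1.0
        mask = segment_transduced(ProbabilityVolume(prob, unit_geometry), unit_geometry)
        assert not mask.data[0, 0, :5].any()
        assert mask.data[5:7, 2:7, 2:7].all()

    def test_exactly_threshold_volume_removed(self, unit_geometry):
        # a blob of exactly 10 µm³ is *not* "larger than 10 µm³"
        prob = np.zeros((5, 5, 5))
        prob[1:3, 1:3, 1:3] = 1.0  # 8 voxels
        prob[1, 3, 1] = 1.0
        prob[1, 3, 2] = 1.0  # 10 voxels total, 26-connected
        mask = segment_transduced(
            ProbabilityVolume(prob, unit_geometry), unit_geometry, min_object_um3=10.0
        )
        assert not mask.data.any()
        # one voxel more and it survives
        prob[2, 3, 1] = 1.0
        mask = segment_transduced(
            ProbabilityVolume(prob, unit_geometry), unit_geometry, min_object_um3=10.0
        )
        assert mask.data.sum() == 11

    def test_boundary_probability_retained(self, unit_geometry):
        prob = np.full((3, 3, 3), 0.5)
        mask = segment_transduced(
            ProbabilityVolume(prob, unit_geometry), unit_geometry, min_object_um3=0.0
        )
        assert mask.data.all()  # "exclude probabilities lower than 50%": 0.5 stays

    def test_raising_threshold_never_adds_voxels(self, unit_geometry):
        rng = np.random.default_rng(5)
        prob = ProbabilityVolume(rng.random((12, 12, 12)), unit_geometry)
        prev = None
        for thr in (0.0, 0.25, 0.5, 0.75, 1.0):
            mask = segment_transduced(prob, unit_geometry, prob_threshold=thr,
                                      min_object_um3=0.0)
            if prev is not None:
                assert not (mask.data & ~prev).any()
            prev = mask.data

    def test_survivors_exceed_min_volume_by_independent_flood_fill(self, unit_geometry):
        rng = np.random.default_rng(9)
        prob = (rng.random((16, 16, 16)) > 0.7).astype(float)
        mask = segment_transduced(
            ProbabilityVolume(prob, unit_geometry), unit_geometry, min_object_um3=10.0
        )
        for size in flood_fill_component_sizes(mask.data):
            assert size * unit_geometry.voxel_volume > 10.0
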