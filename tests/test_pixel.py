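"""Structure-window features, training contract and pixel classification."""

import dataclasses

import numpy as np
import pytest
from shapely.geometry import box

from orbitlite.annotations import Annotation, AnnotationType, effective_roi
from orbitlite.image import build_pyramid
from orbitlite.pixel import (
    FeatureConfig,
    TrainingShape,
    assemble_training_set,
    classify_image,
    classify_region,
    edge_factor,
    feature_maps,
    load_model,
    point_features,
    region_features,
    save_model,
    train_pixel_classifier,
)
from orbitlite.synthetic import generate_scene

from conftest import two_region_spec


def edge_factor_bruteforce(img, s, y, x):
    """Independent per-pixel double-loop implementation of the edge factor
    (mirror boundary), used as oracle."""
    h, w = img.shape
    p = img[y, x]
    total, n = 0.0, 0
    for dy in range(-s, s + 1):
        for dx in range(-s, s + 1):
            yy, xx = y + dy, x + dx
            # mirror reflection without repeating the edge pixel
            if yy < 0:
                yy = -yy
            if yy >= h:
                yy = 2 * h - 2 - yy
            if xx < 0:
                xx = -xx
            if xx >= w:
                xx = 2 * w - 2 - xx
            total += (img[yy, xx] - p) ** 2
            n += 1
    return total / (n - 1)


class TestEdgeFactor:
    def test_constant_window_is_zero(self):
        assert edge_factor(np.full((5, 5), 0.7)) == 0.0

    def test_single_bright_centre(self):
        w = np.zeros((3, 3))
        w[1, 1] = 1.0
        assert edge_factor(w) == pytest.approx(8 * 1.0 / 8)  # = 1

    def test_shift_invariance(self, rng):
        w = rng.random((7, 7))
        assert edge_factor(w) == pytest.approx(edge_factor(w + 0.3), abs=1e-12)

    def test_tiny_window_rejected(self):
        with pytest.raises(ValueError):
            edge_factor(np.array([[1.0]]))

    def test_vectorized_matches_double_loop(self, rng):
        img = rng.random((32, 32))
        s = 3
        edge = feature_maps(img, s)[4]
        for y, x in [(0, 0), (5, 17), (31, 31), (16, 2)]:
            assert edge[y, x] == pytest.approx(
                edge_factor_bruteforce(img, s, y, x), abs=1e-9
            )


class TestFeatures:
    def test_constant_image_features(self):
        img = build_pyramid(np.full((64, 64), 100, np.uint8))
        X = point_features(img, [10, 40], [10, 40], FeatureConfig(structure_size=3))
        v = 100 / 255
        for row in X:
            mn, mx, mean, sd, edge, centre = row[:6]
            assert mn == mx == pytest.approx(v)
            assert mean == pytest.approx(v)
            assert centre == pytest.approx(v)
            assert sd == pytest.approx(0.0, abs=1e-9)
            assert edge == pytest.approx(0.0, abs=1e-9)

    def test_edge_feature_larger_on_step_edge(self):
        base = np.zeros((64, 64), np.uint8)
        base[:, 32:] = 200
        img = build_pyramid(base)
        cfg = FeatureConfig(structure_size=3, levels=(0,))
        X = point_features(img, [32, 10], [32, 32], cfg)
        assert X[0, 4] > X[1, 4]  # edge pixel vs flat region

    def test_identical_neighbourhoods_identical_vectors(self):
        yy, xx = np.mgrid[0:128, 0:128]
        base = (((yy // 8) + (xx // 8)) % 2 * 200).astype(np.uint8)
        img = build_pyramid(base)
        cfg = FeatureConfig(structure_size=2, levels=(0,))
        X = point_features(img, [40, 56], [40, 56], cfg)  # same phase in pattern
        np.testing.assert_allclose(X[0], X[1], atol=1e-12)

    def test_region_features_match_point_features(self, texture_scene):
        img, _ = texture_scene
        cfg = FeatureConfig(structure_size=4)
        R = region_features(img, 100, 200, 8, 6, cfg)
        yy, xx = np.mgrid[200:206, 100:108]
        P = point_features(img, xx.ravel(), yy.ravel(), cfg)
        np.testing.assert_allclose(R, P, atol=1e-12)

    def test_out_of_bounds_rejected(self, texture_scene):
        img, _ = texture_scene
        with pytest.raises(IndexError):
            region_features(img, img.width + 10, 0, 8, 8, FeatureConfig())


class TestTrainingSet:
    def test_under_cap_uses_all_pixels(self, texture_scene):
        img, _ = texture_scene
        shapes = [
            TrainingShape("A", box(10, 10, 40, 40)),
            TrainingShape("B", box(400, 10, 430, 40)),
        ]
        X, y, names = assemble_training_set(shapes, [img], FeatureConfig(), seed=0)
        assert len(X) == 2 * 31 * 31  # boundary-inclusive rasterization
        assert names == ("A", "B")

    def test_cap_applied_exactly(self, texture_scene):
        img, _ = texture_scene
        shapes = [
            TrainingShape("A", box(0, 0, 250, 250)),
            TrainingShape("B", box(350, 300, 600, 550)),
        ]
        X, y, _ = assemble_training_set(shapes, [img], FeatureConfig(), seed=1)
        assert len(X) == 40_000
        assert len(y) == 40_000

    def test_seed_reproducibility(self, texture_scene):
        img, _ = texture_scene
        shapes = [
            TrainingShape("A", box(0, 0, 250, 250)),
            TrainingShape("B", box(350, 300, 600, 550)),
        ]
        X1, y1, _ = assemble_training_set(shapes, [img], FeatureConfig(), seed=5)
        X2, y2, _ = assemble_training_set(shapes, [img], FeatureConfig(), seed=5)
        X3, y3, _ = assemble_training_set(shapes, [img], FeatureConfig(), seed=6)
        np.testing.assert_array_equal(X1, X2)
        np.testing.assert_array_equal(y1, y2)
        assert not np.array_equal(y1, y3) or not np.array_equal(X1, X3)
        # per-class support comparable across seeds (uniform sampling)
        s1 = np.bincount(y1) / len(y1)
        s3 = np.bincount(y3) / len(y3)
        np.testing.assert_allclose(s1, s3, atol=0.02)

    def test_empty_class_named_in_error(self, texture_scene):
        img, _ = texture_scene
        shapes = [
            TrainingShape("A", box(10, 10, 40, 40)),
            TrainingShape("ghost", box(-50, -50, -40, -40)),
        ]
        with pytest.raises(ValueError, match="ghost"):
            assemble_training_set(shapes, [img], FeatureConfig(), seed=0)


class TestTraining:
    def test_separable_classes_full_accuracy_no_warning(self, texture_model):
        assert texture_model.training_accuracy == 1.0
        assert not texture_model.low_accuracy_warning

    def test_confusable_classes_trigger_warning(self):
        # both classes drawn from the same texture distribution
        spec = two_region_spec(seed=300)
        spec.elements[1].mean = spec.elements[0].mean
        img, _ = generate_scene(spec)
        cfg = FeatureConfig(structure_size=3)
        shapes = [
            TrainingShape("A", box(20, 20, 120, 120)),
            TrainingShape("B", box(20, 200, 120, 300)),
        ]
        X, y, names = assemble_training_set(shapes, [img], cfg, seed=0)
        m = train_pixel_classifier(X, y, names, cfg, seed=0)
        assert m.training_accuracy < 0.7
        assert m.low_accuracy_warning

    @pytest.mark.parametrize("flips,expect_warn", [(8, True), (7, False)])
    def test_warning_threshold_at_085(self, flips, expect_warn):
        """50+50 1-D points with `flips` labels swapped on each side give a
        best linear training accuracy of exactly 1 - flips/50; the warning
        must fire below 0.85 and not at or above it."""
        x0 = np.concatenate([-np.ones(50 - flips), np.ones(flips)])
        x1 = np.concatenate([np.ones(50 - flips), -np.ones(flips)])
        X = np.concatenate([x0, x1])[:, None].astype(float)
        y = np.concatenate([np.zeros(50, int), np.ones(50, int)])
        m = train_pixel_classifier(X, y, ("a", "b"), FeatureConfig(), seed=0)
        assert m.training_accuracy == pytest.approx(1 - flips / 50)
        assert m.low_accuracy_warning is expect_warn

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).random((10, 3))
        with pytest.raises(ValueError):
            train_pixel_classifier(X, np.zeros(10, int), ("a",), FeatureConfig())

    def test_model_file_deterministic(self, texture_scene, tmp_path):
        img, _ = texture_scene
        cfg = FeatureConfig(structure_size=3)
        shapes = [
            TrainingShape("A", box(20, 20, 120, 120)),
            TrainingShape("B", box(420, 20, 520, 120)),
        ]

        def build(path):
            X, y, names = assemble_training_set(shapes, [img], cfg, seed=9)
            m = train_pixel_classifier(X, y, names, cfg, seed=9)
            save_model(m, path)

        p1, p2 = str(tmp_path / "m1.json"), str(tmp_path / "m2.json")
        build(p1)
        build(p2)
        assert open(p1).read() == open(p2).read()

    def test_save_load_roundtrip_predictions(self, texture_model, texture_scene, tmp_path):
        img, _ = texture_scene
        path = str(tmp_path / "m.json")
        save_model(texture_model, path)
        back = load_model(path)
        a = classify_region(texture_model, img, 100, 100, 32, 32)
        b = classify_region(back, img, 100, 100, 32, 32)
        np.testing.assert_array_equal(a, b)


class TestClassifyImage:
    def test_area_ratio_recovery(self, texture_scene, texture_model):
        img, gt = texture_scene
        res = classify_image(texture_model, img)
        areas = np.array([r["area"] for r in gt.records["regions"]], float)
        np.testing.assert_allclose(res.ratios, areas / areas.sum(), atol=0.02)

    def test_roi_restricted_to_one_region(self, texture_scene, texture_model):
        img, _ = texture_scene
        pred = effective_roi(
            [Annotation("r", AnnotationType.ROI, box(0, 0, 300, 600))]
        )
        res = classify_image(texture_model, img, roi=pred)
        assert res.ratios[0] >= 0.98  # region A only

    def test_tile_size_invariance(self, texture_scene, texture_model):
        img, _ = texture_scene
        res512 = classify_image(texture_model, img)
        res128 = classify_image(
            texture_model, dataclasses.replace(img, tile_size=128)
        )
        np.testing.assert_array_equal(res512.counts, res128.counts)

    def test_included_ratio_recipe(self, texture_scene, texture_model):
        img, _ = texture_scene
        m = dataclasses.replace(texture_model, include_flags=(True, False))
        res = classify_image(m, img)
        inc = res.included_ratios
        assert set(inc) == {"A"}
        assert inc["A"] == 1.0  # only included class -> ratio of included total
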