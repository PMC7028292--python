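"""Tile-mask training pairs, translation-union refinement, Dice evaluation."""

import numpy as np
import pytest
from shapely.geometry import LineString, box

from orbitlite.annotations import Annotation, AnnotationType, effective_roi, rasterize_polygon
from orbitlite.image import build_pyramid
from orbitlite.maskrefine import (
    SimulatedPredictor,
    ThresholdPredictor,
    deduplicate_objects,
    dice_object_index,
    dl_segment,
    generate_training_masks,
    predict_image_mask,
    predict_refined_mask,
    recenter_refine,
)
from orbitlite.objects import SegmentedObject, segment_bitmap
from orbitlite.synthetic import CompositeFieldSpec, SceneSpec, generate_scene


def obj_from(ys, xs, oid=0):
    return SegmentedObject(id=oid, ys=np.asarray(ys), xs=np.asarray(xs))


def objects_from_labels(labels):
    out = []
    for i, v in enumerate(np.unique(labels)):
        if v == 0:
            continue
        ys, xs = np.nonzero(labels == v)
        out.append(obj_from(ys, xs, i))
    return out


def disc_obj(cy, cx, r, oid=0):
    yy, xx = np.mgrid[cy - r : cy + r + 1, cx - r : cx + r + 1]
    sel = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    return obj_from(yy[sel], xx[sel], oid)


@pytest.fixture(scope="module")
def composite_scene():
    spec = SceneSpec(
        width=1024, height=1024, seed=700,
        elements=[CompositeFieldSpec(n=14, n_border=5, border_tile_size=512)],
    )
    return generate_scene(spec)


class TestTrainingMasks:
    def test_mask_area_matches_rasterization(self):
        img = build_pyramid(np.zeros((1024, 1024), np.uint8))
        sq = box(100, 120, 180, 220)
        pairs = generate_training_masks(
            img, [Annotation("o", AnnotationType.PLAIN, sq)]
        )
        assert len(pairs) == 4
        total = sum(mask.sum() for _, mask in pairs)
        assert total == rasterize_polygon(sq, 1024, 1024).sum()

    def test_annotation_outside_roi_skipped(self):
        img = build_pyramid(np.zeros((1024, 1024), np.uint8))
        roi = effective_roi(
            [Annotation("r", AnnotationType.ROI, box(0, 0, 500, 500))]
        )
        pairs = generate_training_masks(
            img,
            [Annotation("o", AnnotationType.PLAIN, box(600, 600, 700, 700))],
            roi=roi,
        )
        assert len(pairs) == 1  # only tile (0,0) intersects the ROI
        assert pairs[0][1].sum() == 0

    def test_augmentation_triples_and_rotates(self):
        img = build_pyramid(np.zeros((512, 512), np.uint8))
        sq = box(10, 10, 60, 60)  # top-left corner square
        pairs = generate_training_masks(
            img, [Annotation("o", AnnotationType.PLAIN, sq)], augment=True
        )
        assert len(pairs) == 3
        m0, m90, m180 = (p[1] for p in pairs)
        np.testing.assert_array_equal(m90, np.rot90(m0))
        np.testing.assert_array_equal(m180, np.rot90(m0, 2))
        assert m0[:70, :70].any() and m180[-70:, -70:].any()

    def test_open_polygon_rejected(self):
        img = build_pyramid(np.zeros((512, 512), np.uint8))
        line = Annotation("l", AnnotationType.JUNCTION_LINE,
                          LineString([(0, 0), (10, 10)]))
        with pytest.raises(ValueError):
            generate_training_masks(img, [line])


class TestSimulatedPredictor:
    def test_central_object_emitted_border_object_missed(self, composite_scene):
        img, gt = composite_scene
        labels = gt.labels["objects"]
        pred = SimulatedPredictor(labels, centre_margin=64)
        central = next(r for r in gt.records["objects"]
                       if not r["straddles_border"])
        border = next(r for r in gt.records["objects"] if r["straddles_border"])
        for rec, expect in ((central, True), (border, False)):
            cx, cy = rec["centre"]
            # tile of the standard 512 grid containing the centre
            x0, y0 = int(cx // 512) * 512, int(cy // 512) * 512
            tile = img.read_region(0, x0, y0, 512, 512)
            mask = pred.predict(tile, (x0, y0))
            hit = mask[int(cy) - y0, int(cx) - x0] if (
                0 <= int(cy) - y0 < 512 and 0 <= int(cx) - x0 < 512
            ) else False
            assert bool(hit) == expect

    def test_zero_false_positive_rate(self, composite_scene):
        img, gt = composite_scene
        pred = SimulatedPredictor(gt.labels["objects"], centre_margin=64)
        mask = predict_image_mask(pred, img, refined=True)
        assert not mask[gt.labels["objects"] == 0].any()


class TestRefinedMask:
    def test_central_object_refined_equals_plain(self, composite_scene):
        img, gt = composite_scene
        pred = SimulatedPredictor(gt.labels["objects"], centre_margin=64)
        rec = next(r for r in gt.records["objects"] if not r["straddles_border"])
        cx, cy = rec["centre"]
        x0, y0 = int(cx // 512) * 512, int(cy // 512) * 512
        plain = pred.predict(img.read_region(0, x0, y0, 512, 512), (x0, y0))
        refined = predict_refined_mask(pred, img, (x0, y0))
        assert (plain & ~refined).sum() == 0  # refined contains plain
        lab = gt.labels["objects"]
        win = lab[y0 : y0 + 512, x0 : x0 + 512]
        assert (refined & (win == rec["label"])).sum() == plain[
            win == rec["label"]
        ].sum()

    def test_border_object_recovered_by_shifts(self, composite_scene):
        img, gt = composite_scene
        labels = gt.labels["objects"]
        pred = SimulatedPredictor(labels, centre_margin=64)
        rec = next(r for r in gt.records["objects"] if r["straddles_border"])
        cx, cy = rec["centre"]
        x0, y0 = int(cx // 512) * 512, int(cy // 512) * 512
        plain = pred.predict(img.read_region(0, x0, y0, 512, 512), (x0, y0))
        refined = predict_refined_mask(pred, img, (x0, y0))
        win = labels[y0 : y0 + 512, x0 : x0 + 512]
        inside = win == rec["label"]
        assert plain[inside].sum() == 0          # identity prediction misses it
        assert refined[inside].all()             # shifts recover it
        assert (plain & ~refined).sum() == 0     # dominance

    def test_background_tile_stays_empty(self):
        img = build_pyramid(np.zeros((512, 512), np.uint8))
        pred = SimulatedPredictor(np.zeros((512, 512), np.int32))
        assert predict_refined_mask(pred, img, (0, 0)).sum() == 0

    def test_size_mismatch_contract_error(self):
        img = build_pyramid(np.zeros((512, 512), np.uint8))

        class Bad:
            def predict(self, tile, origin):
                return np.zeros((100, 100), bool)

        with pytest.raises(ValueError):
            predict_refined_mask(Bad(), img, (0, 0))


class TestRecenterRefine:
    def test_partial_border_object_completed(self, composite_scene):
        img, gt = composite_scene
        labels = gt.labels["objects"]
        pred = SimulatedPredictor(labels, centre_margin=64)
        rec = next(r for r in gt.records["objects"] if r["straddles_border"])
        ys, xs = np.nonzero(labels == rec["label"])
        # simulate a half detection: left half of the object only
        half = xs <= np.median(xs)
        partial = obj_from(ys[half], xs[half])
        refined = recenter_refine(pred, partial, img)
        assert refined.area == len(ys)
        assert refined.pixel_set() == set(zip(ys.tolist(), xs.tolist()))

    def test_complete_object_unchanged(self, composite_scene):
        img, gt = composite_scene
        labels = gt.labels["objects"]
        pred = SimulatedPredictor(labels, centre_margin=64)
        rec = next(r for r in gt.records["objects"] if not r["straddles_border"])
        ys, xs = np.nonzero(labels == rec["label"])
        full = obj_from(ys, xs)
        refined = recenter_refine(pred, full, img)
        assert refined.pixel_set() == full.pixel_set()

    def test_oversized_object_kept(self, composite_scene):
        img, _ = composite_scene
        ys, xs = np.mgrid[0:600, 100:102]
        big = obj_from(ys.ravel(), xs.ravel())
        pred = SimulatedPredictor(np.zeros((1024, 1024), np.int32))
        assert recenter_refine(pred, big, img) is big


class TestDeduplication:
    def test_exact_duplicate_removed(self):
        a = disc_obj(50, 50, 10, 0)
        b = disc_obj(50, 50, 10, 1)
        assert len(deduplicate_objects([a, b])) == 1

    def test_partial_inside_full_removed(self):
        full = disc_obj(50, 50, 12, 0)
        pix = sorted(full.pixel_set())[:100]
        part = obj_from([p[0] for p in pix], [p[1] for p in pix], 1)
        kept = deduplicate_objects([part, full])
        assert [o.id for o in kept] == [0]

    def test_low_overlap_pair_kept_allpairs_oracle(self):
        a = disc_obj(50, 50, 10, 0)
        b = disc_obj(50, 62, 10, 1)  # ~30% overlap
        kept = deduplicate_objects([a, b])
        assert len(kept) == 2
        # oracle: no pair in the result exceeds the coverage threshold
        for i, o1 in enumerate(kept):
            for o2 in kept[i + 1 :]:
                p1, p2 = o1.pixel_set(), o2.pixel_set()
                assert len(p1 & p2) / len(p2) < 0.9
                assert len(p1 & p2) / len(p1) < 0.9

    def test_idempotent(self):
        objs = [disc_obj(50, 50, 10, 0), disc_obj(50, 50, 8, 1),
                disc_obj(120, 120, 9, 2)]
        once = deduplicate_objects(objs)
        twice = deduplicate_objects(once)
        assert [o.id for o in once] == [o.id for o in twice]


def dice_oracle(G, S):
    """Brute-force all-pairs reference for the weighted Dice object index."""
    if not G and not S:
        return 1.0
    if not G or not S:
        return 0.0
    gm = [o.pixel_set() for o in G]
    sm = [o.pixel_set() for o in S]

    def best(p, others):
        ov = [len(p & q) for q in others]
        return int(np.argmax(ov)) if max(ov) > 0 else None

    def dice(a, b):
        return 2 * len(a & b) / (len(a) + len(b))

    gt_total = sum(len(p) for p in gm)
    st_total = sum(len(p) for p in sm)
    s1 = sum(
        (len(p) / gt_total) * (dice(p, sm[best(p, sm)]) if best(p, sm) is not None else 0.0)
        for p in gm
    )
    s2 = sum(
        (len(p) / st_total) * (dice(p, gm[best(p, gm)]) if best(p, gm) is not None else 0.0)
        for p in sm
    )
    return 0.5 * (s1 + s2)


class TestDiceObjectIndex:
    def test_identity_is_one(self):
        G = [disc_obj(40, 40, 8, 0), disc_obj(90, 90, 12, 1)]
        S = [disc_obj(40, 40, 8, 0), disc_obj(90, 90, 12, 1)]
        assert dice_object_index(G, S).index == pytest.approx(1.0)

    def test_disjoint_is_zero(self):
        G = [disc_obj(40, 40, 8, 0)]
        S = [disc_obj(120, 120, 8, 0)]
        assert dice_object_index(G, S).index == pytest.approx(0.0)

    def test_half_overlap_single_pair(self):
        G = [obj_from(np.repeat(np.arange(10), 10), np.tile(np.arange(10), 10))]
        S = [obj_from(np.repeat(np.arange(10), 10), np.tile(np.arange(5, 15), 10))]
        assert dice_object_index(G, S).index == pytest.approx(0.5)

    def test_empty_conventions(self):
        assert dice_object_index([], []).index == 1.0
        assert dice_object_index([disc_obj(10, 10, 3, 0)], []).index == 0.0
        assert dice_object_index([], [disc_obj(10, 10, 3, 0)]).index == 0.0

    def test_symmetry(self, rng):
        G = [disc_obj(40 + 30 * i, 40, int(rng.integers(4, 10)), i) for i in range(4)]
        S = [disc_obj(42 + 30 * i, 43, int(rng.integers(4, 10)), i) for i in range(4)]
        assert dice_object_index(G, S).index == pytest.approx(
            dice_object_index(S, G).index
        )

    def test_matches_bruteforce_on_random_sets(self, rng):
        for _ in range(5):
            G = [
                disc_obj(int(rng.integers(20, 200)), int(rng.integers(20, 200)),
                         int(rng.integers(4, 14)), i)
                for i in range(6)
            ]
            S = [
                disc_obj(int(rng.integers(20, 200)), int(rng.integers(20, 200)),
                         int(rng.integers(4, 14)), i)
                for i in range(7)
            ]
            assert dice_object_index(G, S).index == pytest.approx(
                dice_oracle(G, S), abs=1e-12
            )


class TestPipeline:
    def test_refined_beats_unrefined(self, composite_scene):
        img, gt = composite_scene
        labels = gt.labels["objects"]
        gt_objs = objects_from_labels(labels)
        pred = SimulatedPredictor(labels, centre_margin=64)
        refined = dice_object_index(gt_objs, dl_segment(pred, img, refine=True))
        unrefined = dice_object_index(gt_objs, dl_segment(pred, img, refine=False))
        assert refined.index >= 0.95
        assert unrefined.index < refined.index

    def test_threshold_predictor_smoke(self):
        base = np.full((512, 512), 20, np.uint8)
        yy, xx = np.mgrid[0:512, 0:512]
        base[(yy - 200) ** 2 + (xx - 300) ** 2 <= 400] = 220
        img = build_pyramid(base)
        objs = dl_segment(ThresholdPredictor(0.5), img, recenter=False)
        assert len(objs) == 1
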