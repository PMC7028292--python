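"""Tile-mask machinery around a pluggable segmentation predictor.

A *tile-mask predictor* maps a 512x512 tile raster to a binary
object/background mask.  In production that predictor would be a trained
encoder-decoder CNN; here it is a contract with two shipped adapters:

* :class:`SimulatedPredictor` — a synthetic stand-in driven by ground-truth
  labels.  It emits an object's pixels only when the object lies entirely
  inside the tile's central window (margin ``m`` from the tile border),
  reproducing the characteristic failure mode of tile-wise CNN inference:
  objects at the tile centre are detected well, objects near or across the
  tile border only partially or not at all, while the false-positive rate
  stays at zero.
* :class:`ThresholdPredictor` — a plain intensity threshold, for smoke
  tests with no ground truth.

Around the contract this module provides: training-pair generation (tile
rasters with annotation-rasterized masks, optionally augmented with 90/180
degree rotations), translation-union refinement (predict under half-tile
shifts and union the inverse-shifted masks), re-centred refinement (re-run
the predictor on a virtual tile centred on each detected object),
covering-based deduplication, and the object-size-weighted Dice object
index for evaluation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon

from .annotations import Annotation, RegionPredicate, rasterize_polygon
from .image import TiledImage
from .objects import SegmentationParams, SegmentedObject, segment_bitmap

logger = logging.getLogger(__name__)

__all__ = [
    "SimulatedPredictor",
    "ThresholdPredictor",
    "generate_training_masks",
    "predict_refined_mask",
    "predict_image_mask",
    "recenter_refine",
    "deduplicate_objects",
    "dice_object_index",
    "DiceReport",
    "dl_segment",
    "DEFAULT_TRANSLATIONS",
]

TILE = 512
# identity + half-tile shifts up, down, left, right
DEFAULT_TRANSLATIONS = ((0, 0), (0, -TILE // 2), (0, TILE // 2),
                        (-TILE // 2, 0), (TILE // 2, 0))

# DL tile masks are already clean object/background maps: no morphology,
# watershed off, tiny specks dropped
DL_SEGMENTATION_PARAMS = SegmentationParams(
    erosion_iterations=0, dilation_iterations=0, use_watershed=False, min_area=10
)


@dataclass
class SimulatedPredictor:
    """Ground-truth-driven stand-in for a CNN tile-mask predictor.

    ``predict`` emits the pixels of every ground-truth object whose full
    extent lies inside the tile's central ``(tile_size - 2*margin)^2``
    window; objects close to or across the tile border are omitted
    entirely.  Output is a pure function of the tile position.
    """

    labels: np.ndarray            # ground-truth label image, level-0 frame
    centre_margin: int = 64
    tile_size: int = TILE
    _bboxes: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for v in np.unique(self.labels):
            if v == 0:
                continue
            ys, xs = np.nonzero(self.labels == v)
            self._bboxes[int(v)] = (
                int(xs.min()), int(ys.min()), int(xs.max()) + 1, int(ys.max()) + 1
            )

    def predict(self, tile: np.ndarray, origin: tuple[int, int]) -> np.ndarray:
        t = self.tile_size
        if tile.shape[0] != t or tile.shape[1] != t:
            raise ValueError(f"predictor expects {t}x{t} tiles, got {tile.shape}")
        x0, y0 = origin
        m = self.centre_margin
        out = np.zeros((t, t), dtype=bool)
        h, w = self.labels.shape
        ix0, iy0 = max(0, x0), max(0, y0)
        ix1, iy1 = min(w, x0 + t), min(h, y0 + t)
        if ix0 >= ix1 or iy0 >= iy1:
            return out
        window = self.labels[iy0:iy1, ix0:ix1]
        for v in np.unique(window):
            if v == 0:
                continue
            bx0, by0, bx1, by1 = self._bboxes[int(v)]
            if (
                bx0 >= x0 + m and by0 >= y0 + m
                and bx1 <= x0 + t - m and by1 <= y0 + t - m
            ):
                out[iy0 - y0 : iy1 - y0, ix0 - x0 : ix1 - x0] |= window == v
        return out


@dataclass
class ThresholdPredictor:
    """Brightness threshold as a trivial predictor (smoke tests)."""

    threshold: float = 0.5
    channel: int = 0
    tile_size: int = TILE

    def predict(self, tile: np.ndarray, origin: tuple[int, int]) -> np.ndarray:
        return tile[:, :, self.channel] > self.threshold


# --------------------------------------------------------------------------- #
# training-pair generation


def generate_training_masks(
    image: TiledImage,
    object_annotations: list[Annotation],
    roi: RegionPredicate | None = None,
    augment: bool = False,
    tile_size: int = TILE,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """(tile raster, binary mask) pairs for every tile intersecting the ROI.

    Annotation polygons are rasterized into a mask aligned with each tile;
    with ``augment`` each pair is additionally emitted rotated by 90 and
    180 degrees, tripling the set.
    """
    geoms = []
    for a in object_annotations:
        if not isinstance(a.geometry, Polygon):
            raise ValueError(
                f"annotation {a.name!r} is not a closed polygon"
            )
        geoms.append(a.geometry)
    pairs = []
    ntx = -(-image.width // tile_size)
    nty = -(-image.height // tile_size)
    for ty in range(nty):
        for tx in range(ntx):
            x0, y0 = tx * tile_size, ty * tile_size
            if roi is not None and not roi.intersects_bbox(
                x0, y0, x0 + tile_size, y0 + tile_size
            ):
                continue
            raster = image.read_region(0, x0, y0, tile_size, tile_size)
            mask = np.zeros((tile_size, tile_size), dtype=bool)
            for g in geoms:
                gx0, gy0, gx1, gy1 = g.bounds
                if gx1 < x0 or gx0 >= x0 + tile_size:
                    continue
                if gy1 < y0 or gy0 >= y0 + tile_size:
                    continue
                mask |= rasterize_polygon(
                    g, tile_size, tile_size, origin=(x0, y0)
                )
            pairs.append((raster, mask))
            if augment:
                for k in (1, 2):  # 90 and 180 degrees
                    pairs.append(
                        (np.rot90(raster, k).copy(), np.rot90(mask, k).copy())
                    )
    return pairs


# --------------------------------------------------------------------------- #
# refinement


def predict_refined_mask(
    predictor,
    image: TiledImage,
    tile_origin: tuple[int, int],
    tile_size: int = TILE,
    translations: tuple[tuple[int, int], ...] = DEFAULT_TRANSLATIONS,
) -> np.ndarray:
    """Union of inverse-translated variant predictions over one tile.

    The predictor runs on the identity tile and on each translated tile;
    every variant mask is shifted back and the refined mask is the
    pixelwise union restricted to the tile footprint.  By construction the
    result contains the identity prediction.
    """
    x0, y0 = tile_origin
    out = np.zeros((tile_size, tile_size), dtype=bool)
    for dx, dy in translations:
        raster = image.read_region(0, x0 + dx, y0 + dy, tile_size, tile_size)
        mask = predictor.predict(raster, (x0 + dx, y0 + dy))
        if mask.shape != (tile_size, tile_size):
            raise ValueError(
                f"predictor returned {mask.shape}, expected {(tile_size, tile_size)}"
            )
        # variant pixel (i, j) sits at global (x0+dx+j, y0+dy+i); keep the
        # part overlapping the footprint
        sj0, si0 = max(0, -dx), max(0, -dy)
        sj1, si1 = min(tile_size, tile_size - dx), min(tile_size, tile_size - dy)
        if sj0 >= sj1 or si0 >= si1:
            continue
        out[si0 + dy : si1 + dy, sj0 + dx : sj1 + dx] |= mask[si0:si1, sj0:sj1]
    return out


def predict_image_mask(
    predictor,
    image: TiledImage,
    refined: bool = True,
    tile_size: int = TILE,
) -> np.ndarray:
    """Stitch per-tile (refined or identity) predictions into a full-image
    binary mask."""
    h, w = image.height, image.width
    out = np.zeros((h, w), dtype=bool)
    for y0 in range(0, h, tile_size):
        for x0 in range(0, w, tile_size):
            if refined:
                tile_mask = predict_refined_mask(
                    predictor, image, (x0, y0), tile_size
                )
            else:
                raster = image.read_region(0, x0, y0, tile_size, tile_size)
                tile_mask = predictor.predict(raster, (x0, y0))
            hh, ww = min(tile_size, h - y0), min(tile_size, w - x0)
            out[y0 : y0 + hh, x0 : x0 + ww] |= tile_mask[:hh, :ww]
    return out


def recenter_refine(
    predictor,
    obj: SegmentedObject,
    image: TiledImage,
    params: SegmentationParams = DL_SEGMENTATION_PARAMS,
    tile_size: int = TILE,
) -> SegmentedObject:
    """Re-predict on a virtual tile centred on the object.

    Partially detected border objects become central in the virtual tile
    and are therefore detected completely; the overlapping re-centred
    detection replaces the input.  If the object exceeds the virtual tile,
    or nothing overlapping is detected, the input is kept unchanged.
    """
    x0b, y0b, x1b, y1b = obj.bbox
    if x1b - x0b > tile_size or y1b - y0b > tile_size:
        logger.warning("object %d larger than virtual tile; kept as-is", obj.id)
        return obj
    cx, cy = obj.centroid
    ox, oy = int(round(cx)) - tile_size // 2, int(round(cy)) - tile_size // 2
    raster = image.read_region(0, ox, oy, tile_size, tile_size)
    mask = predictor.predict(raster, (ox, oy))
    h, w = image.height, image.width
    best, best_overlap = None, 0
    own = obj.pixel_set()
    for cand in segment_bitmap(mask, params):
        ys, xs = cand.ys + oy, cand.xs + ox
        keep = (ys >= 0) & (ys < h) & (xs >= 0) & (xs < w)
        ys, xs = ys[keep], xs[keep]
        if not len(ys):
            continue
        overlap = len(own & set(zip(ys.tolist(), xs.tolist())))
        if overlap > best_overlap:
            best_overlap = overlap
            best = (ys, xs)
    if best is None:
        logger.info("re-centred prediction found nothing overlapping object %d", obj.id)
        return obj
    return SegmentedObject(
        id=obj.id, ys=best[0], xs=best[1],
        origin_tiles=set(obj.origin_tiles), parent_id=obj.parent_id,
    )


def deduplicate_objects(
    objects: list[SegmentedObject], coverage: float = 0.9
) -> list[SegmentedObject]:
    """Keep objects that cover others; drop the covered ones.

    B is removed when some kept object A covers it: |A∩B|/|B| >= coverage.
    Objects are visited largest-first so the most complete detection wins;
    the result has no remaining pair exceeding the threshold.
    """
    order = sorted(objects, key=lambda o: -o.area)
    kept: list[SegmentedObject] = []
    kept_sets: list[set] = []
    for cand in order:
        pix = cand.pixel_set()
        covered = any(
            len(ks & pix) / len(pix) >= coverage for ks in kept_sets
        )
        if not covered:
            kept.append(cand)
            kept_sets.append(pix)
    kept.sort(key=lambda o: o.id)
    return kept


# --------------------------------------------------------------------------- #
# evaluation


@dataclass
class DiceReport:
    index: float
    gt_dice: list[float]          # per ground-truth object, in input order
    seg_dice: list[float]         # per segmented object
    gt_weights: list[float]
    seg_weights: list[float]
    matches: list[tuple[int | None, int | None, float]]  # (gt, seg, dice)


def _dice(a: set, b: set) -> float:
    if not a and not b:
        return 1.0
    return 2.0 * len(a & b) / (len(a) + len(b))


def _best_match(pix: set, centroid, others: list[set], centroids) -> int | None:
    overlaps = [len(pix & o) for o in others]
    mx = max(overlaps, default=0)
    if mx == 0:
        return None
    tied = [i for i, v in enumerate(overlaps) if v == mx]
    if len(tied) == 1:
        return tied[0]
    # tie-break on centroid distance
    cx, cy = centroid
    return min(
        tied,
        key=lambda i: (centroids[i][0] - cx) ** 2 + (centroids[i][1] - cy) ** 2,
    )


def dice_object_index(
    ground_truth: list[SegmentedObject], segmented: list[SegmentedObject]
) -> DiceReport:
    """Object-size-weighted, bidirectionally matched Dice object index.

    Each ground-truth object is matched to the segmented object with
    maximal pixel overlap and vice versa; the two size-weighted mean Dice
    overlaps are summed and divided by two.  Weights are proportional to
    object pixel count within each set.  Empty vs empty scores 1, one
    empty side scores 0; identical object sets score exactly 1.
    """
    if not ground_truth and not segmented:
        return DiceReport(1.0, [], [], [], [], [])
    if not ground_truth or not segmented:
        return DiceReport(
            0.0,
            [0.0] * len(ground_truth),
            [0.0] * len(segmented),
            [o.area for o in ground_truth],
            [o.area for o in segmented],
            [],
        )
    g_sets = [o.pixel_set() for o in ground_truth]
    s_sets = [o.pixel_set() for o in segmented]
    g_cent = [o.centroid for o in ground_truth]
    s_cent = [o.centroid for o in segmented]
    g_tot = sum(len(p) for p in g_sets)
    s_tot = sum(len(p) for p in s_sets)
    g_w = [len(p) / g_tot for p in g_sets]
    s_w = [len(p) / s_tot for p in s_sets]
    matches = []
    g_dice = []
    for i, p in enumerate(g_sets):
        j = _best_match(p, g_cent[i], s_sets, s_cent)
        d = _dice(p, s_sets[j]) if j is not None else 0.0
        g_dice.append(d)
        matches.append((i, j, d))
    s_dice = []
    for j, p in enumerate(s_sets):
        i = _best_match(p, s_cent[j], g_sets, g_cent)
        d = _dice(p, g_sets[i]) if i is not None else 0.0
        s_dice.append(d)
        matches.append((i, j, d))
    index = 0.5 * (
        sum(w * d for w, d in zip(g_w, g_dice))
        + sum(w * d for w, d in zip(s_w, s_dice))
    )
    return DiceReport(float(index), g_dice, s_dice, g_w, s_w, matches)


# --------------------------------------------------------------------------- #
# pipeline


def dl_segment(
    predictor,
    image: TiledImage,
    refine: bool = True,
    recenter: bool = True,
    dedupe: bool = True,
    params: SegmentationParams = DL_SEGMENTATION_PARAMS,
    tile_size: int = TILE,
) -> list[SegmentedObject]:
    """Full predictor-based segmentation pipeline: (refined) tile masks ->
    object segmentation -> re-centred refinement -> deduplication."""
    mask = predict_image_mask(predictor, image, refined=refine, tile_size=tile_size)
    objects = segment_bitmap(mask, params)
    if recenter:
        objects = [recenter_refine(predictor, o, image, params, tile_size)
                   for o in objects]
    if dedupe:
        objects = deduplicate_objects(objects)
    return objects
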