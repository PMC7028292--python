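"""Object segmentation and classification.

Foreground pixels (from a pixel-classification model, a mask, or a simple
threshold) are cleaned by erosion/dilation, grouped into 8-connected
components, optionally split by a distance-transform watershed (touching
cells), filtered by area, and reported as :class:`SegmentedObject` records.

Segmentation is tile-aware: each tile is processed with a halo wide enough
to cover the morphological influence radius, objects touching interior tile
borders are flagged *open*, and a union-find reduce step merges open
objects that are 8-adjacent across a shared border.  Watershed splitting
and area filtering run per merged component, so the tiled result equals
segmentation of the unpartitioned image exactly — for any tile size and
any grid offset.

Object classification mirrors the pixel classifier: a fixed documented
feature set per object (shape, intensity, texture, location), z-scored, and
a linear SVM trained from user-marked example objects.
"""

from __future__ import annotations

import base64
import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.measure import regionprops
from skimage.segmentation import watershed
from sklearn.svm import LinearSVC

from .image import TiledImage
from .pixel import ACCURACY_WARNING_THRESHOLD, feature_maps

logger = logging.getLogger(__name__)

__all__ = [
    "SegmentationParams",
    "SegmentedObject",
    "segment_bitmap",
    "segment_bitmap_tiled",
    "merge_cross_tile_objects",
    "object_features",
    "OBJECT_FEATURE_NAMES",
    "ObjectClassifierModel",
    "train_object_classifier",
    "classify_objects",
    "two_level_segmentation",
    "save_object_model",
    "load_object_model",
]

_S8 = np.ones((3, 3), dtype=bool)  # 8-connectivity / 3x3 structuring element


@dataclass
class SegmentationParams:
    erosion_iterations: int = 1
    dilation_iterations: int = 1
    use_watershed: bool = False
    watershed_min_distance: int = 5
    min_area: int = 1
    max_area: int | None = None
    algorithm: str = "standard"  # reserved for alternative segmenters

    def __post_init__(self) -> None:
        if self.erosion_iterations < 0 or self.dilation_iterations < 0:
            raise ValueError("morphology iterations must be >= 0")
        if self.min_area < 1:
            raise ValueError("min_area must be >= 1")
        if self.algorithm != "standard":
            raise NotImplementedError(f"algorithm {self.algorithm!r} not available")

    @property
    def halo(self) -> int:
        """Influence radius of the morphology; tiles are read with this halo."""
        return self.erosion_iterations + self.dilation_iterations + 1


@dataclass
class SegmentedObject:
    id: int
    ys: np.ndarray                # row coords, image frame
    xs: np.ndarray                # col coords, image frame
    open_border: bool = False     # touches an interior tile border
    origin_tiles: set = field(default_factory=set)
    features: dict | None = None
    class_name: str | None = None
    parent_id: int | None = None

    @property
    def area(self) -> int:
        return len(self.xs)

    @property
    def bbox(self) -> tuple[int, int, int, int]:
        """(x0, y0, x1, y1), exclusive upper bounds."""
        return (
            int(self.xs.min()),
            int(self.ys.min()),
            int(self.xs.max()) + 1,
            int(self.ys.max()) + 1,
        )

    @property
    def centroid(self) -> tuple[float, float]:
        return float(self.xs.mean()), float(self.ys.mean())

    def pixel_set(self) -> set:
        return set(zip(self.ys.tolist(), self.xs.tolist()))

    def local_mask(self, pad: int = 0) -> tuple[np.ndarray, tuple[int, int]]:
        """Binary crop mask and its (x0, y0) offset in the image frame."""
        x0, y0, x1, y1 = self.bbox
        m = np.zeros((y1 - y0 + 2 * pad, x1 - x0 + 2 * pad), dtype=bool)
        m[self.ys - y0 + pad, self.xs - x0 + pad] = True
        return m, (x0 - pad, y0 - pad)

    def outline(self):
        """Pixel-boundary polygon; its area equals the pixel count."""
        from shapely import box as _box
        from shapely.ops import unary_union

        return unary_union(
            [_box(x, y, x + 1, y + 1) for x, y in zip(self.xs, self.ys)]
        )


# --------------------------------------------------------------------------- #
# segmentation core


def _morph(bitmap: np.ndarray, params: SegmentationParams) -> np.ndarray:
    out = bitmap
    if params.erosion_iterations:
        out = ndimage.binary_erosion(
            out, _S8, iterations=params.erosion_iterations, border_value=0
        )
    if params.dilation_iterations:
        out = ndimage.binary_dilation(
            out, _S8, iterations=params.dilation_iterations, border_value=0
        )
    return out


def _split_component(
    ys: np.ndarray, xs: np.ndarray, params: SegmentationParams
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Watershed-split one connected component into touching sub-objects."""
    if not params.use_watershed:
        return [(ys, xs)]
    y0, x0 = ys.min(), xs.min()
    mask = np.zeros((ys.max() - y0 + 3, xs.max() - x0 + 3), dtype=bool)
    mask[ys - y0 + 1, xs - x0 + 1] = True
    dist = ndimage.distance_transform_edt(mask)
    peaks = peak_local_max(
        dist,
        min_distance=params.watershed_min_distance,
        exclude_border=False,
        labels=mask,
    )
    if len(peaks) <= 1:
        return [(ys, xs)]
    markers = np.zeros(mask.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    lab = watershed(-dist, markers, mask=mask)
    out = []
    for v in range(1, len(peaks) + 1):
        sel = lab == v
        if sel.any():
            cy, cx = np.nonzero(sel)
            out.append((cy + y0 - 1, cx + x0 - 1))
    return out


def _finalize(
    components: list[tuple[np.ndarray, np.ndarray, bool, set]],
    params: SegmentationParams,
) -> list[SegmentedObject]:
    """Watershed-split, area-filter and number merged components."""
    objects: list[SegmentedObject] = []
    oid = 0
    for ys, xs, open_border, tiles in components:
        for sy, sx in _split_component(ys, xs, params):
            area = len(sx)
            if area < params.min_area:
                continue
            if params.max_area is not None and area > params.max_area:
                continue
            objects.append(
                SegmentedObject(
                    id=oid, ys=sy, xs=sx, open_border=open_border,
                    origin_tiles=set(tiles),
                )
            )
            oid += 1
    return objects


def segment_bitmap(
    bitmap: np.ndarray, params: SegmentationParams | None = None
) -> list[SegmentedObject]:
    """Segment a full-image foreground bitmap (the untiled reference path)."""
    params = params or SegmentationParams()
    lab, n = ndimage.label(_morph(bitmap, params), structure=_S8)
    comps = []
    objs = ndimage.find_objects(lab)
    for v in range(1, n + 1):
        sl = objs[v - 1]
        cy, cx = np.nonzero(lab[sl] == v)
        comps.append(
            (cy + sl[0].start, cx + sl[1].start, False, set())
        )
    return _finalize(comps, params)


def _grid_starts(extent: int, tile: int, origin: int) -> list[int]:
    """Tile start coordinates covering [0, extent) for a grid anchored at
    ``origin`` (mod tile)."""
    first = origin % tile
    if first > 0:
        first -= tile
    return list(range(first, extent, tile))


def segment_bitmap_tiled(
    bitmap: np.ndarray,
    params: SegmentationParams | None = None,
    tile_size: int = 512,
    origin: tuple[int, int] = (0, 0),
) -> list[SegmentedObject]:
    """Tile-partitioned segmentation with cross-border merging.

    Produces exactly the objects of :func:`segment_bitmap` on the same
    bitmap, for any tile size and grid origin.  Outside the image the
    foreground is background (as in the untiled path); tile halos therefore
    read from the zero-padded bitmap.
    """
    params = params or SegmentationParams()
    h, w = bitmap.shape
    halo = params.halo
    tile_results = []
    for y0 in _grid_starts(h, tile_size, origin[1]):
        for x0 in _grid_starts(w, tile_size, origin[0]):
            fx0, fy0 = max(0, x0), max(0, y0)
            fx1, fy1 = min(w, x0 + tile_size), min(h, y0 + tile_size)
            if fx0 >= fx1 or fy0 >= fy1:
                continue
            wx0, wy0 = fx0 - halo, fy0 - halo
            wx1, wy1 = fx1 + halo, fy1 + halo
            win = np.zeros((wy1 - wy0, wx1 - wx0), dtype=bool)
            sx0, sy0 = max(0, wx0), max(0, wy0)
            sx1, sy1 = min(w, wx1), min(h, wy1)
            win[sy0 - wy0 : sy1 - wy0, sx0 - wx0 : sx1 - wx0] = bitmap[
                sy0:sy1, sx0:sx1
            ]
            tile_results.append(
                _segment_window(
                    win, (wx0, wy0), (fx0, fy0, fx1, fy1), (h, w), params,
                    tile_id=(x0 // tile_size, y0 // tile_size),
                )
            )
    return merge_cross_tile_objects(tile_results, params, image_shape=(h, w))


def _segment_window(
    window: np.ndarray,
    window_origin: tuple[int, int],
    footprint: tuple[int, int, int, int],
    image_shape: tuple[int, int],
    params: SegmentationParams,
    tile_id: tuple[int, int],
) -> dict:
    """Morph + label one haloed window, keep pixels inside the footprint.

    Returns a tile-result record consumed by
    :func:`merge_cross_tile_objects`.
    """
    wx0, wy0 = window_origin
    fx0, fy0, fx1, fy1 = footprint
    h, w = image_shape
    morphed = _morph(window, params)
    crop = morphed[fy0 - wy0 : fy1 - wy0, fx0 - wx0 : fx1 - wx0]
    lab, n = ndimage.label(crop, structure=_S8)
    objects = []
    for v in range(1, n + 1):
        cy, cx = np.nonzero(lab == v)
        ys, xs = cy + fy0, cx + fx0
        open_border = bool(
            (fx0 > 0 and (xs == fx0).any())
            or (fy0 > 0 and (ys == fy0).any())
            or (fx1 < w and (xs == fx1 - 1).any())
            or (fy1 < h and (ys == fy1 - 1).any())
        )
        objects.append(
            {"ys": ys, "xs": xs, "open": open_border, "tile": tile_id}
        )
    return {"footprint": footprint, "tile": tile_id, "objects": objects}


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def merge_cross_tile_objects(
    tile_results: list[dict],
    params: SegmentationParams | None = None,
    image_shape: tuple[int, int] | None = None,
) -> list[SegmentedObject]:
    """Union open objects that touch 8-adjacently across tile borders, then
    watershed-split and area-filter the merged components."""
    params = params or SegmentationParams()
    all_objs = [o for tr in tile_results for o in tr["objects"]]
    borders: dict[tuple[int, int], int] = {}
    # index border-strip pixels of open objects
    strip_pixels: list[tuple[int, np.ndarray, np.ndarray]] = []
    for idx, (tr_obj) in enumerate(all_objs):
        if not tr_obj["open"]:
            continue
        ys, xs = tr_obj["ys"], tr_obj["xs"]
        for y, x in zip(ys.tolist(), xs.tolist()):
            borders[(y, x)] = idx
    uf = _UnionFind(len(all_objs))
    for (y, x), idx in borders.items():
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                other = borders.get((y + dy, x + dx))
                if other is not None and other != idx:
                    uf.union(idx, other)
    grouped: dict[int, list[int]] = {}
    for idx in range(len(all_objs)):
        grouped.setdefault(uf.find(idx), []).append(idx)
    comps = []
    for members in grouped.values():
        ys = np.concatenate([all_objs[m]["ys"] for m in members])
        xs = np.concatenate([all_objs[m]["xs"] for m in members])
        open_border = len(members) == 1 and all_objs[members[0]]["open"]
        tiles = {all_objs[m]["tile"] for m in members}
        comps.append((ys, xs, open_border and len(tiles) == 1, tiles))
    # deterministic order: by top-left pixel
    comps.sort(key=lambda c: (int(c[0].min()), int(c[1].min())))
    return _finalize(comps, params)


# --------------------------------------------------------------------------- #
# object features & classification

OBJECT_FEATURE_NAMES = (
    "area",
    "perimeter",
    "circularity",
    "eccentricity",
    "bbox_aspect",
    "centroid_x_norm",
    "centroid_y_norm",
)
_TEXTURE_STRUCTURE_SIZE = 2  # window for the per-object edge-factor texture stat


def object_features(
    obj: SegmentedObject, image: TiledImage
) -> dict[str, float]:
    """Fixed feature set per object: shape (area, perimeter, circularity
    4*pi*A/P^2, eccentricity, bbox aspect), location (centroid normalized by
    image size), and per-channel intensity (mean/sd/min/max) and texture
    (mean edge factor) statistics."""
    if obj.area == 0:
        raise ValueError("empty object")
    mask, (x0, y0) = obj.local_mask(pad=1)
    props = regionprops(mask.astype(np.uint8))[0]
    perim = float(props.perimeter) or 1.0
    cx, cy = obj.centroid
    feats: dict[str, float] = {
        "area": float(obj.area),
        "perimeter": perim,
        "circularity": float(4.0 * np.pi * obj.area / perim**2),
        "eccentricity": float(props.eccentricity),
        "bbox_aspect": float(
            max(mask.shape[1] - 2, mask.shape[0] - 2)
            / max(1, min(mask.shape[1] - 2, mask.shape[0] - 2))
        ),
        "centroid_x_norm": cx / image.width,
        "centroid_y_norm": cy / image.height,
    }
    pad = _TEXTURE_STRUCTURE_SIZE
    crop = image.read_region(
        0, x0 - pad, y0 - pad, mask.shape[1] + 2 * pad, mask.shape[0] + 2 * pad
    )
    iy, ix = obj.ys - y0 + 1 + pad, obj.xs - x0 + 1 + pad
    for c in range(image.n_channels):
        ch = crop[:, :, c].astype(np.float64)
        vals = ch[iy, ix]
        edge = feature_maps(ch, _TEXTURE_STRUCTURE_SIZE)[4]
        feats[f"ch{c}_mean"] = float(vals.mean())
        feats[f"ch{c}_sd"] = float(vals.std())
        feats[f"ch{c}_min"] = float(vals.min())
        feats[f"ch{c}_max"] = float(vals.max())
        feats[f"ch{c}_edge_mean"] = float(edge[iy, ix].mean())
    return feats


@dataclass
class ObjectClassifierModel:
    class_names: tuple[str, ...]
    feature_names: tuple[str, ...]
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    weights: np.ndarray
    biases: np.ndarray
    training_accuracy: float
    low_accuracy_warning: bool

    def predict(self, X: np.ndarray) -> np.ndarray:
        Z = (X - self.feature_mean) / self.feature_sd
        d = Z @ self.weights.T + self.biases
        if len(self.class_names) == 2:
            return (d[:, 0] > 0).astype(np.int32)
        return np.argmax(d, axis=1).astype(np.int32)


def _feature_matrix(
    objects: list[SegmentedObject], feature_names: tuple[str, ...]
) -> np.ndarray:
    for o in objects:
        if o.features is None:
            raise ValueError(f"object {o.id} has no features; run object_features")
    return np.array(
        [[o.features[k] for k in feature_names] for o in objects], dtype=np.float64
    )


def train_object_classifier(
    objects: list[SegmentedObject],
    labels: list[str],
    seed: int = 0,
) -> ObjectClassifierModel:
    """Linear SVM on standardized object features from user-marked objects;
    same training-accuracy/warning contract as the pixel classifier."""
    class_names = tuple(sorted(set(labels)))
    if len(class_names) < 2:
        raise ValueError("need at least 2 object classes")
    feature_names = tuple(sorted(objects[0].features.keys()))
    X = _feature_matrix(objects, feature_names)
    y = np.array([class_names.index(l) for l in labels])
    mean, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    svc = LinearSVC(C=1.0, random_state=int(seed) % (2**31), max_iter=5000)
    svc.fit((X - mean) / sd, y)
    acc = float(svc.score((X - mean) / sd, y))
    warn = acc < ACCURACY_WARNING_THRESHOLD
    if warn:
        logger.warning("object-classifier training accuracy %.3f below 0.85", acc)
    return ObjectClassifierModel(
        class_names=class_names,
        feature_names=feature_names,
        feature_mean=mean,
        feature_sd=sd,
        weights=np.atleast_2d(svc.coef_.copy()),
        biases=np.atleast_1d(svc.intercept_.copy()),
        training_accuracy=acc,
        low_accuracy_warning=warn,
    )


def classify_objects(
    model: ObjectClassifierModel, objects: list[SegmentedObject]
) -> list[SegmentedObject]:
    """Assign a class label to every featurized object (in place)."""
    if not objects:
        return objects
    X = _feature_matrix(objects, model.feature_names)
    for o, k in zip(objects, model.predict(X)):
        o.class_name = model.class_names[int(k)]
    return objects


def two_level_segmentation(
    primary: list[SegmentedObject],
    secondary_bitmap: np.ndarray,
    params: SegmentationParams | None = None,
) -> list[SegmentedObject]:
    """Secondary segmentation restricted to the interiors of primary
    objects (e.g. spots inside cells); children carry their parent's id."""
    params = params or SegmentationParams()
    children: list[SegmentedObject] = []
    next_id = 0
    for parent in primary:
        mask, (x0, y0) = parent.local_mask(pad=params.halo)
        sub = np.zeros(mask.shape, dtype=bool)
        h, w = secondary_bitmap.shape
        ys = np.clip(parent.ys, 0, h - 1)
        xs = np.clip(parent.xs, 0, w - 1)
        sub[parent.ys - y0, parent.xs - x0] = secondary_bitmap[ys, xs]
        for child in segment_bitmap(sub, params):
            child.ys = child.ys + y0
            child.xs = child.xs + x0
            child.parent_id = parent.id
            child.id = next_id
            next_id += 1
            children.append(child)
    return children


# --------------------------------------------------------------------------- #
# persistence


def _enc(a: np.ndarray) -> dict:
    a = np.ascontiguousarray(a, dtype=np.float64)
    return {"shape": list(a.shape), "data": base64.b64encode(a.tobytes()).decode()}


def _dec(d: dict) -> np.ndarray:
    return np.frombuffer(base64.b64decode(d["data"]), dtype=np.float64).reshape(
        d["shape"]
    )


def save_object_model(model: ObjectClassifierModel, path: str) -> None:
    doc = {
        "format": "orbitlite-object-model",
        "version": 1,
        "class_names": list(model.class_names),
        "feature_names": list(model.feature_names),
        "training_accuracy": model.training_accuracy,
        "low_accuracy_warning": model.low_accuracy_warning,
        "feature_mean": _enc(model.feature_mean),
        "feature_sd": _enc(model.feature_sd),
        "weights": _enc(model.weights),
        "biases": _enc(model.biases),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_object_model(path: str) -> ObjectClassifierModel:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != "orbitlite-object-model":
        raise ValueError(f"{path!r} is not an object-classifier model file")
    return ObjectClassifierModel(
        class_names=tuple(doc["class_names"]),
        feature_names=tuple(doc["feature_names"]),
        feature_mean=_dec(doc["feature_mean"]),
        feature_sd=_dec(doc["feature_sd"]),
        weights=_dec(doc["weights"]),
        biases=_dec(doc["biases"]),
        training_accuracy=doc["training_accuracy"],
        low_accuracy_warning=doc["low_accuracy_warning"],
    )
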