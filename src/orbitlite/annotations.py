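"""Vector annotations and ROI algebra.

Annotations are typed shapes in level-0 pixel coordinates.  Their types
combine into the *effective region of interest* with a fixed precedence:

* the ROI is the union of all ``roi`` polygons (the whole image if none);
* ``exclusion`` polygons — and exclusion-flagged classes of a low-resolution
  exclusion-model class map — remove area from the ROI;
* ``inclusion`` polygons have the highest priority and overrule exclusions
  (but never extend the ROI beyond the union of ``roi`` polygons).

Polygon membership is a pixel-centre test with boundaries counting as
inside, so rasterized areas are reproducible integers.

Annotations persist as a GeoJSON FeatureCollection with ``type`` and
``name`` in feature properties, stored in sidecar files keyed by image ID.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import shapely
from shapely.geometry import LineString, Polygon, box, mapping, shape
from shapely.ops import unary_union

from .image import TiledImage

__all__ = [
    "AnnotationType",
    "Annotation",
    "ExclusionMask",
    "RegionPredicate",
    "effective_roi",
    "select_exclusion_level",
    "upsample_mask",
    "downsample_mask_majority",
    "rasterize_polygon",
    "load_annotations",
    "save_annotations",
]


class AnnotationType(str, Enum):
    PLAIN = "plain"
    ROI = "roi"
    EXCLUSION = "exclusion"
    INCLUSION = "inclusion"
    JUNCTION_LINE = "junction_line"


@dataclass
class Annotation:
    name: str
    type: AnnotationType
    geometry: Polygon | LineString
    image_id: str | None = None

    def __post_init__(self) -> None:
        if isinstance(self.type, str):
            self.type = AnnotationType(self.type)
        if self.type == AnnotationType.JUNCTION_LINE:
            if not isinstance(self.geometry, LineString):
                raise ValueError("junction_line annotations must be open polylines")
        elif isinstance(self.geometry, Polygon) and not self.geometry.is_valid:
            self.geometry = self.geometry.buffer(0)  # normalize self-intersections


@dataclass
class ExclusionMask:
    """Low-resolution class map with per-class exclude flags."""

    class_map: np.ndarray          # 2-D int class indices at `level`
    level: int                     # pyramid level the map was computed at
    factor: int                    # pyramid factor of the owning image
    exclude_flags: tuple[bool, ...]  # True = class is excluded

    def excluded_at_level0(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Nearest-neighbour lookup of the exclude flag at level-0 coords."""
        scale = self.factor**self.level
        h, w = self.class_map.shape
        j = np.minimum((np.asarray(x) / scale).astype(int), w - 1)
        i = np.minimum((np.asarray(y) / scale).astype(int), h - 1)
        flags = np.asarray(self.exclude_flags, dtype=bool)
        return flags[self.class_map[i, j]]


def _union(geoms: list) -> Polygon | None:
    if not geoms:
        return None
    g = unary_union(geoms)
    shapely.prepare(g)
    return g


@dataclass
class RegionPredicate:
    """Composed inclusion test over level-0 coordinates.

    A point is in the region iff it is inside the ROI union (or there is no
    ROI annotation) and is either not excluded or inside an inclusion
    polygon.  Masks (classification/segmentation masks) are *not* part of a
    RegionPredicate: they filter active pixels downstream but never change
    the measured ROI area.
    """

    roi_union: Polygon | None = None        # None = whole image
    exclusion_union: Polygon | None = None
    inclusion_union: Polygon | None = None
    exclusion_mask: ExclusionMask | None = None

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if self.roi_union is not None:
            inside = shapely.intersects_xy(self.roi_union, x, y)
        else:
            inside = np.ones(x.shape, dtype=bool)
        excluded = np.zeros(x.shape, dtype=bool)
        if self.exclusion_union is not None:
            excluded |= shapely.intersects_xy(self.exclusion_union, x, y)
        if self.exclusion_mask is not None:
            excluded |= self.exclusion_mask.excluded_at_level0(x, y)
        if self.inclusion_union is not None:
            included = shapely.intersects_xy(self.inclusion_union, x, y)
        else:
            included = np.zeros(x.shape, dtype=bool)
        return inside & (included | ~excluded)

    def contains_grid(self, x0: int, y0: int, w: int, h: int) -> np.ndarray:
        """Membership bitmap for the pixel grid [x0, x0+w) x [y0, y0+h)."""
        yy, xx = np.mgrid[y0 : y0 + h, x0 : x0 + w]
        return self.contains(xx.ravel(), yy.ravel()).reshape(h, w)

    def intersects_bbox(self, x0: float, y0: float, x1: float, y1: float) -> bool:
        """Whether the supporting geometry touches a bounding box (used for
        tile enumeration; exclusions deliberately do not drop tiles)."""
        if self.roi_union is None:
            return True
        b = box(x0, y0, x1, y1)
        if self.roi_union.intersects(b):
            return True
        return self.inclusion_union is not None and self.inclusion_union.intersects(b)

    def measured_area(self, image: TiledImage, chunk_rows: int = 256) -> int:
        """Exact count of level-0 pixels inside the region."""
        total = 0
        w, h = image.width, image.height
        for y0 in range(0, h, chunk_rows):
            rows = min(chunk_rows, h - y0)
            total += int(self.contains_grid(0, y0, w, rows).sum())
        return total


def effective_roi(
    annotations: list[Annotation],
    exclusion_mask: ExclusionMask | None = None,
) -> RegionPredicate:
    """Combine typed annotations (and an optional exclusion-model mask) into
    a region predicate.  Annotation order is irrelevant."""
    ids = {a.image_id for a in annotations if a.image_id is not None}
    if len(ids) > 1:
        raise ValueError(f"annotations from mixed images: {sorted(ids)}")
    rois = [a.geometry for a in annotations if a.type == AnnotationType.ROI]
    excl = [a.geometry for a in annotations if a.type == AnnotationType.EXCLUSION]
    incl = [a.geometry for a in annotations if a.type == AnnotationType.INCLUSION]
    return RegionPredicate(
        roi_union=_union(rois),
        exclusion_union=_union(excl),
        inclusion_union=_union(incl),
        exclusion_mask=exclusion_mask,
    )


def select_exclusion_level(image: TiledImage, target_pixels: int = 2**20) -> int:
    """Pyramid level whose total pixel count is closest to ~one megapixel
    (ties go to the higher-resolution level)."""
    counts = [h * w for h, w in (image.level_shape(l) for l in range(image.n_levels))]
    diffs = [abs(c - target_pixels) for c in counts]
    return int(np.argmin(diffs))  # argmin returns the first (finer) level on ties


def upsample_mask(
    mask: np.ndarray, scale: int, target_shape: tuple[int, int]
) -> np.ndarray:
    """Nearest-neighbour upsample of a class map by an integer scale,
    cropped/edge-clamped to the target (h, w)."""
    h, w = mask.shape
    th, tw = target_shape
    i = np.minimum(np.arange(th) // scale, h - 1)
    j = np.minimum(np.arange(tw) // scale, w - 1)
    return mask[np.ix_(i, j)]


def downsample_mask_majority(mask: np.ndarray, scale: int) -> np.ndarray:
    """Majority-vote block downsample of a class map (used for round-trip
    consistency checks of block-constant masks)."""
    h, w = mask.shape
    oh, ow = -(-h // scale), -(-w // scale)
    out = np.zeros((oh, ow), dtype=mask.dtype)
    for bi in range(oh):
        for bj in range(ow):
            blk = mask[bi * scale : (bi + 1) * scale, bj * scale : (bj + 1) * scale]
            vals, counts = np.unique(blk, return_counts=True)
            out[bi, bj] = vals[np.argmax(counts)]
    return out


def rasterize_polygon(
    geom, h: int, w: int, origin: tuple[int, int] = (0, 0)
) -> np.ndarray:
    """Pixel-centre rasterization of a polygon onto an (h, w) grid whose
    top-left pixel centre is at `origin` (boundary pixels count as inside)."""
    x0, y0 = origin
    minx, miny, maxx, maxy = geom.bounds
    j0 = max(0, int(minx - x0) - 1)
    j1 = min(w, int(maxx - x0) + 2)
    i0 = max(0, int(miny - y0) - 1)
    i1 = min(h, int(maxy - y0) + 2)
    out = np.zeros((h, w), dtype=bool)
    if j0 >= j1 or i0 >= i1:
        return out
    yy, xx = np.mgrid[i0:i1, j0:j1]
    out[i0:i1, j0:j1] = shapely.intersects_xy(
        geom, (xx + x0).astype(float).ravel(), (yy + y0).astype(float).ravel()
    ).reshape(yy.shape)
    return out


# --------------------------------------------------------------------------- #
# GeoJSON persistence


def save_annotations(annotations: list[Annotation], path: str) -> None:
    features = []
    for a in annotations:
        props = {"name": a.name, "type": a.type.value}
        if a.image_id:
            props["image_id"] = a.image_id
        features.append(
            {"type": "Feature", "properties": props, "geometry": mapping(a.geometry)}
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def load_annotations(path: str) -> list[Annotation]:
    with open(path) as fh:
        data = json.load(fh)
    out = []
    for feat in data.get("features", []):
        props = feat.get("properties", {})
        out.append(
            Annotation(
                name=props.get("name", ""),
                type=AnnotationType(props.get("type", "plain")),
                geometry=shape(feat["geometry"]),
                image_id=props.get("image_id"),
            )
        )
    return out
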