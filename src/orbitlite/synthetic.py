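"""Synthetic whole-slide scene generator.

Real WSI material (scanned, stained tissue) cannot ship with a code
repository, so every analysis in this package is exercised on synthetic
scenes that emulate the image structure the algorithms care about:

* *texture regions* — polygonal areas filled with a noisy sinusoidal
  grating, standing in for stained tissue classes.  Mean intensity,
  grating amplitude and spatial period are set per class, so classes can
  differ in brightness, in texture scale, or (deliberately) in nothing.
* *blob fields* — bright quasi-circular "cells" on a dark background,
  with an exact object count and the option to force a given number of
  blobs to straddle tile borders.
* *fibre sets* — thin curvilinear structures ("nerve fibres") with a
  bright core and optionally a dimmer tail, each recorded as a centreline
  polyline.
* *composite fields* — larger textured discs ("glomeruli"-like objects)
  used by the segmentation-refinement pipeline, again with controlled
  tile-border straddling.

Generation is a pure function of the scene spec: the same spec (including
its seed) always yields byte-identical pixels and ground truth.  Ground
truth is returned as integer label maps plus per-element vector records.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
import shapely
import shapely.ops
from shapely.geometry import LineString, Polygon

from .image import DEFAULT_TILE_SIZE, TiledImage, build_pyramid

__all__ = [
    "TextureRegionSpec",
    "BlobFieldSpec",
    "FibreSetSpec",
    "CompositeFieldSpec",
    "SceneSpec",
    "GroundTruth",
    "generate_scene",
    "scene_from_json",
    "scene_to_json",
]


@dataclass
class TextureRegionSpec:
    """Polygonal region filled with a noisy grating."""

    kind: str = "texture_region"
    polygon: list[tuple[float, float]] = field(default_factory=list)
    class_name: str = "tissue"
    mean: float = 0.5          # mean intensity in [0,1]
    amplitude: float = 0.0     # grating amplitude
    period: float = 16.0       # grating period, px
    orientation: str = "x"     # "x", "y" or "xy" (product grating)
    noise_sd: float = 0.02     # i.i.d. gaussian pixel noise
    channel: int = 0


@dataclass
class BlobFieldSpec:
    """Bright discs ("cells") with exact count bookkeeping."""

    kind: str = "blob_field"
    n: int = 20
    radius: tuple[float, float] = (6.0, 12.0)
    intensity: float = 0.85
    intensity_jitter: float = 0.0   # per-blob uniform jitter on intensity
    n_border: int = 0               # blobs forced to straddle a tile border
    border_tile_size: int = DEFAULT_TILE_SIZE
    min_gap: float = 6.0            # min gap between blob boundaries
    channel: int = 0


@dataclass
class FibreSetSpec:
    """Curvilinear fibres with bright core and optional dim tail."""

    kind: str = "fibre_set"
    n: int = 8
    width: float = 4.0
    core_intensity: float = 0.9
    tail_intensity: float = 0.45    # between the two hysteresis thresholds
    tail_fraction: float = 0.0      # arc-length fraction rendered at tail level
    length: tuple[float, float] = (120.0, 240.0)
    wiggle: float = 0.25            # sd of per-step heading change (radians)
    n_border: int = 0
    border_tile_size: int = DEFAULT_TILE_SIZE
    channel: int = 0


@dataclass
class CompositeFieldSpec:
    """Large textured discs emulating heterogeneous objects."""

    kind: str = "composite_field"
    n: int = 10
    radius: tuple[float, float] = (18.0, 36.0)
    mean: float = 0.7
    texture_amplitude: float = 0.12
    texture_period: float = 9.0
    n_border: int = 0
    border_tile_size: int = DEFAULT_TILE_SIZE
    min_gap: float = 10.0
    # keep objects out of double-margin corner zones of the tile grid:
    # axis-aligned translation refinement cannot recover an object that sits
    # close to a vertical AND a horizontal grid line at once
    corner_margin: float = 70.0
    channel: int = 0


ElementSpec = TextureRegionSpec | BlobFieldSpec | FibreSetSpec | CompositeFieldSpec

_KIND_MAP = {
    "texture_region": TextureRegionSpec,
    "blob_field": BlobFieldSpec,
    "fibre_set": FibreSetSpec,
    "composite_field": CompositeFieldSpec,
}


@dataclass
class SceneSpec:
    width: int = 512
    height: int = 512
    seed: int = 0
    background: float = 0.1
    background_noise_sd: float = 0.01
    n_channels: int = 1
    tile_size: int = DEFAULT_TILE_SIZE
    pyramid_factor: int = 4
    elements: list[ElementSpec] = field(default_factory=list)


@dataclass
class GroundTruth:
    """Pixel-accurate labels and vector records for every element.

    ``labels`` maps a category ("regions", "blobs", "fibres", "objects") to
    an int32 label image (0 = background; region maps hold 1-based class
    indices).  ``records`` holds per-element metadata: blob centres/radii,
    fibre centreline polylines, region class names and polygons, composite
    object ids.
    """

    labels: dict[str, np.ndarray] = field(default_factory=dict)
    records: dict[str, list] = field(default_factory=dict)

    def count(self, category: str) -> int:
        return len(self.records.get(category, []))


# --------------------------------------------------------------------------- #
# geometry helpers


def _disc_mask(h: int, w: int, cx: float, cy: float, r: float) -> np.ndarray:
    y0, y1 = max(0, int(cy - r) - 1), min(h, int(cy + r) + 2)
    x0, x1 = max(0, int(cx - r) - 1), min(w, int(cx + r) + 2)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    out = np.zeros((h, w), dtype=bool)
    out[y0:y1, x0:x1] = (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
    return out


def _grating(shape: tuple[int, int], spec: TextureRegionSpec) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(np.float32)
    w = 2.0 * math.pi / spec.period
    if spec.orientation == "x":
        g = np.sin(w * xx)
    elif spec.orientation == "y":
        g = np.sin(w * yy)
    else:
        g = np.sin(w * xx) * np.sin(w * yy)
    return spec.mean + spec.amplitude * g


def _polygon_mask(poly: Polygon, h: int, w: int) -> np.ndarray:
    """Pixel-centre-in-polygon rasterization (boundary counts as inside)."""
    minx, miny, maxx, maxy = poly.bounds
    x0, x1 = max(0, int(minx) - 1), min(w, int(maxx) + 2)
    y0, y1 = max(0, int(miny) - 1), min(h, int(maxy) + 2)
    out = np.zeros((h, w), dtype=bool)
    if x0 >= x1 or y0 >= y1:
        return out
    yy, xx = np.mgrid[y0:y1, x0:x1]
    out[y0:y1, x0:x1] = shapely.intersects_xy(
        poly, xx.astype(float).ravel(), yy.astype(float).ravel()
    ).reshape(yy.shape)
    return out


def _place_centres(
    rng: np.random.Generator,
    n: int,
    n_border: int,
    radii: np.ndarray,
    w: int,
    h: int,
    tile: int,
    min_gap: float,
    corner_margin: float = 0.0,
) -> np.ndarray:
    """Rejection-sample non-overlapping disc centres.

    The first ``n_border`` discs are forced to straddle exactly one interior
    tile-grid line (away from grid corners); the rest are kept clear of all
    grid lines so their border status is unambiguous.  With a positive
    ``corner_margin`` no disc may lie within that margin of a vertical and
    a horizontal grid line (or image edge) at the same time.
    """
    vlines = [x for x in range(tile, w, tile)]
    hlines = [y for y in range(tile, h, tile)]
    vedges = vlines + [0, w]
    hedges = hlines + [0, h]
    centres: list[tuple[float, float]] = []

    def near_corner(cx: float, cy: float, r: float) -> bool:
        if corner_margin <= 0:
            return False
        nx = any(abs(cx - L) < r + corner_margin for L in vedges)
        ny = any(abs(cy - L) < r + corner_margin for L in hedges)
        return nx and ny

    def ok(cx: float, cy: float, r: float) -> bool:
        if not (r + 2 <= cx <= w - r - 2 and r + 2 <= cy <= h - r - 2):
            return False
        for (px, py), pr in zip(centres, radii[: len(centres)]):
            if (px - cx) ** 2 + (py - cy) ** 2 < (pr + r + min_gap) ** 2:
                return False
        return True

    def clear_of_lines(
        c: float, lines: list[int], r: float, margin: float = 3.0
    ) -> bool:
        return all(abs(c - L) > r + margin for L in lines)

    for i in range(n):
        r = radii[i]
        placed = False
        for _ in range(4000):
            if i < n_border and (vlines or hlines):
                # straddle one grid line, stay clear of the perpendicular ones
                use_v = bool(rng.integers(2)) if (vlines and hlines) else bool(vlines)
                perp_margin = max(3.0, corner_margin)
                if use_v:
                    cx = float(rng.choice(vlines)) + float(rng.uniform(-r / 2, r / 2))
                    cy = float(rng.uniform(r + 2, h - r - 2))
                    if not clear_of_lines(cy, hedges, r, perp_margin):
                        continue
                else:
                    cy = float(rng.choice(hlines)) + float(rng.uniform(-r / 2, r / 2))
                    cx = float(rng.uniform(r + 2, w - r - 2))
                    if not clear_of_lines(cx, vedges, r, perp_margin):
                        continue
            else:
                cx = float(rng.uniform(r + 2, w - r - 2))
                cy = float(rng.uniform(r + 2, h - r - 2))
                if not (
                    clear_of_lines(cx, vlines, r) and clear_of_lines(cy, hlines, r)
                ):
                    continue
                if near_corner(cx, cy, r):
                    continue
            if ok(cx, cy, r):
                centres.append((cx, cy))
                placed = True
                break
        if not placed:
            raise ValueError(
                "could not place non-overlapping objects; reduce n or radii"
            )
    return np.asarray(centres, dtype=float)


def _fibre_polyline(
    rng: np.random.Generator,
    spec: FibreSetSpec,
    w: int,
    h: int,
    must_cross: int | None,
    axis_vertical: bool,
) -> np.ndarray:
    """Random smooth open polyline; optionally forced across a grid line."""
    step = 6.0
    length = float(rng.uniform(*spec.length))
    n_steps = max(4, int(length / step))
    margin = spec.width * 2 + 4
    if must_cross is not None:
        if axis_vertical:
            x = must_cross - length / 4
            y = rng.uniform(margin + 20, h - margin - 20)
            heading = 0.0
        else:
            y = must_cross - length / 4
            x = rng.uniform(margin + 20, w - margin - 20)
            heading = math.pi / 2
    else:
        x = rng.uniform(margin + 20, w - margin - 20)
        y = rng.uniform(margin + 20, h - margin - 20)
        heading = rng.uniform(0, 2 * math.pi)
    pts = [(x, y)]
    for _ in range(n_steps):
        heading += float(rng.normal(0.0, spec.wiggle))
        x = min(max(x + step * math.cos(heading), margin), w - margin)
        y = min(max(y + step * math.sin(heading), margin), h - margin)
        pts.append((x, y))
    return np.asarray(pts, dtype=float)


# --------------------------------------------------------------------------- #
# renderers


def _render_texture_region(
    canvas: np.ndarray,
    region_labels: np.ndarray,
    spec: TextureRegionSpec,
    class_index: int,
    rng: np.random.Generator,
) -> dict:
    h, w = canvas.shape[:2]
    poly = Polygon(spec.polygon)
    mask = _polygon_mask(poly, h, w)
    tex = _grating((h, w), spec)
    if spec.noise_sd > 0:
        tex = tex + rng.normal(0.0, spec.noise_sd, size=(h, w)).astype(np.float32)
    canvas[:, :, spec.channel][mask] = tex[mask]
    region_labels[mask] = class_index
    return {
        "class_name": spec.class_name,
        "class_index": class_index,
        "polygon": list(map(tuple, spec.polygon)),
        "area": int(mask.sum()),
    }


def _render_blob_field(
    canvas: np.ndarray,
    labels: np.ndarray,
    spec: BlobFieldSpec,
    rng: np.random.Generator,
) -> list[dict]:
    h, w = canvas.shape[:2]
    radii = rng.uniform(spec.radius[0], spec.radius[1], size=spec.n)
    centres = _place_centres(
        rng, spec.n, spec.n_border, radii, w, h, spec.border_tile_size, spec.min_gap
    )
    records = []
    next_label = int(labels.max()) + 1
    for i, ((cx, cy), r) in enumerate(zip(centres, radii)):
        mask = _disc_mask(h, w, cx, cy, r)
        inten = spec.intensity
        if spec.intensity_jitter:
            inten += float(rng.uniform(-spec.intensity_jitter, spec.intensity_jitter))
        canvas[:, :, spec.channel][mask] = inten
        labels[mask] = next_label
        records.append(
            {
                "label": next_label,
                "centre": (float(cx), float(cy)),
                "radius": float(r),
                "intensity": float(inten),
                "straddles_border": i < spec.n_border,
                "area": int(mask.sum()),
            }
        )
        next_label += 1
    return records


def _render_fibre_set(
    canvas: np.ndarray,
    labels: np.ndarray,
    spec: FibreSetSpec,
    rng: np.random.Generator,
) -> list[dict]:
    h, w = canvas.shape[:2]
    tile = spec.border_tile_size
    vlines = list(range(tile, w, tile))
    hlines = list(range(tile, h, tile))
    records = []
    next_label = int(labels.max()) + 1
    placed_buffers: list = []
    for i in range(spec.n):
        for _ in range(300):
            if i < spec.n_border and (vlines or hlines):
                use_v = bool(rng.integers(2)) if (vlines and hlines) else bool(vlines)
                line = int(rng.choice(vlines if use_v else hlines))
                poly = _fibre_polyline(rng, spec, w, h, line, use_v)
            else:
                poly = _fibre_polyline(rng, spec, w, h, None, False)
            ls = LineString(poly)
            if ls.length < spec.length[0] * 0.5:
                continue
            buf = ls.buffer(spec.width / 2.0 + 2.0)
            if any(buf.intersects(b) for b in placed_buffers):
                continue
            placed_buffers.append(buf)
            break
        else:
            raise ValueError("could not place non-overlapping fibres")
        body = ls.buffer(spec.width / 2.0)
        mask = _polygon_mask(body, h, w)
        # split arc-length into core and (optional) tail
        if spec.tail_fraction > 0:
            cut = ls.length * (1.0 - spec.tail_fraction)
            core_ls = shapely.ops.substring(ls, 0, cut)
            core_mask = _polygon_mask(core_ls.buffer(spec.width / 2.0), h, w)
        else:
            core_mask = mask
        tail_mask = mask & ~core_mask
        canvas[:, :, spec.channel][core_mask] = spec.core_intensity
        canvas[:, :, spec.channel][tail_mask] = spec.tail_intensity
        labels[mask] = next_label
        records.append(
            {
                "label": next_label,
                "polyline": [tuple(p) for p in poly],
                "width": float(spec.width),
                "has_tail": bool(spec.tail_fraction > 0),
                "area": int(mask.sum()),
            }
        )
        next_label += 1
    return records


def _render_composite_field(
    canvas: np.ndarray,
    labels: np.ndarray,
    spec: CompositeFieldSpec,
    rng: np.random.Generator,
) -> list[dict]:
    h, w = canvas.shape[:2]
    radii = rng.uniform(spec.radius[0], spec.radius[1], size=spec.n)
    centres = _place_centres(
        rng, spec.n, spec.n_border, radii, w, h, spec.border_tile_size,
        spec.min_gap, corner_margin=spec.corner_margin,
    )
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float32)
    wfreq = 2.0 * math.pi / spec.texture_period
    records = []
    next_label = int(labels.max()) + 1
    for i, ((cx, cy), r) in enumerate(zip(centres, radii)):
        mask = _disc_mask(h, w, cx, cy, r)
        phase = float(rng.uniform(0, 2 * math.pi))
        tex = spec.mean + spec.texture_amplitude * np.sin(wfreq * xx + phase) * np.sin(
            wfreq * yy + phase
        )
        canvas[:, :, spec.channel][mask] = tex[mask]
        labels[mask] = next_label
        records.append(
            {
                "label": next_label,
                "centre": (float(cx), float(cy)),
                "radius": float(r),
                "straddles_border": i < spec.n_border,
                "area": int(mask.sum()),
            }
        )
        next_label += 1
    return records


# --------------------------------------------------------------------------- #
# entry points


def generate_scene(spec: SceneSpec) -> tuple[TiledImage, GroundTruth]:
    """Render a scene spec into a pyramidal image plus ground truth.

    Deterministic: the same spec always produces byte-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    canvas = np.full((h, w, spec.n_channels), spec.background, dtype=np.float32)
    if spec.background_noise_sd > 0:
        canvas += rng.normal(
            0.0, spec.background_noise_sd, size=canvas.shape
        ).astype(np.float32)

    gt = GroundTruth()
    region_labels = np.zeros((h, w), dtype=np.int32)
    blob_labels = np.zeros((h, w), dtype=np.int32)
    fibre_labels = np.zeros((h, w), dtype=np.int32)
    object_labels = np.zeros((h, w), dtype=np.int32)
    regions: list = []
    blobs: list = []
    fibres: list = []
    objects: list = []
    class_index = 0
    for el in spec.elements:
        if isinstance(el, TextureRegionSpec):
            class_index += 1
            regions.append(
                _render_texture_region(canvas, region_labels, el, class_index, rng)
            )
        elif isinstance(el, BlobFieldSpec):
            blobs.extend(_render_blob_field(canvas, blob_labels, el, rng))
        elif isinstance(el, FibreSetSpec):
            fibres.extend(_render_fibre_set(canvas, fibre_labels, el, rng))
        elif isinstance(el, CompositeFieldSpec):
            objects.extend(_render_composite_field(canvas, object_labels, el, rng))
        else:  # pragma: no cover
            raise ValueError(f"unknown element kind {el!r}")

    np.clip(canvas, 0.0, 1.0, out=canvas)
    image = build_pyramid(
        canvas, tile_size=spec.tile_size, factor=spec.pyramid_factor
    )
    gt.labels = {
        "regions": region_labels,
        "blobs": blob_labels,
        "fibres": fibre_labels,
        "objects": object_labels,
    }
    gt.records = {
        "regions": regions,
        "blobs": blobs,
        "fibres": fibres,
        "objects": objects,
    }
    return image, gt


def scene_to_json(spec: SceneSpec) -> str:
    d = dataclasses.asdict(spec)
    return json.dumps(d, indent=2)


def scene_from_json(text: str) -> SceneSpec:
    d = json.loads(text)
    elements = []
    for e in d.get("elements", []):
        cls = _KIND_MAP[e["kind"]]
        kwargs = dict(e)
        for k, v in list(kwargs.items()):
            if isinstance(v, list) and k in ("radius", "length"):
                kwargs[k] = tuple(v)
            if k == "polygon" and isinstance(v, list):
                kwargs[k] = [tuple(p) for p in v]
        elements.append(cls(**kwargs))
    d["elements"] = elements
    return SceneSpec(**d)
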