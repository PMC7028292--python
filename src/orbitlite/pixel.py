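"""Structure-size pixel classification.

Each pixel is described by statistics of the square *structure-size* window
around it — per channel and per pyramid level: minimum, maximum, mean,
standard deviation, edge factor and the centre-pixel intensity.  The edge
factor of pixel p over window W is

    edge_p = 1/(|W|-1) * sum_{p' in W} (p' - p)^2,

the mean squared deviation of the window from its centre pixel: zero on
flat patches, large on edges and fine texture.  The structure size s (the
window is (2s+1) x (2s+1)) controls how much spatial context enters the
features: small s discriminates fine-grained structure, large s takes more
surrounding tissue context into account.

A linear SVM (one-vs-rest for more than two classes) on z-scored features
turns user-drawn training shapes into a pixel classifier.  Training
subsamples at most 40,000 pixels from all training regions, reports the
training-set accuracy (no cross-validation), and raises a warning flag when
that accuracy falls below 0.85 — the signal that training regions should be
placed differently.

Classification of a whole image runs as a tile map-reduce job; features are
computed per tile from haloed reads so the per-pixel result is bit-identical
to an untiled computation for any tile size.
"""

from __future__ import annotations

import base64
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import shapely.affinity
from scipy import ndimage
from sklearn.svm import LinearSVC

from .annotations import rasterize_polygon
from .engine import LocalExecutor, TileData, TileJob, run_map_reduce
from .image import TiledImage

logger = logging.getLogger(__name__)

__all__ = [
    "ACCURACY_WARNING_THRESHOLD",
    "TRAINING_PIXEL_CAP",
    "FeatureConfig",
    "TrainingShape",
    "PixelClassifierModel",
    "ClassificationResult",
    "edge_factor",
    "feature_maps",
    "point_features",
    "region_features",
    "assemble_training_set",
    "train_pixel_classifier",
    "classify_region",
    "classify_level",
    "classify_image",
    "save_model",
    "load_model",
]

ACCURACY_WARNING_THRESHOLD = 0.85
TRAINING_PIXEL_CAP = 40_000
FEATURE_NAMES = ("min", "max", "mean", "sd", "edge", "centre")


@dataclass
class FeatureConfig:
    """Feature-extraction configuration.

    levels are *relative* pyramid offsets from the working level, so a model
    trained at full resolution can be reapplied at a coarser working level
    (exclusion models) with the same relative context.
    """

    structure_size: int = 5
    levels: tuple[int, ...] = (0, 1)
    channels: tuple[int, ...] | None = None  # None = all channels

    @property
    def n_features_per_channel(self) -> int:
        return len(self.levels) * len(FEATURE_NAMES)


@dataclass
class TrainingShape:
    """A user-drawn training region: class label + geometry on one image."""

    class_name: str
    geometry: object  # shapely polygon, level-0 (or working-level) coords
    image_index: int = 0


@dataclass
class PixelClassifierModel:
    class_names: tuple[str, ...]
    config: FeatureConfig
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    weights: np.ndarray          # (1, d) binary or (k, d) one-vs-rest
    biases: np.ndarray
    training_accuracy: float
    low_accuracy_warning: bool
    include_flags: tuple[bool, ...] | None = None  # True = class included
    class_colors: tuple[str, ...] = ()

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def decision(self, X: np.ndarray) -> np.ndarray:
        Z = (X - self.feature_mean) / self.feature_sd
        return Z @ self.weights.T + self.biases

    def predict(self, X: np.ndarray) -> np.ndarray:
        d = self.decision(X)
        if self.n_classes == 2:
            return (d[:, 0] > 0).astype(np.int32)
        return np.argmax(d, axis=1).astype(np.int32)


@dataclass
class ClassificationResult:
    class_names: tuple[str, ...]
    counts: np.ndarray           # per-class active-pixel counts
    include_flags: tuple[bool, ...] | None = None

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def ratios(self) -> np.ndarray:
        t = self.counts.sum()
        return self.counts / t if t else np.zeros_like(self.counts, dtype=float)

    @property
    def included_ratios(self) -> dict[str, float] | None:
        """Per-class ratio relative to the included-class total, e.g. the
        fibrotic/(fibrotic+normal) recipe of the IPF workflow."""
        if self.include_flags is None:
            return None
        inc = np.asarray(self.include_flags, dtype=bool)
        denom = self.counts[inc].sum()
        if denom == 0:
            return {n: 0.0 for n, f in zip(self.class_names, inc) if f}
        return {
            n: float(c / denom)
            for n, c, f in zip(self.class_names, self.counts, inc)
            if f
        }


# --------------------------------------------------------------------------- #
# features


def edge_factor(window: np.ndarray, centre: float | None = None) -> float:
    """Edge factor of a structure window (mean squared deviation from the
    centre pixel, normalized by |W|-1).  Shift-invariant and >= 0."""
    w = np.asarray(window, dtype=np.float64)
    n = w.size
    if n < 2:
        raise ValueError("structure window needs at least 2 pixels")
    if centre is None:
        if w.ndim != 2 or w.shape[0] % 2 == 0 or w.shape[1] % 2 == 0:
            raise ValueError("centre not given and window has no middle pixel")
        centre = float(w[w.shape[0] // 2, w.shape[1] // 2])
    return float(np.sum((w - centre) ** 2) / (n - 1))


def feature_maps(channel: np.ndarray, s: int) -> np.ndarray:
    """All six feature maps of a 2-D channel, stacked (6, h, w).

    Boundary handling is mirror reflection, matching the padding used for
    tile halos, so per-tile and whole-image computation agree exactly.
    """
    a = np.asarray(channel, dtype=np.float64)
    size = 2 * s + 1
    n = size * size
    mn = ndimage.minimum_filter(a, size=size, mode="mirror")
    mx = ndimage.maximum_filter(a, size=size, mode="mirror")
    m1 = ndimage.uniform_filter(a, size=size, mode="mirror")
    m2 = ndimage.uniform_filter(a * a, size=size, mode="mirror")
    var = np.clip(m2 - m1 * m1, 0.0, None)
    sd = np.sqrt(var)
    edge = np.clip(n * (m2 - 2.0 * a * m1 + a * a) / (n - 1), 0.0, None)
    return np.stack([mn, mx, m1, sd, edge, a])


def _channel_indices(image: TiledImage, config: FeatureConfig) -> tuple[int, ...]:
    return (
        config.channels
        if config.channels is not None
        else tuple(range(image.n_channels))
    )


def point_features(
    image: TiledImage,
    xs: np.ndarray,
    ys: np.ndarray,
    config: FeatureConfig,
    base_level: int = 0,
) -> np.ndarray:
    """Feature matrix (n, d) for points given in base-level coordinates.

    Feature maps are computed over the full level rasters (the training
    path; training images are small).  Layout: channel-major, then level,
    then the six statistics.
    """
    xs = np.asarray(xs, dtype=np.int64)
    ys = np.asarray(ys, dtype=np.int64)
    chans = _channel_indices(image, config)
    cols = []
    for c in chans:
        for dl in config.levels:
            lvl = min(base_level + dl, image.n_levels - 1)
            scale = image.factor ** (lvl - base_level)
            arr = image.levels[lvl][:, :, c]
            maps = feature_maps(arr, config.structure_size)
            h, w = arr.shape
            j = np.minimum(xs // scale, w - 1)
            i = np.minimum(ys // scale, h - 1)
            cols.append(maps[:, i, j].T)  # (n, 6)
    return np.concatenate(cols, axis=1)


def region_features(
    image: TiledImage,
    x0: int,
    y0: int,
    w: int,
    h: int,
    config: FeatureConfig,
    base_level: int = 0,
) -> np.ndarray:
    """Feature matrix (h*w, d) for a base-level pixel window, computed from
    haloed level reads only — the tile-classification path.  Identical to
    :func:`point_features` on the same pixels."""
    bh, bw = image.level_shape(base_level)
    if x0 < 0 or y0 < 0 or x0 + w > bw or y0 + h > bh:
        raise IndexError(
            f"window ({x0},{y0},{w},{h}) outside level-{base_level} bounds {bw}x{bh}"
        )
    s = config.structure_size
    chans = _channel_indices(image, config)
    cols = []
    for c in chans:
        for dl in config.levels:
            lvl = min(base_level + dl, image.n_levels - 1)
            scale = image.factor ** (lvl - base_level)
            lh, lw = image.level_shape(lvl)
            u0 = min(x0 // scale, lw - 1)
            u1 = min((x0 + w - 1) // scale, lw - 1) + 1
            v0 = min(y0 // scale, lh - 1)
            v1 = min((y0 + h - 1) // scale, lh - 1) + 1
            region = image.read_region(
                lvl, u0 - s, v0 - s, (u1 - u0) + 2 * s, (v1 - v0) + 2 * s
            )[:, :, c]
            maps = feature_maps(region, s)[:, s : s + (v1 - v0), s : s + (u1 - u0)]
            xs = np.minimum(np.arange(x0, x0 + w) // scale, lw - 1) - u0
            ys = np.minimum(np.arange(y0, y0 + h) // scale, lh - 1) - v0
            jj = np.broadcast_to(xs, (h, w))
            ii = np.broadcast_to(ys[:, None], (h, w))
            cols.append(maps[:, ii.ravel(), jj.ravel()].T)
    return np.concatenate(cols, axis=1)


# --------------------------------------------------------------------------- #
# training


def assemble_training_set(
    shapes: list[TrainingShape],
    images: list[TiledImage],
    config: FeatureConfig,
    cap: int = TRAINING_PIXEL_CAP,
    seed: int = 0,
    base_level: int = 0,
) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    """Collect (features, labels) from training shapes.

    The union of all pixels inside the shapes defines the training set; if
    it exceeds ``cap`` pixels a uniform random subsample of exactly ``cap``
    pixels is drawn (reproducible from ``seed``).  Returns the class-name
    tuple in sorted order; labels are indices into it.
    """
    class_names = tuple(sorted({s.class_name for s in shapes}))
    name_to_idx = {n: i for i, n in enumerate(class_names)}
    per_image: dict[int, list[tuple[np.ndarray, np.ndarray, int]]] = {}
    class_pixels = {n: 0 for n in class_names}
    for sh in shapes:
        img = images[sh.image_index]
        scale = img.factor**base_level
        geom = (
            shapely.affinity.scale(
                sh.geometry, 1 / scale, 1 / scale, origin=(0, 0)
            )
            if scale != 1
            else sh.geometry
        )
        lh, lw = img.level_shape(base_level)
        m = rasterize_polygon(geom, lh, lw)
        ys, xs = np.nonzero(m)
        class_pixels[sh.class_name] += len(xs)
        if len(xs):
            per_image.setdefault(sh.image_index, []).append(
                (xs, ys, name_to_idx[sh.class_name])
            )
    for n, c in class_pixels.items():
        if c == 0:
            raise ValueError(f"training class {n!r} has zero pixels")

    all_xs, all_ys, all_img, all_lab = [], [], [], []
    for idx in sorted(per_image):
        for xs, ys, lab in per_image[idx]:
            all_xs.append(xs)
            all_ys.append(ys)
            all_img.append(np.full(len(xs), idx))
            all_lab.append(np.full(len(xs), lab))
    xs = np.concatenate(all_xs)
    ys = np.concatenate(all_ys)
    img_idx = np.concatenate(all_img)
    labels = np.concatenate(all_lab).astype(np.int32)

    total = len(xs)
    if total > cap:
        rng = np.random.default_rng(seed)
        keep = rng.choice(total, size=cap, replace=False)
        keep.sort()
        xs, ys, img_idx, labels = xs[keep], ys[keep], img_idx[keep], labels[keep]
        logger.info("training set capped: %d of %d pixels", cap, total)
    support = np.bincount(labels, minlength=len(class_names))
    logger.info(
        "training support per class: %s",
        dict(zip(class_names, support.tolist())),
    )

    # rows are grouped by ascending image index (built that way above), so
    # per-image feature blocks concatenate back into the original row order
    feats = np.empty((len(xs), 0))
    blocks = []
    for idx in sorted(set(img_idx.tolist())):
        sel = img_idx == idx
        blocks.append(
            point_features(images[idx], xs[sel], ys[sel], config, base_level)
        )
    feats = np.concatenate(blocks, axis=0) if blocks else feats
    return feats, labels, class_names


def train_pixel_classifier(
    features: np.ndarray,
    labels: np.ndarray,
    class_names: tuple[str, ...],
    config: FeatureConfig,
    seed: int = 0,
    include_flags: tuple[bool, ...] | None = None,
) -> PixelClassifierModel:
    """Fit the linear SVM on z-scored features and report training accuracy.

    Emits a structured warning (and sets ``low_accuracy_warning``) when the
    training-set accuracy is below 0.85.
    """
    present = np.unique(labels)
    if len(present) < 2:
        raise ValueError("need at least 2 classes with training pixels")
    mean = features.mean(axis=0)
    sd = features.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (features - mean) / sd
    svc = LinearSVC(C=1.0, random_state=int(seed) % (2**31), max_iter=5000)
    svc.fit(Z, labels)
    acc = float(svc.score(Z, labels))
    warn = acc < ACCURACY_WARNING_THRESHOLD
    if warn:
        logger.warning(
            "training accuracy %.3f below %.2f: training regions should be "
            "placed differently",
            acc,
            ACCURACY_WARNING_THRESHOLD,
        )
    return PixelClassifierModel(
        class_names=class_names,
        config=config,
        feature_mean=mean,
        feature_sd=sd,
        weights=np.atleast_2d(svc.coef_.copy()),
        biases=np.atleast_1d(svc.intercept_.copy()),
        training_accuracy=acc,
        low_accuracy_warning=warn,
        include_flags=include_flags,
    )


# --------------------------------------------------------------------------- #
# inference


def classify_region(
    model: PixelClassifierModel,
    image: TiledImage,
    x0: int,
    y0: int,
    w: int,
    h: int,
    base_level: int = 0,
) -> np.ndarray:
    """Class-index map (h, w) for a pixel window at a working level."""
    X = region_features(image, x0, y0, w, h, model.config, base_level)
    return model.predict(X).reshape(h, w)


def classify_level(
    model: PixelClassifierModel, image: TiledImage, level: int
) -> np.ndarray:
    """Class-index map of a whole pyramid level (exclusion-model path)."""
    lh, lw = image.level_shape(level)
    return classify_region(model, image, 0, 0, lw, lh, base_level=level)


def _active_bitmap(mask, x0: int, y0: int, w: int, h: int) -> np.ndarray:
    if mask is None:
        return np.ones((h, w), dtype=bool)
    if isinstance(mask, np.ndarray):
        return mask[y0 : y0 + h, x0 : x0 + w]
    return mask(x0, y0, w, h)  # callable protocol


def classify_image(
    model: PixelClassifierModel,
    image: TiledImage,
    roi=None,
    mask=None,
    executor: LocalExecutor | None = None,
) -> ClassificationResult:
    """Per-class active-pixel counts over the ROI, as a tile job.

    ``mask`` is an optional active-pixel filter (full-image boolean array or
    a callable ``(x0, y0, w, h) -> bitmap``), e.g. from a classification or
    segmentation mask model.  Masks restrict the counted pixels but never
    change the measured ROI area.
    """
    k = model.n_classes

    def map_fn(td: TileData) -> np.ndarray:
        x0, y0, w, h = td.footprint
        cmap = classify_region(model, image, x0, y0, w, h)
        active = _active_bitmap(mask, x0, y0, w, h)
        if roi is not None:
            active = active & roi.contains_grid(x0, y0, w, h)
        return np.bincount(cmap[active].ravel(), minlength=k).astype(np.int64)

    job = TileJob(
        image=image,
        map_fn=map_fn,
        reduce_fn=lambda parts: (
            np.sum(parts, axis=0) if len(parts) else np.zeros(k, dtype=np.int64)
        ),
        roi=roi,
        halo=0,
    )
    counts = run_map_reduce(job, executor)
    return ClassificationResult(
        class_names=model.class_names,
        counts=np.asarray(counts, dtype=np.int64),
        include_flags=model.include_flags,
    )


def classification_mask(
    mask_model: PixelClassifierModel, image: TiledImage
):
    """Active-pixel filter from a classification-mask model: a pixel is
    active when its class is include-flagged.  Returns a callable suitable
    for the ``mask`` argument of :func:`classify_image`."""
    if mask_model.include_flags is None:
        raise ValueError("mask model needs include/exclude flags per class")
    inc = np.asarray(mask_model.include_flags, dtype=bool)

    def active(x0: int, y0: int, w: int, h: int) -> np.ndarray:
        cmap = classify_region(mask_model, image, x0, y0, w, h)
        return inc[cmap]

    return active


# --------------------------------------------------------------------------- #
# model persistence: JSON header + base64-embedded float64 arrays


def _enc(a: np.ndarray) -> dict:
    a = np.ascontiguousarray(a, dtype=np.float64)
    return {"shape": list(a.shape), "data": base64.b64encode(a.tobytes()).decode()}


def _dec(d: dict) -> np.ndarray:
    return np.frombuffer(
        base64.b64decode(d["data"]), dtype=np.float64
    ).reshape(d["shape"])


def save_model(model: PixelClassifierModel, path: str) -> None:
    doc = {
        "format": "orbitlite-pixel-model",
        "version": 1,
        "class_names": list(model.class_names),
        "structure_size": model.config.structure_size,
        "levels": list(model.config.levels),
        "channels": (
            list(model.config.channels) if model.config.channels else None
        ),
        "training_accuracy": model.training_accuracy,
        "low_accuracy_warning": model.low_accuracy_warning,
        "include_flags": (
            list(model.include_flags) if model.include_flags else None
        ),
        "feature_mean": _enc(model.feature_mean),
        "feature_sd": _enc(model.feature_sd),
        "weights": _enc(model.weights),
        "biases": _enc(model.biases),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path: str) -> PixelClassifierModel:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != "orbitlite-pixel-model":
        raise ValueError(f"{path!r} is not a pixel-classifier model file")
    return PixelClassifierModel(
        class_names=tuple(doc["class_names"]),
        config=FeatureConfig(
            structure_size=doc["structure_size"],
            levels=tuple(doc["levels"]),
            channels=tuple(doc["channels"]) if doc["channels"] else None,
        ),
        feature_mean=_dec(doc["feature_mean"]),
        feature_sd=_dec(doc["feature_sd"]),
        weights=_dec(doc["weights"]),
        biases=_dec(doc["biases"]),
        training_accuracy=doc["training_accuracy"],
        low_accuracy_warning=doc["low_accuracy_warning"],
        include_flags=(
            tuple(doc["include_flags"]) if doc["include_flags"] else None
        ),
    )
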