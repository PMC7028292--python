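"""Pyramidal tiled-image model.

A :class:`TiledImage` is an in-memory multi-resolution pyramid over a raster.
Level 0 is full resolution; each coarser level is produced by block-averaging
with a fixed integer factor (default 4, the usual WSI convention).  Every
level is addressed by square tiles (default 512 px); edge tiles may be
partial.  Pixel data are held as float32 in [0, 1] — 8- and 16-bit inputs
are scaled by their type maximum on ingest and rescaled on export.

Coordinates are 0-based, x rightward, y downward.  Tile indices are
``(tx, ty)`` (column, row); iteration over a grid is row-major
(``ty`` outer, ``tx`` inner).
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import numpy as np
import tifffile

__all__ = [
    "TiledImage",
    "build_pyramid",
    "image_id",
    "read_image",
    "write_image",
]

DEFAULT_TILE_SIZE = 512
DEFAULT_FACTOR = 4


def _as_3d(arr: np.ndarray) -> np.ndarray:
    """Promote a 2-D raster to (h, w, 1)."""
    if arr.ndim == 2:
        return arr[:, :, None]
    if arr.ndim == 3:
        return arr
    raise ValueError(f"expected 2-D or 3-D raster, got shape {arr.shape}")


def _normalize(arr: np.ndarray) -> tuple[np.ndarray, np.dtype]:
    """Scale integer rasters to float32 in [0, 1]; floats pass through."""
    arr = _as_3d(np.asarray(arr))
    if arr.dtype == np.uint8:
        return (arr.astype(np.float32) / 255.0), np.dtype(np.uint8)
    if arr.dtype == np.uint16:
        return (arr.astype(np.float32) / 65535.0), np.dtype(np.uint16)
    if np.issubdtype(arr.dtype, np.floating):
        out = arr.astype(np.float32, copy=False)
        if out.size and (out.min() < 0.0 or out.max() > 1.0):
            raise ValueError("float input must already lie in [0, 1]")
        return out, np.dtype(np.uint8)
    raise ValueError(f"unsupported pixel type {arr.dtype}")


def _block_mean(arr: np.ndarray, f: int) -> np.ndarray:
    """Downsample (h, w, c) by factor f with partial edge blocks averaged
    over the pixels actually present, so level dims follow ceil(d / f)."""
    h, w, c = arr.shape
    oh, ow = math.ceil(h / f), math.ceil(w / f)
    ys = np.arange(0, h, f)
    xs = np.arange(0, w, f)
    # reduceat sums each block along one axis at a time
    s = np.add.reduceat(np.add.reduceat(arr, ys, axis=0), xs, axis=1)
    ny = np.minimum(ys + f, h) - ys
    nx = np.minimum(xs + f, w) - xs
    counts = np.outer(ny, nx).astype(np.float32)
    return (s / counts[:, :, None]).astype(np.float32)


@dataclass
class TiledImage:
    """Multi-resolution tiled raster.

    Attributes
    ----------
    levels : list of (h, w, c) float32 arrays in [0, 1]; index 0 is full
        resolution.
    tile_size : side of the square tiles used to address every level.
    factor : integer downsampling factor between consecutive levels.
    source_dtype : dtype the image is exported/hashed as (uint8 or uint16).
    channel_names : semantic tag per channel ("R","G","B" or stain names).
    """

    levels: list[np.ndarray]
    tile_size: int = DEFAULT_TILE_SIZE
    factor: int = DEFAULT_FACTOR
    source_dtype: np.dtype = field(default_factory=lambda: np.dtype(np.uint8))
    channel_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.levels:
            raise ValueError("empty raster")
        self.levels = [_as_3d(lv) for lv in self.levels]
        if not self.channel_names:
            c = self.levels[0].shape[2]
            self.channel_names = (
                ("R", "G", "B")[:c] if c <= 3 else tuple(f"ch{i}" for i in range(c))
            )

    # ------------------------------------------------------------------ geometry

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @property
    def width(self) -> int:
        return self.levels[0].shape[1]

    @property
    def height(self) -> int:
        return self.levels[0].shape[0]

    @property
    def n_channels(self) -> int:
        return self.levels[0].shape[2]

    def level_shape(self, level: int) -> tuple[int, int]:
        """(height, width) of a pyramid level."""
        self._check_level(level)
        return self.levels[level].shape[:2]

    def grid_shape(self, level: int) -> tuple[int, int]:
        """(n_tiles_x, n_tiles_y) of the tile grid at a level."""
        h, w = self.level_shape(level)
        return math.ceil(w / self.tile_size), math.ceil(h / self.tile_size)

    def _check_level(self, level: int) -> None:
        if not 0 <= level < self.n_levels:
            raise IndexError(f"level {level} out of range [0, {self.n_levels})")

    # ------------------------------------------------------------------ reading

    def read_region(
        self, level: int, x0: int, y0: int, w: int, h: int
    ) -> np.ndarray:
        """Read an arbitrary window of a level; parts outside the image are
        mirror-padded (reflection about the border, edge row not repeated)."""
        self._check_level(level)
        arr = self.levels[level]
        H, W = arr.shape[:2]
        ix0, iy0 = max(0, x0), max(0, y0)
        ix1, iy1 = min(W, x0 + w), min(H, y0 + h)
        if ix0 >= ix1 or iy0 >= iy1:
            raise IndexError("window lies entirely outside the image")
        sub = arr[iy0:iy1, ix0:ix1]
        pads = (
            (iy0 - y0, (y0 + h) - iy1),
            (ix0 - x0, (x0 + w) - ix1),
            (0, 0),
        )
        if any(p for pair in pads[:2] for p in pair):
            sub = np.pad(sub, pads, mode="reflect")
        return sub

    def read_tile(
        self, level: int, tx: int, ty: int, halo: int = 0
    ) -> tuple[np.ndarray, tuple[int, int]]:
        """Read tile ``(tx, ty)`` of a level, expanded by ``halo`` pixels on
        every side (mirror-padded beyond the image bounds).

        Returns ``(raster, offset)`` where ``offset`` is the (x, y) position
        of the raster's top-left corner in level coordinates (negative when
        the halo extends past the origin).
        """
        if halo < 0:
            raise ValueError("halo must be >= 0")
        ntx, nty = self.grid_shape(level)
        if not (0 <= tx < ntx and 0 <= ty < nty):
            raise IndexError(f"tile ({tx}, {ty}) out of range for grid {ntx}x{nty}")
        h, w = self.level_shape(level)
        ts = self.tile_size
        x0, y0 = tx * ts, ty * ts
        x1, y1 = min(x0 + ts, w), min(y0 + ts, h)
        raster = self.read_region(
            level, x0 - halo, y0 - halo, (x1 - x0) + 2 * halo, (y1 - y0) + 2 * halo
        )
        return raster, (x0 - halo, y0 - halo)

    def tile_footprint(
        self, level: int, tx: int, ty: int
    ) -> tuple[int, int, int, int]:
        """(x0, y0, w, h) of a tile in level coordinates (clipped to bounds)."""
        h, w = self.level_shape(level)
        ts = self.tile_size
        x0, y0 = tx * ts, ty * ts
        return x0, y0, min(ts, w - x0), min(ts, h - y0)

    # ------------------------------------------------------------------ export

    def to_integer(self, level: int = 0) -> np.ndarray:
        """Level raster rescaled back to the source integer dtype."""
        vmax = np.iinfo(self.source_dtype).max
        return np.round(self.levels[level] * vmax).astype(self.source_dtype)


def build_pyramid(
    base: np.ndarray,
    tile_size: int = DEFAULT_TILE_SIZE,
    factor: int = DEFAULT_FACTOR,
    channel_names: tuple[str, ...] = (),
) -> TiledImage:
    """Build a pyramid from a full-resolution raster.

    Coarser levels are block averages; levels are appended until the top
    level fits inside a single tile.
    """
    if factor < 2:
        raise ValueError("pyramid factor must be >= 2")
    arr = np.asarray(base)
    if arr.size == 0:
        raise ValueError("empty raster")
    lvl0, dtype = _normalize(arr)
    levels = [lvl0]
    while max(levels[-1].shape[:2]) >= tile_size and min(levels[-1].shape[:2]) >= factor:
        levels.append(_block_mean(levels[-1], factor))
    return TiledImage(
        levels=levels,
        tile_size=tile_size,
        factor=factor,
        source_dtype=dtype,
        channel_names=channel_names,
    )


def image_id(image: TiledImage) -> str:
    """32-hex md5 digest of the level-0 pixel bytes.

    The digest is taken over the image in its source integer dtype, row-major
    with channels interleaved, so two images with identical full-resolution
    content share an ID regardless of how their pyramids were built.
    """
    raw = image.to_integer(0)
    if raw.shape[2] == 1:
        raw = raw[:, :, 0]
    return hashlib.md5(np.ascontiguousarray(raw).tobytes()).hexdigest()


def write_image(image: TiledImage, path: str) -> None:
    """Write a pyramidal tiled TIFF (one page per level, 512-px tiles)."""
    ts = image.tile_size
    with tifffile.TiffWriter(path) as tw:
        for lv in range(image.n_levels):
            raw = image.to_integer(lv)
            photometric = "rgb" if raw.shape[2] == 3 else "minisblack"
            if raw.shape[2] == 1:
                raw = raw[:, :, 0]
            tw.write(
                raw,
                tile=(ts, ts),
                photometric=photometric,
                subfiletype=0 if lv == 0 else 1,
            )


def read_image(
    path: str,
    tile_size: int = DEFAULT_TILE_SIZE,
    factor: int = DEFAULT_FACTOR,
) -> TiledImage:
    """Read a TIFF or PNG into a :class:`TiledImage`.

    Only the full-resolution plane is trusted; the pyramid is (re)built by
    block averaging so that level geometry is consistent regardless of how
    the file was produced.  Plain single-level files are pyramidized the
    same way.
    """
    try:
        if path.lower().endswith((".tif", ".tiff")):
            base = tifffile.imread(path, key=0)
        else:
            import imageio.v3 as iio

            base = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover - corrupt-file path
        raise OSError(f"cannot read image file {path!r}: {exc}") from exc
    return build_pyramid(base, tile_size=tile_size, factor=factor)
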