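"""Tile-based map-reduce execution.

Every analysis in this package runs as a :class:`TileJob`: a *map* function
is applied independently to each tile of a pyramidal image (optionally
expanded by a halo so context-dependent operators see across tile borders),
and a *reduce* function combines the per-tile partial results.  For simple
counting analyses the reduce step is a plain sum; object-level analyses
reduce with a cross-tile merge.

The shipped executor runs map calls in a local thread pool.  The contract —
every tile's partial result delivered exactly once, final result independent
of scheduling order and worker count — is what alternative (distributed)
executors would have to honour; reduce functions receive partial results in
deterministic row-major tile order regardless of completion order.
"""

from __future__ import annotations

import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Any, Callable, Sequence

from .image import TiledImage

logger = logging.getLogger(__name__)

__all__ = [
    "TileData",
    "TileJob",
    "LocalExecutor",
    "TileJobError",
    "enumerate_tiles",
    "run_map_reduce",
]


@dataclass
class TileData:
    """Everything a map function sees for one tile."""

    image: TiledImage
    level: int
    tx: int
    ty: int
    raster: Any            # haloed pixel data, float32 (h, w, c)
    offset: tuple[int, int]  # (x, y) of raster origin in level coords
    footprint: tuple[int, int, int, int]  # (x0, y0, w, h) without halo
    halo: int


@dataclass
class TileJob:
    image: TiledImage
    map_fn: Callable[[TileData], Any]
    reduce_fn: Callable[[Sequence[Any]], Any]
    level: int = 0
    roi: Any = None        # RegionPredicate or None (whole image)
    halo: int = 0


@dataclass
class LocalExecutor:
    """Multi-threaded local executor."""

    name: str = "local"
    max_workers: int = 1


class TileJobError(RuntimeError):
    """A map function failed; carries the tile it failed on."""

    def __init__(self, tile: tuple[int, int], cause: BaseException):
        super().__init__(f"map function failed on tile {tile}: {cause!r}")
        self.tile = tile
        self.cause = cause


def enumerate_tiles(
    image: TiledImage, level: int, roi: Any = None
) -> list[tuple[int, int]]:
    """Tiles of a level whose level-0 footprint intersects the ROI.

    Order is deterministic row-major (ty outer, tx inner).  With no ROI all
    tiles are returned.  The test uses the ROI's supporting geometry (union
    of ROI and inclusion polygons), so tiles are never dropped because of
    exclusions — excluded pixels simply contribute nothing downstream.
    """
    ntx, nty = image.grid_shape(level)
    tiles = [(tx, ty) for ty in range(nty) for tx in range(ntx)]
    if roi is None:
        return tiles
    scale = image.factor**level
    out = []
    for tx, ty in tiles:
        x0, y0, w, h = image.tile_footprint(level, tx, ty)
        # footprint in level-0 coordinates
        if roi.intersects_bbox(
            x0 * scale, y0 * scale, (x0 + w) * scale, (y0 + h) * scale
        ):
            out.append((tx, ty))
    return out


def _run_one(job: TileJob, tx: int, ty: int) -> Any:
    raster, offset = job.image.read_tile(job.level, tx, ty, halo=job.halo)
    footprint = job.image.tile_footprint(job.level, tx, ty)
    data = TileData(
        image=job.image,
        level=job.level,
        tx=tx,
        ty=ty,
        raster=raster,
        offset=offset,
        footprint=footprint,
        halo=job.halo,
    )
    try:
        return job.map_fn(data)
    except Exception as exc:
        raise TileJobError((tx, ty), exc) from exc


def run_map_reduce(job: TileJob, executor: LocalExecutor | None = None) -> Any:
    """Execute a tile job and reduce its partial results.

    Partial results are passed to ``reduce_fn`` in row-major tile order so
    the outcome is identical for any worker count; a map failure aborts the
    job with the failing tile's index (fail-fast).
    """
    executor = executor or LocalExecutor()
    tiles = enumerate_tiles(job.image, job.level, job.roi)
    logger.debug("tile job: %d tiles, %d workers", len(tiles), executor.max_workers)
    if executor.max_workers <= 1 or len(tiles) <= 1:
        partials = [_run_one(job, tx, ty) for tx, ty in tiles]
    else:
        with ThreadPoolExecutor(max_workers=executor.max_workers) as pool:
            futures = [pool.submit(_run_one, job, tx, ty) for tx, ty in tiles]
            partials = [f.result() for f in futures]
    return job.reduce_fn(partials)
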