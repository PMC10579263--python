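"""Tiling slides into 448x448 tiles and partitioning tiles 7:2:1.

A slide is cut on a regular non-overlapping grid; every annotation polygon
is clipped (exactly, via shapely box intersection) to each tile it touches
and translated into tile-local coordinates, so the per-tile clipped pixel
counts of a finding sum to its slide-level count.  Tiles are then assigned
to train/validation/test subsets by a seeded uniform shuffle.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely.geometry as sgeom

from .annotation_io import AnnotatedRegion, AnnotationSet, Polygon

logger = logging.getLogger(__name__)

TILE_SIZE = 448
DEFAULT_RATIOS = (0.7, 0.2, 0.1)
SUBSETS = ("train", "validation", "test")


@dataclass
class Tile:
    """One grid tile of a slide with its clipped annotations."""

    parent_slide_id: str
    row: int
    col: int
    image: np.ndarray  # (tile, tile, 3) uint8
    annotations: AnnotationSet  # tile-local coordinates
    tile_size: int = TILE_SIZE

    @property
    def tile_id(self) -> str:
        return f"{self.parent_slide_id}_r{self.row}_c{self.col}"

    @property
    def origin(self) -> tuple[int, int]:
        """(y, x) of the tile's top-left corner in slide pixels."""
        return (self.tile_size * self.row, self.tile_size * self.col)


@dataclass
class DatasetSplit:
    """Tile-id -> subset assignment with its provenance."""

    assignment: dict[str, str]
    ratios: tuple[float, ...] = DEFAULT_RATIOS
    seed: int = 0

    def subset(self, name: str) -> list[str]:
        return [t for t, s in self.assignment.items() if s == name]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tile_id": list(self.assignment),
                "subset": list(self.assignment.values()),
                "seed": self.seed,
            }
        )


def _clip_polygon_to_box(
    polygon: Polygon, x0: float, y0: float, x1: float, y1: float
) -> tuple[list[Polygon], int]:
    """Exact intersection of a simple polygon with an axis-aligned box.

    Returns (pieces, n_dropped): zero or more polygons in the original
    coordinate frame, plus the number of degenerate slivers (fewer than 3
    distinct vertices or zero area) that were discarded.
    """
    xmin, ymin, xmax, ymax = polygon.bounds()
    if xmin >= x1 or xmax <= x0 or ymin >= y1 or ymax <= y0:
        return [], 0
    if xmin >= x0 and xmax <= x1 and ymin >= y0 and ymax <= y1:
        return [polygon], 0
    shp = sgeom.Polygon(polygon.vertices)
    if not shp.is_valid:
        shp = shp.buffer(0)
    clipped = shp.intersection(sgeom.box(x0, y0, x1, y1))
    out: list[Polygon] = []
    dropped = 0
    geoms = getattr(clipped, "geoms", [clipped])
    for g in geoms:
        if g.is_empty:
            continue
        if g.geom_type != "Polygon" or g.area <= 0:
            dropped += 1
            continue
        verts = tuple(g.exterior.coords)[:-1]  # drop closing duplicate
        if len({(round(x, 9), round(y, 9)) for x, y in verts}) < 3:
            dropped += 1
            continue
        out.append(Polygon(verts))
    return out, dropped


def tile_grid(
    slide_image: np.ndarray,
    truth: AnnotationSet,
    tile_size: int = TILE_SIZE,
    pad: bool = False,
) -> list[Tile]:
    """Cut a slide into non-overlapping tiles with clipped annotations.

    Every slide pixel is covered exactly once; tiles without any region are
    retained as background tiles.  When dimensions do not divide evenly,
    ``pad=True`` zero-pads the right/bottom edge to the next multiple of
    tile_size (the padding carries no annotations); otherwise an error
    states the remainder.
    """
    height, width = slide_image.shape[:2]
    if (height % tile_size or width % tile_size) and not pad:
        raise ValueError(
            f"slide {height}x{width} does not divide into {tile_size}px tiles "
            f"(remainders {height % tile_size}, {width % tile_size}); "
            "enable pad mode for general inputs"
        )
    n_rows = math.ceil(height / tile_size)
    n_cols = math.ceil(width / tile_size)
    if pad and (height % tile_size or width % tile_size):
        padded = np.zeros(
            (n_rows * tile_size, n_cols * tile_size) + slide_image.shape[2:],
            dtype=slide_image.dtype,
        )
        padded[:height, :width] = slide_image
        slide_image = padded

    dropped = 0
    tiles: list[Tile] = []
    for r in range(n_rows):
        for c in range(n_cols):
            y0, x0 = r * tile_size, c * tile_size
            regions: list[AnnotatedRegion] = []
            for reg in truth.regions:
                pieces, n_dropped = _clip_polygon_to_box(
                    reg.polygon, x0, y0, x0 + tile_size, y0 + tile_size
                )
                dropped += n_dropped
                for piece in pieces:
                    regions.append(
                        AnnotatedRegion(
                            piece.translate(-x0, -y0),
                            reg.finding,
                            image_id=f"{truth.image_id}_r{r}_c{c}",
                        )
                    )
            tiles.append(
                Tile(
                    parent_slide_id=truth.image_id,
                    row=r,
                    col=c,
                    image=slide_image[y0 : y0 + tile_size, x0 : x0 + tile_size],
                    annotations=AnnotationSet(
                        image_id=f"{truth.image_id}_r{r}_c{c}",
                        width=tile_size,
                        height=tile_size,
                        regions=regions,
                        microns_per_pixel=truth.microns_per_pixel,
                    ),
                    tile_size=tile_size,
                )
            )
    if dropped:
        logger.info("dropped %d degenerate clipped regions", dropped)
    return tiles


def stitch_tiles(tiles: list[Tile]) -> np.ndarray:
    """Reassemble tile rasters into the slide raster (exact inverse of tiling)."""
    if not tiles:
        raise ValueError("no tiles to stitch")
    ts = tiles[0].tile_size
    n_rows = max(t.row for t in tiles) + 1
    n_cols = max(t.col for t in tiles) + 1
    out = np.zeros((n_rows * ts, n_cols * ts) + tiles[0].image.shape[2:],
                   dtype=tiles[0].image.dtype)
    for t in tiles:
        out[t.row * ts : (t.row + 1) * ts, t.col * ts : (t.col + 1) * ts] = t.image
    return out


def split(
    tiles: list[Tile] | list[str],
    ratios: tuple[float, float, float] = DEFAULT_RATIOS,
    seed: int = 0,
    by_slide: bool = False,
) -> DatasetSplit:
    """Partition tiles into train/validation/test at the given ratios.

    Assignment is a seeded uniform shuffle followed by contiguous slicing at
    rounded boundaries, so realized subset sizes are within one tile of
    ``round(n * ratio)`` and the same seed always reproduces the same
    partition.  With ``by_slide=True`` whole slides are assigned to one
    subset (leakage control for correlated tiles; off by default).
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1, got {ratios}")
    if not tiles:
        raise ValueError("cannot split zero tiles")
    tile_ids = [t if isinstance(t, str) else t.tile_id for t in tiles]
    if len(set(tile_ids)) != len(tile_ids):
        raise ValueError("duplicate tile ids")

    if by_slide:
        slide_of = {
            tid: (tid.rsplit("_r", 1)[0] if "_r" in tid else tid)
            for tid in tile_ids
        }
        units = sorted(set(slide_of.values()))
    else:
        units = list(tile_ids)

    rng = np.random.default_rng(seed)
    order = [units[i] for i in rng.permutation(len(units))]
    n = len(order)
    n_train = round(n * ratios[0])
    n_val = round(n * ratios[1])
    unit_subset: dict[str, str] = {}
    for i, u in enumerate(order):
        if i < n_train:
            unit_subset[u] = "train"
        elif i < n_train + n_val:
            unit_subset[u] = "validation"
        else:
            unit_subset[u] = "test"

    if by_slide:
        assignment = {tid: unit_subset[slide_of[tid]] for tid in tile_ids}
    else:
        assignment = {tid: unit_subset[tid] for tid in tile_ids}
    return DatasetSplit(assignment=assignment, ratios=tuple(ratios), seed=seed)


__all__ = [
    "DEFAULT_RATIOS",
    "DatasetSplit",
    "SUBSETS",
    "TILE_SIZE",
    "Tile",
    "split",
    "stitch_tiles",
    "tile_grid",
]
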