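"""Eight-fold tile augmentation: the dihedral orbit plus brightness jitter.

Each square tile yields exactly eight image/annotation pairs — the D4
symmetry group of the square (rotations by 0/90/180/270 degrees, each with
and without horizontal reversal) — and every output additionally receives a
multiplicative brightness factor drawn from a configurable range (the
identity geometry, fold 1, is jittered like the rest).  Annotation polygons
undergo exactly the geometric map applied to the raster, so rasterizing a
transformed polygon equals transforming the rasterized original; brightness
never touches geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .annotation_io import AnnotatedRegion, AnnotationSet, Polygon
from .tiling import Tile

DEFAULT_BRIGHTNESS_RANGE = (0.9, 1.1)

#: The eight D4 transforms as (quarter-turns CCW, horizontal flip first).
D4_TRANSFORMS: tuple[tuple[int, bool], ...] = tuple(
    (k, f) for f in (False, True) for k in range(4)
)


def transform_tag(k: int, flipped: bool) -> str:
    return f"rot{90 * k}" + ("_flip" if flipped else "")


@dataclass
class AugmentedTile:
    """One augmented copy of a tile."""

    source_tile_id: str
    tag: str
    image: np.ndarray
    annotations: AnnotationSet
    rotations: int  # quarter-turns CCW applied after the optional flip
    flipped: bool
    brightness: float


def transform_image(image: np.ndarray, k: int, flipped: bool) -> np.ndarray:
    """Apply the D4 element (flip horizontally first, then rotate CCW)."""
    out = np.fliplr(image) if flipped else image
    return np.rot90(out, k).copy()


def inverse_transform_image(image: np.ndarray, k: int, flipped: bool) -> np.ndarray:
    """Inverse of :func:`transform_image` (recovers the original geometry)."""
    out = np.rot90(image, -k)
    return (np.fliplr(out) if flipped else out).copy()


def transform_polygon(polygon: Polygon, k: int, flipped: bool, n: int) -> Polygon:
    """Map polygon coordinates by the same D4 element as the raster.

    On a square raster of side ``n`` with continuous coordinates in
    [0, n]^2: horizontal reversal sends x -> n - x; one CCW quarter-turn
    (matching ``np.rot90``) sends (x, y) -> (y, n - x).  Pixel centres map
    to pixel centres, so the polygon/raster correspondence is exact.
    """
    pts = [(float(x), float(y)) for x, y in polygon.vertices]
    if flipped:
        pts = [(n - x, y) for x, y in pts]
    for _ in range(k % 4):
        pts = [(y, n - x) for x, y in pts]
    return Polygon(tuple(pts))


def _transform_annotations(
    annotations: AnnotationSet, k: int, flipped: bool, image_id: str
) -> AnnotationSet:
    n = annotations.width
    regions = [
        AnnotatedRegion(
            transform_polygon(r.polygon, k, flipped, n), r.finding, image_id=image_id
        )
        for r in annotations.regions
    ]
    return replace(annotations, image_id=image_id, regions=regions)


def augment(
    tile: Tile,
    brightness_range: tuple[float, float] = DEFAULT_BRIGHTNESS_RANGE,
    seed: int = 0,
) -> list[AugmentedTile]:
    """The eight-fold augmentation of one square tile, deterministic in seed."""
    h, w = tile.image.shape[:2]
    if h != w:
        raise ValueError(f"augmentation requires a square tile, got {h}x{w}")
    if tile.annotations.width != w or tile.annotations.height != h:
        raise ValueError("tile annotation dimensions disagree with the raster")
    rng = np.random.default_rng(seed)
    factors = rng.uniform(*brightness_range, size=len(D4_TRANSFORMS))

    out: list[AugmentedTile] = []
    for (k, flipped), factor in zip(D4_TRANSFORMS, factors):
        tag = transform_tag(k, flipped)
        image = transform_image(tile.image, k, flipped)
        image = np.clip(
            image.astype(np.float64) * factor, 0, 255
        ).astype(np.uint8)
        aug_id = f"{tile.tile_id}_aug_{tag}"
        out.append(
            AugmentedTile(
                source_tile_id=tile.tile_id,
                tag=tag,
                image=image,
                annotations=_transform_annotations(
                    tile.annotations, k, flipped, aug_id
                ),
                rotations=k,
                flipped=flipped,
                brightness=float(factor),
            )
        )
    return out


__all__ = [
    "AugmentedTile",
    "D4_TRANSFORMS",
    "DEFAULT_BRIGHTNESS_RANGE",
    "augment",
    "inverse_transform_image",
    "transform_image",
    "transform_polygon",
    "transform_tag",
]
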