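"""Slide-level mask merging and priority-ordered overlap resolution.

Per-tile instance masks are translated by their tile origins back onto the
slide canvas and unioned per slide group, with fibrosis folded into the
combined connective-tissue group (the two are indistinguishable at slide
level).  Pixels claimed by several groups are then assigned to exactly one
by the fixed priority order — necrosis, connective tissue (incl. fibrosis),
infiltration, portal area, vacuolation — yielding a per-pixel label map.
Instance identity is deliberately dropped: slide-level quantification is by
area, not object count.

Ground-truth annotations are pushed through the same merge + resolution
path, so predicted and annotated areas are measured under one rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .annotation_io import AnnotationSet, rasterize_union
from .backend import InstancePrediction
from .scheme import DEFAULT_SCHEME, ClassScheme
from .tiling import Tile


@dataclass
class LabelMask:
    """Per-pixel slide labels: 0 = background, i = scheme.priority[i-1]."""

    labels: np.ndarray  # (H, W) uint8
    scheme: ClassScheme
    provenance: str = "prediction"  # or "annotation"

    def group_mask(self, group: str) -> np.ndarray:
        return self.labels == self.scheme.label_index(group)

    def counts(self) -> dict[str, int]:
        """Pixel count per slide group (background excluded)."""
        binc = np.bincount(self.labels.ravel(), minlength=len(self.scheme.priority) + 1)
        return {
            g: int(binc[self.scheme.label_index(g)]) for g in self.scheme.priority
        }


def stitch(
    preds_by_tile: Mapping[str, Sequence[InstancePrediction]],
    tiles: Sequence[Tile],
    slide_shape: tuple[int, int],
    scheme: ClassScheme = DEFAULT_SCHEME,
) -> dict[str, np.ndarray]:
    """Union per-tile prediction masks onto slide-scale per-group masks.

    Each prediction's mask is translated by its tile origin (no resampling)
    and OR-ed into the slide group its finding maps to.  Predictions are
    expected to be confidence-filtered already.
    """
    height, width = slide_shape
    tile_by_id = {t.tile_id: t for t in tiles}
    masks = {
        g: np.zeros((height, width), dtype=bool) for g in scheme.slide_groups
    }
    for tile_id, preds in preds_by_tile.items():
        if not preds:
            continue
        tile = tile_by_id.get(tile_id)
        if tile is None:
            raise ValueError(f"predictions for unknown tile {tile_id!r}")
        y0, x0 = tile.origin
        ts = tile.tile_size
        if y0 + ts > height or x0 + ts > width or y0 < 0 or x0 < 0:
            raise ValueError(
                f"tile {tile_id!r} origin {(y0, x0)} outside slide {slide_shape}"
            )
        for p in preds:
            group = scheme.group_of(p.finding)
            masks[group][y0 : y0 + ts, x0 : x0 + ts] |= p.mask
    return masks


def annotation_group_masks(
    annotations: AnnotationSet, scheme: ClassScheme = DEFAULT_SCHEME
) -> dict[str, np.ndarray]:
    """Rasterized per-group masks of slide-level ground-truth annotations.

    Applies the same fibrosis merge as the prediction path so that both
    sides of the area comparison obey one rule.
    """
    masks: dict[str, np.ndarray] = {}
    for group in scheme.slide_groups:
        polys = [
            r.polygon
            for r in annotations.regions
            if scheme.group_of(r.finding) == group
        ]
        masks[group] = rasterize_union(polys, annotations.height, annotations.width)
    return masks


def resolve_overlaps(
    group_masks: Mapping[str, np.ndarray],
    scheme: ClassScheme = DEFAULT_SCHEME,
    provenance: str = "prediction",
) -> LabelMask:
    """Assign each pixel to the highest-priority group claiming it.

    Unclaimed pixels stay background (0).  The result is independent of the
    mapping's iteration order and idempotent: resolving the masks of an
    already-resolved LabelMask returns the same labels.
    """
    groups = scheme.priority
    shape = next(iter(group_masks.values())).shape
    labels = np.zeros(shape, dtype=np.uint8)
    # paint lowest priority first; higher priority overwrites
    for group in reversed(groups):
        mask = group_masks.get(group)
        if mask is None:
            continue
        if mask.shape != shape:
            raise ValueError("group masks have inconsistent shapes")
        labels[mask] = scheme.label_index(group)
    return LabelMask(labels=labels, scheme=scheme, provenance=provenance)


def render_overlay(
    label_mask: LabelMask, slide_image: np.ndarray, alpha: float = 0.55
) -> np.ndarray:
    """Tint labelled pixels with their group colour over the slide raster."""
    if slide_image.shape[:2] != label_mask.labels.shape:
        raise ValueError("slide raster and label mask dimensions differ")
    out = slide_image.astype(np.float64).copy()
    for group in label_mask.scheme.priority:
        color = np.asarray(label_mask.scheme.overlay_colors[group], dtype=np.float64)
        sel = label_mask.group_mask(group)
        out[sel] = (1.0 - alpha) * out[sel] + alpha * color
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def merge_slide(
    preds_by_tile: Mapping[str, Sequence[InstancePrediction]],
    tiles: Sequence[Tile],
    slide_shape: tuple[int, int],
    scheme: ClassScheme = DEFAULT_SCHEME,
) -> LabelMask:
    """stitch + resolve_overlaps in one step (the prediction path)."""
    return resolve_overlaps(
        stitch(preds_by_tile, tiles, slide_shape, scheme), scheme, "prediction"
    )


def merge_annotations(
    annotations: AnnotationSet, scheme: ClassScheme = DEFAULT_SCHEME
) -> LabelMask:
    """Group-merge + priority resolution of ground truth (the annotation path)."""
    return resolve_overlaps(
        annotation_group_masks(annotations, scheme), scheme, "annotation"
    )


__all__ = [
    "LabelMask",
    "annotation_group_masks",
    "merge_annotations",
    "merge_slide",
    "render_overlay",
    "resolve_overlaps",
    "stitch",
]
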