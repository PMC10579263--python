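"""Polygon annotations: VGG Image Annotator (VIA) 2.x JSON I/O, rasterization,
and per-finding pixel counting.

Annotations are polygons in image pixel coordinates (x = column, y = row,
0-based, continuous values allowed) labelled with one of the six findings in
:mod:`hepaseg.scheme`.  Areas are quantified by pixel counting: a polygon's
area on a raster is the number of pixels whose *centre* ``(c + 0.5, r + 0.5)``
lies inside the polygon under the even-odd rule.  Same-finding overlaps are
unioned before counting so no area is counted twice; cross-finding overlaps
are preserved here and resolved downstream by the slide-merge priority rule.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import IO, Iterable

import numpy as np
import pandas as pd

from .scheme import FINDINGS, UnknownFindingError, validate_finding

#: Aperio 20x scan resolution of the source slides, in microns per pixel.
DEFAULT_MICRONS_PER_PIXEL = 0.4993

#: Region attribute under which the finding label is stored in VIA JSON.
DEFAULT_FINDING_KEY = "finding"


class DegeneratePolygonError(ValueError):
    """Polygon with fewer than three distinct vertices."""


class ViaFormatError(ValueError):
    """Malformed or unsupported VIA JSON content."""


@dataclass(frozen=True)
class Polygon:
    """A closed polygon as an ordered ring of (x, y) pixel coordinates."""

    vertices: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise DegeneratePolygonError(
                f"polygon needs >= 3 vertices, got {len(self.vertices)}"
            )

    @property
    def xy(self) -> np.ndarray:
        """Vertices as an (n, 2) float array of (x, y)."""
        return np.asarray(self.vertices, dtype=float)

    def n_distinct(self) -> int:
        return len({(float(x), float(y)) for x, y in self.vertices})

    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax)."""
        v = self.xy
        return (
            float(v[:, 0].min()),
            float(v[:, 1].min()),
            float(v[:, 0].max()),
            float(v[:, 1].max()),
        )

    def translate(self, dx: float, dy: float) -> "Polygon":
        return Polygon(tuple((x + dx, y + dy) for x, y in self.vertices))


@dataclass(frozen=True)
class AnnotatedRegion:
    """One labelled polygon on one image."""

    polygon: Polygon
    finding: str
    image_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "finding", validate_finding(self.finding))


@dataclass
class AnnotationSet:
    """All annotated regions of one image plus its geometry metadata."""

    image_id: str
    width: int
    height: int
    regions: list[AnnotatedRegion] = field(default_factory=list)
    microns_per_pixel: float = DEFAULT_MICRONS_PER_PIXEL

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError(
                f"image dimensions must be positive, got {self.width}x{self.height}"
            )
        if self.microns_per_pixel <= 0:
            raise ValueError("microns_per_pixel must be positive")

    def findings_present(self) -> set[str]:
        return {r.finding for r in self.regions}


# ---------------------------------------------------------------------------
# Rasterization: pixel-centre even-odd scanline fill
# ---------------------------------------------------------------------------

def _raster_window(
    verts: np.ndarray, height: int, width: int
) -> tuple[np.ndarray, int, int]:
    """Rasterize a polygon into its clipped bounding-box window.

    Returns (mask, r0, c0) where mask is a boolean array positioned at
    image row r0, column c0.  A pixel is set iff its centre lies strictly
    inside the polygon by the even-odd (crossing-number) rule; centres
    exactly on an edge follow the half-open scanline convention.
    """
    xs, ys = verts[:, 0], verts[:, 1]
    r0 = max(0, int(math.floor(ys.min() - 0.5)))
    r1 = min(height - 1, int(math.ceil(ys.max())))
    c0 = max(0, int(math.floor(xs.min() - 0.5)))
    c1 = min(width - 1, int(math.ceil(xs.max())))
    if r1 < r0 or c1 < c0:
        return np.zeros((0, 0), dtype=bool), 0, 0

    n_rows, n_cols = r1 - r0 + 1, c1 - c0 + 1
    yc = np.arange(r0, r1 + 1, dtype=float) + 0.5  # row centres

    x1, y1 = xs, ys
    x2, y2 = np.roll(xs, -1), np.roll(ys, -1)

    # half-open vertical span test per (edge, row): (y1 <= yc) != (y2 <= yc)
    below1 = y1[:, None] <= yc[None, :]
    below2 = y2[:, None] <= yc[None, :]
    crossing = below1 != below2
    if not crossing.any():
        return np.zeros((n_rows, n_cols), dtype=bool), r0, c0

    e_idx, row_idx = np.nonzero(crossing)
    t = (yc[row_idx] - y1[e_idx]) / (y2[e_idx] - y1[e_idx])
    xint = x1[e_idx] + t * (x2[e_idx] - x1[e_idx])

    # pixel (row, c) is inside iff the number of intersections with
    # xint > c + 0.5 is odd; accumulate step thresholds per row
    thresh = np.ceil(xint - 0.5 - c0).astype(int)  # first col with centre >= xint
    thresh = np.clip(thresh, 0, n_cols)
    delta = np.zeros((n_rows, n_cols + 1), dtype=np.int64)
    np.add.at(delta, (row_idx, thresh), 1)
    n_leq = np.cumsum(delta[:, :-1], axis=1)  # intersections <= centre
    n_total = np.bincount(row_idx, minlength=n_rows)[:, None]
    return ((n_total - n_leq) % 2).astype(bool), r0, c0


def rasterize(polygon: Polygon, height: int, width: int) -> np.ndarray:
    """Rasterize a polygon to a (height, width) boolean mask.

    Pixel (r, c) is set iff its centre (c + 0.5, r + 0.5) lies inside the
    polygon under the even-odd rule; pixels outside the image are dropped.

    Raises
    ------
    DegeneratePolygonError
        If the polygon has fewer than three distinct vertices.
    """
    if polygon.n_distinct() < 3:
        raise DegeneratePolygonError(
            f"polygon has only {polygon.n_distinct()} distinct vertices"
        )
    mask = np.zeros((height, width), dtype=bool)
    window, r0, c0 = _raster_window(polygon.xy, height, width)
    if window.size:
        mask[r0 : r0 + window.shape[0], c0 : c0 + window.shape[1]] = window
    return mask


def rasterize_union(
    polygons: Iterable[Polygon], height: int, width: int
) -> np.ndarray:
    """Union of several rasterized polygons on one canvas."""
    mask = np.zeros((height, width), dtype=bool)
    for poly in polygons:
        if poly.n_distinct() < 3:
            raise DegeneratePolygonError("degenerate polygon in union")
        window, r0, c0 = _raster_window(poly.xy, height, width)
        if window.size:
            mask[r0 : r0 + window.shape[0], c0 : c0 + window.shape[1]] |= window
    return mask


def count_pixels(
    annotation_set: AnnotationSet, um2: bool = False
) -> dict[str, float]:
    """Per-finding pixel counts (or areas in square microns).

    Polygons of the same finding are unioned first, so overlapping
    same-finding regions are counted once.  With ``um2=True`` counts are
    scaled by microns_per_pixel squared.
    """
    scale = annotation_set.microns_per_pixel ** 2 if um2 else 1
    counts: dict[str, float] = {}
    for finding in FINDINGS:
        polys = [r.polygon for r in annotation_set.regions if r.finding == finding]
        if not polys:
            counts[finding] = 0 * scale
            continue
        mask = rasterize_union(
            polys, annotation_set.height, annotation_set.width
        )
        counts[finding] = int(mask.sum()) * scale
    return counts


def counts_table(sets: Iterable[AnnotationSet]) -> pd.DataFrame:
    """Long-format pixel-count table: image_id, finding, pixels, um2."""
    rows = []
    for s in sets:
        px = count_pixels(s)
        for finding in FINDINGS:
            rows.append(
                {
                    "image_id": s.image_id,
                    "finding": finding,
                    "pixels": int(px[finding]),
                    "um2": px[finding] * s.microns_per_pixel ** 2,
                }
            )
    return pd.DataFrame(rows, columns=["image_id", "finding", "pixels", "um2"])


# ---------------------------------------------------------------------------
# VIA 2.x JSON
# ---------------------------------------------------------------------------

def _via_entries(doc: dict) -> dict:
    if "_via_img_metadata" in doc:  # project-save dialect
        entries = doc["_via_img_metadata"]
        if not isinstance(entries, dict):
            raise ViaFormatError("_via_img_metadata is not a mapping")
        return entries
    return doc


def _parse_region(raw: dict, image_id: str, finding_key: str) -> AnnotatedRegion:
    shape = raw.get("shape_attributes", {})
    if shape.get("name") != "polygon":
        raise ViaFormatError(
            f"unsupported region shape {shape.get('name')!r} on {image_id!r}; "
            "only polygon regions are accepted"
        )
    xs = shape.get("all_points_x")
    ys = shape.get("all_points_y")
    if xs is None or ys is None or len(xs) != len(ys):
        raise ViaFormatError(f"polygon on {image_id!r} lacks matching point lists")
    label = raw.get("region_attributes", {}).get(finding_key)
    if label is None:
        raise ViaFormatError(
            f"region on {image_id!r} has no {finding_key!r} attribute"
        )
    return AnnotatedRegion(
        polygon=Polygon(tuple(zip(map(float, xs), map(float, ys)))),
        finding=label,
        image_id=image_id,
    )


def read_via_json(
    source: IO | str, finding_key: str = DEFAULT_FINDING_KEY
) -> list[AnnotationSet]:
    """Read VIA 2.x polygon annotations into AnnotationSets.

    Accepts both the flat export map and the project ``_via_img_metadata``
    dialect.  ``source`` may be an open text stream or a filesystem path.
    Image width/height and microns-per-pixel are read from the entry's
    ``file_attributes`` when present (keys ``width``, ``height``,
    ``microns_per_pixel``); otherwise dimensions fall back to the bounding
    extent of the polygons.
    """
    if isinstance(source, str):
        with open(source) as fh:
            doc = json.load(fh)
    else:
        doc = json.load(source)
    if not isinstance(doc, dict):
        raise ViaFormatError("top-level VIA JSON must be an object")

    sets: list[AnnotationSet] = []
    for entry in _via_entries(doc).values():
        if not isinstance(entry, dict) or "filename" not in entry:
            raise ViaFormatError("VIA image entry lacks a filename")
        image_id = entry["filename"]
        raw_regions = entry.get("regions", [])
        if isinstance(raw_regions, dict):  # legacy indexed dialect
            raw_regions = [raw_regions[k] for k in sorted(raw_regions)]
        regions = [_parse_region(r, image_id, finding_key) for r in raw_regions]

        attrs = entry.get("file_attributes", {}) or {}
        width, height = attrs.get("width"), attrs.get("height")
        if width is None or height is None:
            xmax = max((r.polygon.bounds()[2] for r in regions), default=0.0)
            ymax = max((r.polygon.bounds()[3] for r in regions), default=0.0)
            width = int(math.ceil(xmax)) or 1
            height = int(math.ceil(ymax)) or 1
        sets.append(
            AnnotationSet(
                image_id=image_id,
                width=int(width),
                height=int(height),
                regions=regions,
                microns_per_pixel=float(
                    attrs.get("microns_per_pixel", DEFAULT_MICRONS_PER_PIXEL)
                ),
            )
        )
    return sets


def write_via_json(
    sets: Iterable[AnnotationSet],
    stream: IO | str | None = None,
    finding_key: str = DEFAULT_FINDING_KEY,
) -> str:
    """Write AnnotationSets as flat VIA 2.x export JSON.

    Image geometry is stored under ``file_attributes`` so that
    ``read_via_json(write_via_json(sets))`` is the identity on the data
    model.  Returns the JSON text; also writes it to ``stream`` (an open
    stream or a path) when given.
    """
    doc: dict[str, dict] = {}
    for s in sets:
        key = f"{s.image_id}-1"  # VIA keys are filename + file size; size unknown
        doc[key] = {
            "filename": s.image_id,
            "size": -1,
            "regions": [
                {
                    "shape_attributes": {
                        "name": "polygon",
                        "all_points_x": [float(x) for x, _ in r.polygon.vertices],
                        "all_points_y": [float(y) for _, y in r.polygon.vertices],
                    },
                    "region_attributes": {finding_key: r.finding},
                }
                for r in s.regions
            ],
            "file_attributes": {
                "width": int(s.width),
                "height": int(s.height),
                "microns_per_pixel": float(s.microns_per_pixel),
            },
        }
    text = json.dumps(doc, indent=1)
    if stream is not None:
        if isinstance(stream, str):
            with open(stream, "w") as fh:
                fh.write(text)
        else:
            stream.write(text)
    return text


__all__ = [
    "AnnotatedRegion",
    "AnnotationSet",
    "DEFAULT_MICRONS_PER_PIXEL",
    "DegeneratePolygonError",
    "Polygon",
    "UnknownFindingError",
    "ViaFormatError",
    "count_pixels",
    "counts_table",
    "rasterize",
    "rasterize_union",
    "read_via_json",
    "write_via_json",
]
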