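"""The instance-segmenter contract, a deterministic toy segmenter, the
confidence filter, and SFM/MFM execution over tiles.

The pipeline consumes instance predictions (mask + finding + confidence +
bounding box) from any segmenter honouring :class:`Segmenter`; a trained
network (e.g. a Mask R-CNN running elsewhere) plugs in by emitting the same
records, and the JSON interchange format below lets it do so offline.  Two
built-in segmenters cover testing needs:

* :class:`ToySegmenter` — pure colour-rule thresholding + connected
  components; deterministic, no learned weights.  With a single declared
  class it behaves like a single-finding model (SFM): every pixel within
  tolerance of that class's colour is claimed.  With several classes it
  behaves like the multiple-finding model (MFM): pixels are assigned
  exclusively to the nearest declared colour, so ambiguous colours create
  genuine inter-class competition.
* :class:`TruthSegmenter` — replays ground-truth annotations as
  predictions with confidence 1.0 (the perfect-oracle limit).

Predictions with confidence below the detection threshold (study setting
0.5, the Mask R-CNN ``DETECTION_MIN_CONFIDENCE``) are discarded before any
merging.
"""

from __future__ import annotations

import json
from abc import ABC, abstractmethod
from dataclasses import dataclass
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
from scipy import ndimage

from .annotation_io import AnnotationSet, rasterize
from .scheme import FINDINGS, validate_finding
from .synthetic import DEFAULT_COLORS, SynthProfile
from .tiling import Tile

DEFAULT_CONFIDENCE_THRESHOLD = 0.5
DEFAULT_MIN_AREA = 20  # px; suppresses speckle components


def tight_bbox(mask: np.ndarray) -> tuple[int, int, int, int]:
    """(y0, x0, y1, x1) half-open tight bounding box of a nonempty mask."""
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0:
        raise ValueError("empty mask has no bounding box")
    return int(rows[0]), int(cols[0]), int(rows[-1] + 1), int(cols[-1] + 1)


@dataclass
class InstancePrediction:
    """One predicted object on one tile."""

    tile_id: str
    finding: str
    mask: np.ndarray  # (H, W) bool
    score: float
    bbox: tuple[int, int, int, int] | None = None  # filled from mask if None

    def __post_init__(self) -> None:
        self.finding = validate_finding(self.finding)
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("prediction mask is empty")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score {self.score} outside [0, 1]")
        tight = tight_bbox(self.mask)
        if self.bbox is None:
            self.bbox = tight
        elif tuple(self.bbox) != tight:
            raise ValueError(f"bbox {self.bbox} is not tight (expected {tight})")

    @property
    def area(self) -> int:
        return int(self.mask.sum())


class Segmenter(ABC):
    """Contract every instance segmenter must honour.

    ``classes`` declares the finding set the segmenter may emit: a single
    finding for SFM operation, all six for MFM.  ``predict`` maps one tile
    raster to instance predictions over the declared classes only.
    External models (e.g. a GPU Mask R-CNN) integrate by implementing this
    interface or by writing the JSON interchange format; the pipeline never
    depends on network internals.
    """

    @property
    @abstractmethod
    def classes(self) -> tuple[str, ...]: ...

    @abstractmethod
    def predict(
        self, image: np.ndarray, tile_id: str = ""
    ) -> list[InstancePrediction]: ...


@dataclass(frozen=True)
class ColorRule:
    """Match pixels within euclidean RGB distance ``tol`` of ``rgb``."""

    rgb: tuple[int, int, int]
    tol: float = 40.0


def rules_from_profile(
    profile: SynthProfile | None = None, tol: float = 40.0
) -> dict[str, ColorRule]:
    """Colour rules consistent with a synthetic profile's paint colours."""
    colors = profile.colors if profile is not None else DEFAULT_COLORS
    return {f: ColorRule(tuple(colors[f]), tol) for f in FINDINGS if f in colors}


class ToySegmenter(Segmenter):
    """Deterministic colour-rule segmenter (no seed, no weights).

    Per declared finding, pixels within the rule's colour tolerance form
    candidate area; with multiple declared classes each candidate pixel is
    assigned exclusively to the class whose rule colour is nearest (ties
    broken by declaration order).  8-connected components above
    ``min_area`` become instances.  Confidence is ``1 - mean colour
    distance / tolerance`` over the component, a deterministic value in
    [0, 1] that exercises the detection threshold.
    """

    def __init__(
        self,
        rules: Mapping[str, ColorRule],
        classes: Sequence[str] | None = None,
        min_area: int = DEFAULT_MIN_AREA,
    ):
        self._classes = tuple(
            validate_finding(c) for c in (classes if classes is not None else rules)
        )
        missing = [c for c in self._classes if c not in rules]
        if missing:
            raise ValueError(f"no colour rule for declared classes {missing}")
        self.rules = {c: rules[c] for c in self._classes}
        self.min_area = min_area

    @property
    def classes(self) -> tuple[str, ...]:
        return self._classes

    def predict(
        self, image: np.ndarray, tile_id: str = ""
    ) -> list[InstancePrediction]:
        img = image.astype(np.float64)
        dists = np.stack(
            [
                np.sqrt(((img - np.asarray(self.rules[c].rgb)) ** 2).sum(axis=-1))
                for c in self._classes
            ]
        )
        tols = np.asarray([self.rules[c].tol for c in self._classes])
        matched = dists <= tols[:, None, None]
        if len(self._classes) > 1:
            # exclusive assignment: nearest declared colour wins the pixel
            nearest = np.argmin(dists, axis=0)
            claims = matched & (
                nearest[None] == np.arange(len(self._classes))[:, None, None]
            )
        else:
            claims = matched

        preds: list[InstancePrediction] = []
        eight = np.ones((3, 3), dtype=int)
        for ci, cls in enumerate(self._classes):
            labels, n = ndimage.label(claims[ci], structure=eight)
            if n == 0:
                continue
            for comp in ndimage.find_objects(labels):
                for lab in np.unique(labels[comp]):
                    if lab == 0:
                        continue
                    comp_mask = np.zeros(labels.shape, dtype=bool)
                    comp_mask[comp] = labels[comp] == lab
                    area = int(comp_mask.sum())
                    if area < self.min_area:
                        continue
                    score = 1.0 - float(dists[ci][comp_mask].mean()) / self.rules[cls].tol
                    preds.append(
                        InstancePrediction(
                            tile_id=tile_id,
                            finding=cls,
                            mask=comp_mask,
                            score=float(np.clip(score, 0.0, 1.0)),
                        )
                    )
        return preds


class TruthSegmenter(Segmenter):
    """Perfect oracle: replays ground-truth annotations at confidence 1.0.

    Useful as the upper-bound reference — fed through merging and
    evaluation it must yield AP = mAP = 1 and an exact area regression.
    """

    def __init__(
        self,
        truth_by_tile: Mapping[str, AnnotationSet],
        classes: Sequence[str] = FINDINGS,
    ):
        self.truth_by_tile = dict(truth_by_tile)
        self._classes = tuple(validate_finding(c) for c in classes)

    @property
    def classes(self) -> tuple[str, ...]:
        return self._classes

    def predict(
        self, image: np.ndarray, tile_id: str = ""
    ) -> list[InstancePrediction]:
        ann = self.truth_by_tile.get(tile_id)
        if ann is None:
            return []
        preds = []
        for region in ann.regions:
            if region.finding not in self._classes:
                continue
            mask = rasterize(region.polygon, ann.height, ann.width)
            if not mask.any():
                continue
            preds.append(
                InstancePrediction(
                    tile_id=tile_id, finding=region.finding, mask=mask, score=1.0
                )
            )
        return preds


def filter_by_confidence(
    preds: Iterable[InstancePrediction],
    threshold: float = DEFAULT_CONFIDENCE_THRESHOLD,
) -> list[InstancePrediction]:
    """Keep predictions with score >= threshold (boundary kept), order preserved."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold {threshold} outside [0, 1]")
    return [p for p in preds if p.score >= threshold]


def run_backend(
    tiles: Sequence[Tile],
    segmenter: Segmenter | Sequence[Segmenter],
    mode: str = "MFM",
    threshold: float = DEFAULT_CONFIDENCE_THRESHOLD,
) -> dict[str, list[InstancePrediction]]:
    """Run a segmenter (MFM) or a composition of single-class segmenters
    (SFM) over tiles and return confidence-filtered predictions per tile.

    MFM mode requires one segmenter declaring more than one class; SFM mode
    requires a sequence of segmenters each declaring exactly one class
    (their outputs are concatenated per tile, one independent pass each).
    """
    mode = mode.upper()
    if mode == "MFM":
        if not isinstance(segmenter, Segmenter) or len(segmenter.classes) < 2:
            raise ValueError(
                "MFM mode needs a single segmenter declaring multiple classes"
            )
        segmenters: list[Segmenter] = [segmenter]
    elif mode == "SFM":
        if isinstance(segmenter, Segmenter):
            raise ValueError("SFM mode needs a sequence of single-class segmenters")
        segmenters = list(segmenter)
        bad = [s for s in segmenters if len(s.classes) != 1]
        if bad:
            raise ValueError("every SFM segmenter must declare exactly one class")
    else:
        raise ValueError(f"unknown mode {mode!r}; expected 'SFM' or 'MFM'")

    out: dict[str, list[InstancePrediction]] = {}
    for tile in tiles:
        preds: list[InstancePrediction] = []
        for seg in segmenters:
            preds.extend(seg.predict(tile.image, tile_id=tile.tile_id))
        out[tile.tile_id] = filter_by_confidence(preds, threshold)
    return out


# ---------------------------------------------------------------------------
# JSON interchange (offline external segmenters)
# ---------------------------------------------------------------------------

def _rle_encode(mask: np.ndarray) -> dict:
    """Uncompressed row-major RLE: run lengths alternating 0s then 1s."""
    flat = np.asarray(mask, dtype=bool).ravel()
    change = np.flatnonzero(np.diff(flat.astype(np.int8))) + 1
    boundaries = np.concatenate(([0], change, [flat.size]))
    counts = np.diff(boundaries).tolist()
    if flat.size and flat[0]:
        counts = [0] + counts
    return {"size": list(mask.shape), "counts": counts}


def _rle_decode(rle: dict) -> np.ndarray:
    total = int(np.prod(rle["size"]))
    flat = np.zeros(total, dtype=bool)
    pos, val = 0, False
    for run in rle["counts"]:
        if val:
            flat[pos : pos + run] = True
        pos += run
        val = not val
    if pos != total:
        raise ValueError("RLE runs do not cover the mask")
    return flat.reshape(rle["size"])


def predictions_to_json(
    preds_by_tile: Mapping[str, list[InstancePrediction]],
    stream: IO | str | None = None,
) -> str:
    doc = {
        tile_id: [
            {
                "finding": p.finding,
                "score": p.score,
                "bbox": list(p.bbox),
                "mask_rle": _rle_encode(p.mask),
            }
            for p in preds
        ]
        for tile_id, preds in preds_by_tile.items()
    }
    text = json.dumps(doc)
    if stream is not None:
        if isinstance(stream, str):
            with open(stream, "w") as fh:
                fh.write(text)
        else:
            stream.write(text)
    return text


def predictions_from_json(source: IO | str) -> dict[str, list[InstancePrediction]]:
    if isinstance(source, str):
        with open(source) as fh:
            doc = json.load(fh)
    else:
        doc = json.load(source)
    return {
        tile_id: [
            InstancePrediction(
                tile_id=tile_id,
                finding=r["finding"],
                mask=_rle_decode(r["mask_rle"]),
                score=float(r["score"]),
                bbox=tuple(r["bbox"]),
            )
            for r in raw
        ]
        for tile_id, raw in doc.items()
    }


__all__ = [
    "ColorRule",
    "DEFAULT_CONFIDENCE_THRESHOLD",
    "DEFAULT_MIN_AREA",
    "InstancePrediction",
    "Segmenter",
    "ToySegmenter",
    "TruthSegmenter",
    "filter_by_confidence",
    "predictions_from_json",
    "predictions_to_json",
    "rules_from_profile",
    "run_backend",
    "tight_bbox",
]
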