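"""Instance-segmentation and area-quantification metrics.

Tile-level model quality is scored by IoU-thresholded greedy instance
matching (study settings: confidence 0.5, IoU acceptance 0.667), all-point
average precision per class, mAP, and a stricter "transformed" mAP in which
an image containing any misprediction (false positive by class or by IoU
failure) contributes zero.  AP aggregation is per image: a class's AP is
the mean over images containing that class of the image's AP, and mAP is
the unweighted mean over classes — the convention of the Matterport-style
evaluation loop this pipeline mirrors.  The pooled ranked-list all-point AP
over an arbitrary image set is exposed as :func:`average_precision`.

Slide-level quantification compares predicted and annotated per-group pixel
counts across slides by ordinary least squares (slope, intercept, R²).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation_io import AnnotationSet, rasterize
from .backend import InstancePrediction
from .merge import LabelMask
from .scheme import validate_finding

logger = logging.getLogger(__name__)

DEFAULT_IOU_THRESHOLD = 0.667


def iou(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Intersection over union of two boolean masks of equal shape.

    Raises ValueError when both masks are empty (the ratio is undefined).
    """
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        raise ValueError("IoU undefined: both masks are empty")
    return float(np.logical_and(a, b).sum() / union)


@dataclass(frozen=True)
class GroundTruthInstance:
    """One annotated object used as matching target."""

    finding: str
    mask: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "finding", validate_finding(self.finding))


def gt_instances(annotations: AnnotationSet) -> list[GroundTruthInstance]:
    """Rasterize each annotated region into a matching target.

    Regions whose raster is empty at this resolution are skipped.
    """
    out = []
    for region in annotations.regions:
        mask = rasterize(region.polygon, annotations.height, annotations.width)
        if mask.any():
            out.append(GroundTruthInstance(region.finding, mask))
    return out


@dataclass
class MatchResult:
    """Greedy matching outcome for one image.

    ``records`` has one row per prediction in ranked order:
    (score, finding, matched gt index or None, iou of the match or of the
    best same-class candidate).  ``n_gt`` counts ground-truth instances per
    class; unmatched ground truths are the false negatives.
    """

    image_id: str
    records: list[tuple[float, str, int | None, float]]
    n_gt: dict[str, int]
    iou_threshold: float

    def tp(self, cls: str | None = None) -> int:
        return sum(
            1
            for _, f, m, _ in self.records
            if m is not None and (cls is None or f == cls)
        )

    def fp(self, cls: str | None = None) -> int:
        return sum(
            1 for _, f, m, _ in self.records if m is None and (cls is None or f == cls)
        )

    def fn(self, cls: str | None = None) -> int:
        classes = [cls] if cls is not None else list(self.n_gt)
        return sum(self.n_gt.get(c, 0) - self.tp(c) for c in classes)

    @property
    def has_misprediction(self) -> bool:
        return self.fp() > 0


def match_instances(
    preds: Sequence[InstancePrediction],
    gts: Sequence[GroundTruthInstance],
    iou_threshold: float = DEFAULT_IOU_THRESHOLD,
    image_id: str = "",
) -> MatchResult:
    """Greedy per-class matching of predictions to ground truth.

    Predictions are visited in descending score order (ties broken by
    larger best-candidate IoU, then by position in the input list); each
    claims the unmatched same-class ground truth of highest IoU, a true
    positive iff that IoU >= the threshold, otherwise a false positive.
    """
    n_gt: dict[str, int] = {}
    for g in gts:
        n_gt[g.finding] = n_gt.get(g.finding, 0) + 1

    # best candidate IoU per prediction, for the deterministic tie-break
    def best_iou(p: InstancePrediction) -> float:
        best = 0.0
        for g in gts:
            if g.finding == p.finding:
                best = max(best, iou(p.mask, g.mask))
        return best

    order = sorted(
        range(len(preds)),
        key=lambda i: (-preds[i].score, -best_iou(preds[i]), i),
    )
    taken: set[int] = set()
    records: list[tuple[float, str, int | None, float]] = []
    for i in order:
        p = preds[i]
        best_j, best_v = None, 0.0
        for j, g in enumerate(gts):
            if j in taken or g.finding != p.finding:
                continue
            v = iou(p.mask, g.mask)
            if v > best_v:
                best_j, best_v = j, v
        if best_j is not None and best_v >= iou_threshold:
            taken.add(best_j)
            records.append((p.score, p.finding, best_j, best_v))
        else:
            records.append((p.score, p.finding, None, best_v))
    return MatchResult(
        image_id=image_id, records=records, n_gt=n_gt, iou_threshold=iou_threshold
    )


def _pr_points(
    results: Sequence[MatchResult], cls: str
) -> tuple[np.ndarray, np.ndarray, int]:
    """Precision/recall at every distinct score cutoff, pooled over images."""
    n_gt = sum(r.n_gt.get(cls, 0) for r in results)
    rows = [
        (score, matched is not None)
        for r in results
        for score, f, matched, _ in r.records
        if f == cls
    ]
    if n_gt == 0:
        raise ValueError(f"no ground-truth instances of class {cls!r}")
    if not rows:
        return np.array([]), np.array([]), n_gt
    scores = np.array([s for s, _ in rows])
    is_tp = np.array([t for _, t in rows])
    order = np.argsort(-scores, kind="stable")
    scores, is_tp = scores[order], is_tp[order]
    cum_tp = np.cumsum(is_tp)
    cum_n = np.arange(1, len(rows) + 1)
    # tied scores share one cutoff: keep the last row of each score group
    last = np.flatnonzero(np.diff(scores, append=np.nan) != 0)
    recall = cum_tp[last] / n_gt
    precision = cum_tp[last] / cum_n[last]
    return recall, precision, n_gt


def average_precision(
    results: MatchResult | Sequence[MatchResult],
    cls: str,
    interpolation: str = "all",
) -> float:
    """All-point (or 11-point) interpolated AP for one class.

    The precision/recall curve is evaluated at every distinct score cutoff
    of the pooled predictions, the precision envelope is made monotone
    non-increasing in recall, and AP = sum (r_i - r_{i-1}) * p_env(r_i)
    ('all'), or the mean of the envelope at recalls 0, 0.1, ..., 1
    ('11point').
    """
    if isinstance(results, MatchResult):
        results = [results]
    recall, precision, _ = _pr_points(results, cls)
    if recall.size == 0:
        return 0.0
    p_env = np.maximum.accumulate(precision[::-1])[::-1]
    if interpolation == "all":
        prev = np.concatenate(([0.0], recall[:-1]))
        return float(np.sum((recall - prev) * p_env))
    if interpolation == "11point":
        grid = np.linspace(0.0, 1.0, 11)
        vals = [
            float(p_env[recall >= r].max()) if (recall >= r).any() else 0.0
            for r in grid
        ]
        return float(np.mean(vals))
    raise ValueError(f"unknown interpolation {interpolation!r}")


def mean_ap(per_class_ap: Mapping[str, float]) -> float:
    """Unweighted mean over evaluated classes."""
    if not per_class_ap:
        raise ValueError("no evaluated classes")
    return float(np.mean(list(per_class_ap.values())))


@dataclass
class APResult:
    """Per-class AP, mAP, and the misprediction-zeroed transformed mAP."""

    per_class_ap: dict[str, float]
    map: float
    per_class_transformed: dict[str, float]
    transformed_map: float
    iou_threshold: float
    confidence_threshold: float
    n_images: int
    excluded_classes: list[str] = field(default_factory=list)


def evaluate(
    results: Sequence[MatchResult],
    classes: Sequence[str] | None = None,
    confidence_threshold: float = 0.5,
    interpolation: str = "all",
) -> APResult:
    """Aggregate per-image matches into AP/mAP and transformed mAP.

    A class's AP is the mean of its per-image APs over images holding at
    least one ground truth of that class; classes with no ground truth
    anywhere are excluded (and logged).  For the transformed variant every
    image containing a misprediction — any false positive, whether a class
    confusion or an IoU failure — has its per-image APs set to zero before
    averaging, so transformed mAP <= mAP with equality when no image is
    flagged.
    """
    if not results:
        raise ValueError("no match results to evaluate")
    if classes is None:
        classes = sorted({c for r in results for c in r.n_gt})
    per_ap: dict[str, float] = {}
    per_tr: dict[str, float] = {}
    excluded: list[str] = []
    for cls in classes:
        imgs = [r for r in results if r.n_gt.get(cls, 0) > 0]
        if not imgs:
            excluded.append(cls)
            logger.info("class %s has no ground truth; excluded from mAP", cls)
            continue
        aps = [average_precision(r, cls, interpolation) for r in imgs]
        per_ap[cls] = float(np.mean(aps))
        zeroed = [
            0.0 if r.has_misprediction else ap for r, ap in zip(imgs, aps)
        ]
        per_tr[cls] = float(np.mean(zeroed))
    if not per_ap:
        raise ValueError("no class with ground truth; nothing to evaluate")
    return APResult(
        per_class_ap=per_ap,
        map=mean_ap(per_ap),
        per_class_transformed=per_tr,
        transformed_map=mean_ap(per_tr),
        iou_threshold=results[0].iou_threshold,
        confidence_threshold=confidence_threshold,
        n_images=len(results),
        excluded_classes=excluded,
    )


# ---------------------------------------------------------------------------
# Slide-level area comparison
# ---------------------------------------------------------------------------

def area_report(
    predicted: LabelMask, annotated: LabelMask, slide_id: str
) -> pd.DataFrame:
    """Per-group predicted vs annotated pixel counts for one slide."""
    if predicted.scheme.priority != annotated.scheme.priority:
        raise ValueError("predicted and annotated label masks use different schemes")
    if predicted.labels.shape != annotated.labels.shape:
        raise ValueError("label mask dimensions differ")
    pred_counts = predicted.counts()
    annot_counts = annotated.counts()
    return pd.DataFrame(
        {
            "slide_id": slide_id,
            "group": list(predicted.scheme.priority),
            "annotated_pixels": [annot_counts[g] for g in predicted.scheme.priority],
            "predicted_pixels": [pred_counts[g] for g in predicted.scheme.priority],
        }
    )


@dataclass
class RegressionResult:
    """OLS of predicted on annotated pixel counts for one slide group."""

    group: str
    slope: float
    intercept: float
    r_squared: float
    n_slides: int


def regress(report: pd.DataFrame, group: str) -> RegressionResult:
    """Fit predicted = slope * annotated + intercept over slides of a group.

    Requires at least three slides and nonzero variance in the annotated
    counts.
    """
    rows = report[report["group"] == group]
    n = len(rows)
    if n < 3:
        raise ValueError(f"group {group!r} has {n} slides; need >= 3")
    x = rows["annotated_pixels"].to_numpy(dtype=float)
    y = rows["predicted_pixels"].to_numpy(dtype=float)
    if np.var(x) == 0:
        raise ValueError(f"annotated counts of group {group!r} have zero variance")
    fit = stats.linregress(x, y)
    return RegressionResult(
        group=group,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n_slides=n,
    )


def regress_all(report: pd.DataFrame) -> pd.DataFrame:
    """Regression table over every group present in an area report."""
    rows = []
    for group in report["group"].unique():
        res = regress(report, group)
        rows.append(
            {
                "group": res.group,
                "slope": res.slope,
                "intercept": res.intercept,
                "r_squared": res.r_squared,
                "n_slides": res.n_slides,
            }
        )
    return pd.DataFrame(rows)


__all__ = [
    "APResult",
    "DEFAULT_IOU_THRESHOLD",
    "GroundTruthInstance",
    "MatchResult",
    "RegressionResult",
    "area_report",
    "average_precision",
    "evaluate",
    "gt_instances",
    "iou",
    "match_instances",
    "mean_ap",
    "regress",
    "regress_all",
]
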