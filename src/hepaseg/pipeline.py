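"""End-to-end orchestration: synthetic cohort -> tiling -> backend ->
slide merging -> evaluation, and the SFM-vs-MFM comparison harness.

The comparison harness mirrors the study workflow: a cohort of slides from
the four treatment-group profiles is tiled, a set of six single-finding
segmenters (SFM composition) and one multiple-finding segmenter (MFM) are
each run over every tile, per-tile predictions are confidence-filtered,
stitched back to slide scale, group-merged and priority-resolved, and the
resulting label maps are compared with ground truth both at tile level
(per-class AP, mAP, transformed mAP over the six findings) and at slide
level (per-group OLS of predicted on annotated pixel counts over the five
merged groups).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .backend import (
    DEFAULT_CONFIDENCE_THRESHOLD,
    DEFAULT_MIN_AREA,
    Segmenter,
    ToySegmenter,
    TruthSegmenter,
    rules_from_profile,
    run_backend,
)
from .evaluation import (
    APResult,
    DEFAULT_IOU_THRESHOLD,
    MatchResult,
    area_report,
    evaluate,
    gt_instances,
    match_instances,
    regress_all,
)
from .merge import LabelMask, merge_annotations, merge_slide
from .scheme import DEFAULT_SCHEME, ClassScheme, FINDINGS
from .synthetic import (
    DEFAULT_SLIDE_SIZE,
    DEFAULT_TILE_SIZE,
    SynthSlide,
    default_profiles,
    generate_cohort,
)
from .tiling import DEFAULT_RATIOS, tile_grid


@dataclass
class PipelineConfig:
    """Knobs of the end-to-end run (study defaults)."""

    tile_size: int = DEFAULT_TILE_SIZE
    slide_size: int = DEFAULT_SLIDE_SIZE
    split_ratios: tuple[float, float, float] = DEFAULT_RATIOS
    confidence_threshold: float = DEFAULT_CONFIDENCE_THRESHOLD
    iou_threshold: float = DEFAULT_IOU_THRESHOLD
    min_area: int = DEFAULT_MIN_AREA
    n_per_group: int = 5
    seed: int = 0
    confusable_fibrosis: bool = False
    scheme: ClassScheme = field(default_factory=lambda: DEFAULT_SCHEME)

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence_threshold <= 1.0:
            raise ValueError("confidence threshold outside [0, 1]")
        if not 0.0 <= self.iou_threshold <= 1.0:
            raise ValueError("IoU threshold outside [0, 1]")
        if abs(sum(self.split_ratios) - 1.0) > 1e-9:
            raise ValueError("split ratios must sum to 1")
        if self.slide_size % self.tile_size:
            raise ValueError("slide size must be divisible by tile size")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")


@dataclass
class SlideRun:
    """Everything computed for one slide under one backend mode."""

    slide_id: str
    group: str
    predicted: LabelMask
    annotated: LabelMask
    matches: list[MatchResult]


@dataclass
class ComparisonReport:
    """SFM-vs-MFM comparison over one synthetic cohort."""

    areas: dict[str, pd.DataFrame]  # mode -> per-slide per-group pixel counts
    regressions: dict[str, pd.DataFrame]  # mode -> per-group OLS table
    ap: dict[str, APResult]  # mode -> tile-level six-class AP result
    config: PipelineConfig

    def to_json(self) -> str:
        doc = {
            mode: {
                "per_class_ap": res.per_class_ap,
                "map": res.map,
                "per_class_transformed": res.per_class_transformed,
                "transformed_map": res.transformed_map,
                "iou_threshold": res.iou_threshold,
                "confidence_threshold": res.confidence_threshold,
                "n_images": res.n_images,
                "regressions": self.regressions[mode].to_dict(orient="records"),
            }
            for mode, res in self.ap.items()
        }
        return json.dumps(doc, indent=1, sort_keys=True)


def sfm_composition(segmenter_factory, classes: Sequence[str] = FINDINGS):
    """Build six independent single-class segmenters from a factory."""
    return [segmenter_factory(cls) for cls in classes]


def run_slide(
    slide: SynthSlide,
    segmenter: Segmenter | Sequence[Segmenter],
    mode: str,
    config: PipelineConfig,
) -> SlideRun:
    """Tile one slide, run the backend, merge, and match against truth."""
    tiles = tile_grid(slide.image, slide.truth, tile_size=config.tile_size)
    preds = run_backend(
        tiles, segmenter, mode=mode, threshold=config.confidence_threshold
    )
    predicted = merge_slide(
        preds, tiles, slide.image.shape[:2], scheme=config.scheme
    )
    annotated = merge_annotations(slide.truth, scheme=config.scheme)
    matches = [
        match_instances(
            preds[t.tile_id],
            gt_instances(t.annotations),
            iou_threshold=config.iou_threshold,
            image_id=t.tile_id,
        )
        for t in tiles
    ]
    return SlideRun(
        slide_id=slide.truth.image_id,
        group=slide.profile_name,
        predicted=predicted,
        annotated=annotated,
        matches=matches,
    )


def _mode_segmenters(
    mode: str, config: PipelineConfig, slides: Sequence[SynthSlide], backend: str
):
    if backend == "toy":
        profile = next(iter(default_profiles(config.confusable_fibrosis).values()))
        rules = rules_from_profile(profile)
        if mode == "MFM":
            return ToySegmenter(rules, min_area=config.min_area)
        return sfm_composition(
            lambda cls: ToySegmenter(rules, classes=[cls], min_area=config.min_area)
        )
    if backend == "oracle":
        truth_by_tile = {}
        for slide in slides:
            for t in tile_grid(slide.image, slide.truth, tile_size=config.tile_size):
                truth_by_tile[t.tile_id] = t.annotations
        if mode == "MFM":
            return TruthSegmenter(truth_by_tile)
        return sfm_composition(
            lambda cls: TruthSegmenter(truth_by_tile, classes=[cls])
        )
    raise ValueError(f"unknown backend {backend!r}; expected 'toy' or 'oracle'")


def run_mode(
    slides: Sequence[SynthSlide],
    mode: str,
    config: PipelineConfig,
    backend: str = "toy",
) -> tuple[pd.DataFrame, pd.DataFrame, APResult]:
    """Run one backend mode over a cohort: areas, regressions, AP."""
    segmenter = _mode_segmenters(mode, config, slides, backend)
    runs = [run_slide(s, segmenter, mode, config) for s in slides]
    areas = pd.concat(
        [area_report(r.predicted, r.annotated, r.slide_id) for r in runs],
        ignore_index=True,
    )
    matches = [m for r in runs for m in r.matches]
    ap = evaluate(
        matches,
        classes=FINDINGS,
        confidence_threshold=config.confidence_threshold,
    )
    return areas, regress_all(areas), ap


def run_compare(
    config: PipelineConfig | None = None, backend: str = "toy"
) -> ComparisonReport:
    """The full SFM-vs-MFM comparison on a fresh synthetic cohort.

    Fully reproducible from (config, backend): the cohort is generated
    from config.seed and both modes see identical slides.
    """
    config = config if config is not None else PipelineConfig()
    slides = generate_cohort(
        default_profiles(config.confusable_fibrosis),
        n_per_group=config.n_per_group,
        seed=config.seed,
        height=config.slide_size,
        width=config.slide_size,
        tile_size=config.tile_size,
    )
    areas: dict[str, pd.DataFrame] = {}
    regressions: dict[str, pd.DataFrame] = {}
    ap: dict[str, APResult] = {}
    for mode in ("SFM", "MFM"):
        areas[mode], regressions[mode], ap[mode] = run_mode(
            slides, mode, config, backend=backend
        )
    return ComparisonReport(
        areas=areas, regressions=regressions, ap=ap, config=config
    )


__all__ = [
    "ComparisonReport",
    "PipelineConfig",
    "SlideRun",
    "run_compare",
    "run_mode",
    "run_slide",
    "sfm_composition",
]
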