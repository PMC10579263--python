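"""Synthetic H&E-like slides with exact ground truth.

Generates RGB rasters that emulate the four treatment-group lesion profiles
of a rat liver toxicity study — control (normal features only), NDMA
(fibrosis), APAP (necrosis + inflammatory-cell infiltration) and corn oil
(vacuolation) — so the whole tiling/prediction/merging/evaluation pipeline
runs without any scanned slide or trained network.

Regions are sampled polygon-first: a simple star-shaped polygon is drawn,
rasterized with the package's own pixel-centre rasterizer, and painted onto
the canvas, so the stored truth polygon reproduces the painted footprint
exactly.  Regions are placed with at least a two-pixel gap between
footprints (rejection sampling), which keeps connected components of one
colour in one-to-one correspondence with truth instances.

Each finding is painted in a distinct colour family with small per-pixel
jitter.  The palette is a free parameter: it makes a simple colour-rule
segmenter well-posed; it is not a claim about real H&E appearance.  A
"confusable" palette that paints fibrosis in connective tissue's colour is
available to reproduce the discrimination failure between those two
findings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .annotation_io import AnnotatedRegion, AnnotationSet, Polygon, _raster_window
from .scheme import validate_finding

DEFAULT_TILE_SIZE = 448
DEFAULT_SLIDE_SIZE = 2240  # 5x5 tiles; full-study slides are 10752 (24x24)

#: Background parenchyma (eosin-pink) and per-finding paint colours.
BACKGROUND_COLOR = (228, 178, 188)
DEFAULT_COLORS: dict[str, tuple[int, int, int]] = {
    "portal_area": (120, 90, 160),
    "connective_tissue": (90, 120, 200),
    "fibrosis": (60, 160, 210),
    "infiltration": (70, 60, 130),
    "necrosis": (240, 225, 205),
    "vacuolation": (250, 250, 250),
}


@dataclass(frozen=True)
class FindingSpec:
    """How many regions of one finding to draw and what they look like.

    count_range and diameter_range are inclusive (min, max); shape is one of
    'blob' (roundish), 'band' (elongated strand, aspect ~5:1) or 'cluster'
    (a group of small blobs, each its own instance).
    """

    finding: str
    count_range: tuple[int, int]
    diameter_range: tuple[float, float]
    shape: str = "blob"
    cluster_size: tuple[int, int] = (4, 8)

    def __post_init__(self) -> None:
        object.__setattr__(self, "finding", validate_finding(self.finding))
        if self.count_range[0] < 0 or self.count_range[1] < self.count_range[0]:
            raise ValueError(f"bad count_range {self.count_range}")
        if self.diameter_range[0] <= 0:
            raise ValueError("diameter_range must be positive")
        if self.shape not in ("blob", "band", "cluster"):
            raise ValueError(f"unknown shape {self.shape!r}")


@dataclass(frozen=True)
class SynthProfile:
    """A treatment-group profile: which findings appear and how they render."""

    name: str
    specs: tuple[FindingSpec, ...]
    colors: dict[str, tuple[int, int, int]] = field(
        default_factory=lambda: dict(DEFAULT_COLORS)
    )
    background_color: tuple[int, int, int] = BACKGROUND_COLOR
    color_jitter: int = 6
    background_jitter: int = 4

    def __post_init__(self) -> None:
        seen: dict[tuple[int, int, int], str] = {}
        present = {s.finding for s in self.specs}
        for f in present:
            if f not in self.colors:
                raise ValueError(f"profile {self.name!r} has no colour for {f!r}")
        # distinct colours are only required among findings actually drawn,
        # which permits the deliberately confusable fibrosis/connective palette
        # only when requested via identical colours for that pair
        for f in sorted(present):
            c = tuple(self.colors[f])
            if c in seen and {seen[c], f} != {"connective_tissue", "fibrosis"}:
                raise ValueError(
                    f"colour {c} shared by {seen[c]!r} and {f!r}; signatures must differ"
                )
            seen[c] = f

    def with_confusable_fibrosis(self) -> "SynthProfile":
        """Fibrosis painted in connective tissue's colour family."""
        colors = dict(self.colors)
        colors["fibrosis"] = colors["connective_tissue"]
        return replace(self, colors=colors)


@dataclass
class SynthSlide:
    """One generated slide: RGB image, exact truth, provenance."""

    image: np.ndarray  # (H, W, 3) uint8
    truth: AnnotationSet
    profile_name: str
    seed: int


# base normal-feature burden shared by every group
_NORMAL_SPECS = (
    FindingSpec("portal_area", (6, 10), (60, 110), "blob"),
    FindingSpec("connective_tissue", (3, 6), (70, 120), "band"),
)

DEFAULT_PROFILES: dict[str, SynthProfile] = {
    "control": SynthProfile("control", _NORMAL_SPECS),
    "NDMA": SynthProfile(
        "NDMA",
        _NORMAL_SPECS + (FindingSpec("fibrosis", (4, 8), (70, 130), "band"),),
    ),
    "APAP": SynthProfile(
        "APAP",
        _NORMAL_SPECS
        + (
            FindingSpec("necrosis", (3, 6), (120, 220), "blob"),
            FindingSpec("infiltration", (3, 6), (12, 30), "cluster"),
        ),
    ),
    "corn_oil": SynthProfile(
        "corn_oil",
        _NORMAL_SPECS + (FindingSpec("vacuolation", (8, 16), (25, 60), "blob"),),
    ),
}


def default_profiles(confusable_fibrosis: bool = False) -> dict[str, SynthProfile]:
    """The four study-group profiles, optionally with the confusable palette."""
    profiles = dict(DEFAULT_PROFILES)
    if confusable_fibrosis:
        profiles = {k: p.with_confusable_fibrosis() for k, p in profiles.items()}
    return profiles


# ---------------------------------------------------------------------------
# Region sampling
# ---------------------------------------------------------------------------

def _star_polygon(
    rng: np.random.Generator,
    cx: float,
    cy: float,
    radius: float,
    aspect: float,
    angle: float,
    n_vertices: int = 20,
    roughness: float = 0.22,
) -> Polygon:
    """A simple (star-shaped, hence non-self-intersecting) polygon."""
    theta = np.linspace(0.0, 2.0 * math.pi, n_vertices, endpoint=False)
    r = radius * (1.0 + rng.uniform(-roughness, roughness, n_vertices))
    x = r * np.cos(theta) * aspect
    y = r * np.sin(theta) / aspect
    ca, sa = math.cos(angle), math.sin(angle)
    xr = cx + ca * x - sa * y
    yr = cy + sa * x + ca * y
    return Polygon(tuple(zip(xr.tolist(), yr.tolist())))


def _try_place(
    rng: np.random.Generator,
    occupancy: np.ndarray,
    diameter: float,
    aspect: float,
    center_box: tuple[float, float, float, float] | None = None,
    max_attempts: int = 80,
) -> tuple[Polygon, np.ndarray, int, int]:
    """Sample a polygon that fits inside the image and clears occupied area.

    Returns (polygon, window mask, r0, c0) and marks nothing; the caller
    updates occupancy.  Placement requires the polygon's footprint, dilated
    by one pixel, to miss every previously painted pixel, guaranteeing
    8-connectivity separation between instances.
    """
    height, width = occupancy.shape
    # worst-case extent of the star polygon from its centre
    reach = diameter / 2.0 * 1.25 * max(aspect, 1.0 / aspect)
    if center_box is None:
        x_lo, x_hi = reach + 1, width - reach - 1
        y_lo, y_hi = reach + 1, height - reach - 1
    else:
        x_lo = max(center_box[0], reach + 1)
        x_hi = min(center_box[2], width - reach - 1)
        y_lo = max(center_box[1], reach + 1)
        y_hi = min(center_box[3], height - reach - 1)
    if x_hi <= x_lo or y_hi <= y_lo:
        raise RuntimeError(
            f"region of diameter {diameter:.0f} cannot fit the {height}x{width} canvas"
        )
    for _ in range(max_attempts):
        cx = rng.uniform(x_lo, x_hi)
        cy = rng.uniform(y_lo, y_hi)
        angle = rng.uniform(0.0, math.pi)
        poly = _star_polygon(rng, cx, cy, diameter / 2.0, aspect, angle)
        window, r0, c0 = _raster_window(poly.xy, height, width)
        if not window.any():
            continue
        pad = np.pad(window, 1)
        dilated = ndimage.binary_dilation(pad, structure=np.ones((3, 3), bool))
        rr0, cc0 = r0 - 1, c0 - 1
        rs = slice(max(rr0, 0), min(rr0 + dilated.shape[0], height))
        cs = slice(max(cc0, 0), min(cc0 + dilated.shape[1], width))
        d_rs = slice(rs.start - rr0, rs.stop - rr0)
        d_cs = slice(cs.start - cc0, cs.stop - cc0)
        if np.logical_and(occupancy[rs, cs], dilated[d_rs, d_cs]).any():
            continue
        return poly, window, r0, c0
    raise RuntimeError(
        "could not place a region after "
        f"{max_attempts} attempts (diameter {diameter:.0f}); lower the lesion burden"
    )


def _paint(
    rng: np.random.Generator,
    image: np.ndarray,
    window: np.ndarray,
    r0: int,
    c0: int,
    color: tuple[int, int, int],
    jitter: int,
) -> None:
    rows, cols = np.nonzero(window)
    n = rows.size
    pix = np.asarray(color, dtype=np.int16) + rng.integers(
        -jitter, jitter + 1, size=(n, 3), dtype=np.int16
    )
    image[rows + r0, cols + c0] = np.clip(pix, 0, 255).astype(np.uint8)


def generate_slide(
    profile: SynthProfile,
    seed: int,
    height: int = DEFAULT_SLIDE_SIZE,
    width: int = DEFAULT_SLIDE_SIZE,
    tile_size: int = DEFAULT_TILE_SIZE,
    slide_id: str | None = None,
) -> SynthSlide:
    """Generate one synthetic slide, deterministic in (profile, seed, size).

    Raises ValueError if the requested size is not a multiple of tile_size
    (the tiling grid downstream assumes exact coverage).
    """
    if height % tile_size or width % tile_size:
        raise ValueError(
            f"slide size {height}x{width} is not divisible by tile size "
            f"{tile_size} (remainders {height % tile_size}, {width % tile_size})"
        )
    rng = np.random.default_rng(seed)
    slide_id = slide_id or f"{profile.name}_seed{seed}"

    image = np.empty((height, width, 3), dtype=np.uint8)
    bj = profile.background_jitter
    for ch, base in enumerate(profile.background_color):
        image[:, :, ch] = rng.integers(
            base - bj, base + bj + 1, size=(height, width), dtype=np.uint8
        )

    occupancy = np.zeros((height, width), dtype=bool)
    regions: list[AnnotatedRegion] = []
    for spec in profile.specs:
        color = profile.colors[spec.finding]
        count = int(rng.integers(spec.count_range[0], spec.count_range[1] + 1))
        aspect = 2.3 if spec.shape == "band" else 1.0  # bands ~5:1 after /aspect
        for _ in range(count):
            if spec.shape == "cluster":
                k = int(
                    rng.integers(spec.cluster_size[0], spec.cluster_size[1] + 1)
                )
                spread = spec.diameter_range[1] * 3.0
                ccx = rng.uniform(spread, width - spread)
                ccy = rng.uniform(spread, height - spread)
                box = (ccx - spread, ccy - spread, ccx + spread, ccy + spread)
                for _ in range(k):
                    diam = rng.uniform(*spec.diameter_range)
                    poly, window, r0, c0 = _try_place(
                        rng, occupancy, diam, 1.0, center_box=box
                    )
                    occupancy[r0 : r0 + window.shape[0], c0 : c0 + window.shape[1]] |= window
                    _paint(rng, image, window, r0, c0, color, profile.color_jitter)
                    regions.append(
                        AnnotatedRegion(poly, spec.finding, image_id=slide_id)
                    )
            else:
                diam = rng.uniform(*spec.diameter_range)
                poly, window, r0, c0 = _try_place(rng, occupancy, diam, aspect)
                occupancy[r0 : r0 + window.shape[0], c0 : c0 + window.shape[1]] |= window
                _paint(rng, image, window, r0, c0, color, profile.color_jitter)
                regions.append(AnnotatedRegion(poly, spec.finding, image_id=slide_id))

    truth = AnnotationSet(
        image_id=slide_id, width=width, height=height, regions=regions
    )
    return SynthSlide(image=image, truth=truth, profile_name=profile.name, seed=seed)


def generate_cohort(
    profiles: dict[str, SynthProfile] | None = None,
    n_per_group: int = 25,
    seed: int = 0,
    height: int = DEFAULT_SLIDE_SIZE,
    width: int = DEFAULT_SLIDE_SIZE,
    tile_size: int = DEFAULT_TILE_SIZE,
) -> list[SynthSlide]:
    """A cohort of n_per_group slides per profile (study default: 25 x 4 groups).

    Slide seeds are derived deterministically from the master seed; slide
    ids encode group membership as ``<group>_s<index>``.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    profiles = profiles if profiles is not None else default_profiles()
    master = np.random.default_rng(seed)
    slides: list[SynthSlide] = []
    for name, profile in profiles.items():
        group_seeds = master.integers(0, 2**31, size=n_per_group)
        for i, s in enumerate(group_seeds):
            slides.append(
                generate_slide(
                    profile,
                    int(s),
                    height=height,
                    width=width,
                    tile_size=tile_size,
                    slide_id=f"{name}_s{i:03d}",
                )
            )
    return slides


__all__ = [
    "BACKGROUND_COLOR",
    "DEFAULT_COLORS",
    "DEFAULT_PROFILES",
    "DEFAULT_SLIDE_SIZE",
    "DEFAULT_TILE_SIZE",
    "FindingSpec",
    "SynthProfile",
    "SynthSlide",
    "default_profiles",
    "generate_cohort",
    "generate_slide",
]
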