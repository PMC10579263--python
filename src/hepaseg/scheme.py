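"""Finding vocabulary and the slide-level class scheme.

Six tile-level findings are annotated on rat liver tissue: two normal
features (portal area, connective tissue) and four toxicant-induced lesions
(infiltration, necrosis, fibrosis, vacuolation).  At slide level fibrosis is
histologically indistinguishable from normal connective tissue, so the two
are merged into a single combined group, leaving five slide-level groups.
Where several groups claim the same pixel, the conflict is resolved by a
fixed clinical priority order (necrosis first, vacuolation last).
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: The closed tile-level vocabulary.
FINDINGS: tuple[str, ...] = (
    "portal_area",
    "connective_tissue",
    "infiltration",
    "necrosis",
    "fibrosis",
    "vacuolation",
)

#: Combined slide-level group name for connective tissue + fibrosis.
CONNECTIVE_GROUP = "connective_tissue_incl_fibrosis"

#: Slide-level groups, highest priority first.
DEFAULT_PRIORITY: tuple[str, ...] = (
    "necrosis",
    CONNECTIVE_GROUP,
    "infiltration",
    "portal_area",
    "vacuolation",
)

DEFAULT_MERGE_MAP: dict[str, str] = {
    "portal_area": "portal_area",
    "connective_tissue": CONNECTIVE_GROUP,
    "infiltration": "infiltration",
    "necrosis": "necrosis",
    "fibrosis": CONNECTIVE_GROUP,
    "vacuolation": "vacuolation",
}

#: Overlay colours for rendered label maps (RGB).
DEFAULT_OVERLAY_COLORS: dict[str, tuple[int, int, int]] = {
    "portal_area": (255, 255, 0),        # yellow
    CONNECTIVE_GROUP: (0, 0, 255),       # blue
    "infiltration": (0, 200, 0),         # green
    "vacuolation": (255, 0, 0),          # red
    "necrosis": (255, 255, 255),         # white
}


class UnknownFindingError(ValueError):
    """A finding label outside the closed six-class vocabulary."""

    def __init__(self, label: str):
        super().__init__(
            f"unknown finding {label!r}; expected one of {', '.join(FINDINGS)}"
        )
        self.label = label


def validate_finding(label: str) -> str:
    """Return the canonical (lower-case) finding name or raise.

    Matching is case-insensitive; surrounding whitespace is ignored.
    """
    canon = label.strip().lower()
    if canon not in FINDINGS:
        raise UnknownFindingError(label)
    return canon


@dataclass(frozen=True)
class ClassScheme:
    """Tile classes, slide groups, the fibrosis merge, and the priority order.

    Parameters
    ----------
    tile_classes
        The findings a segmenter may emit (default: all six).
    merge_map
        Total map tile class -> slide group (fibrosis and connective tissue
        both map to the combined group by default).
    priority
        Slide groups from highest to lowest precedence; a pixel claimed by
        several groups is assigned the first one in this order.
    overlay_colors
        RGB colour per slide group for rendered overlays.
    """

    tile_classes: tuple[str, ...] = FINDINGS
    merge_map: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_MERGE_MAP)
    )
    priority: tuple[str, ...] = DEFAULT_PRIORITY
    overlay_colors: dict[str, tuple[int, int, int]] = field(
        default_factory=lambda: dict(DEFAULT_OVERLAY_COLORS)
    )

    def __post_init__(self) -> None:
        missing = [c for c in self.tile_classes if c not in self.merge_map]
        if missing:
            raise ValueError(f"merge_map is not total; missing {missing}")
        groups = set(self.merge_map[c] for c in self.tile_classes)
        if groups - set(self.priority):
            raise ValueError(
                f"priority order does not cover groups {groups - set(self.priority)}"
            )

    @property
    def slide_groups(self) -> tuple[str, ...]:
        """Slide-level groups in priority order."""
        return self.priority

    def group_of(self, finding: str) -> str:
        return self.merge_map[finding]

    def label_index(self, group: str) -> int:
        """Integer label for a group in a LabelMask (background is 0)."""
        return self.priority.index(group) + 1


DEFAULT_SCHEME = ClassScheme()
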