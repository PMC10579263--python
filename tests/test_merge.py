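"""Slide stitching, fibrosis group merge, and priority overlap resolution."""

import numpy as np
import pytest

from hepaseg.annotation_io import AnnotatedRegion, AnnotationSet, Polygon
from hepaseg.backend import InstancePrediction
from hepaseg.merge import (
    LabelMask,
    annotation_group_masks,
    merge_annotations,
    render_overlay,
    resolve_overlaps,
    stitch,
)
from hepaseg.scheme import CONNECTIVE_GROUP, DEFAULT_SCHEME
from hepaseg.tiling import Tile


def _tile(row, col, size=448):
    return Tile(
        "s",
        row,
        col,
        np.zeros((size, size, 3), np.uint8),
        AnnotationSet(f"s_r{row}_c{col}", size, size),
        tile_size=size,
    )


def _point_pred(r, c, finding, tile_id, size=448):
    mask = np.zeros((size, size), bool)
    mask[r, c] = True
    return InstancePrediction(tile_id, finding, mask, 1.0)


class TestStitch:
    def test_origin_offsets(self):
        tiles = [_tile(0, 0), _tile(1, 0)]
        preds = {
            "s_r0_c0": [_point_pred(5, 7, "necrosis", "s_r0_c0")],
            "s_r1_c0": [_point_pred(5, 7, "necrosis", "s_r1_c0")],
        }
        masks = stitch(preds, tiles, (896, 448))
        assert masks["necrosis"][5, 7]
        assert masks["necrosis"][448 + 5, 7]
        assert masks["necrosis"].sum() == 2

    def test_fibrosis_and_connective_share_a_group(self):
        tiles = [_tile(0, 0)]
        preds = {
            "s_r0_c0": [
                _point_pred(1, 1, "fibrosis", "s_r0_c0"),
                _point_pred(2, 2, "connective_tissue", "s_r0_c0"),
            ]
        }
        masks = stitch(preds, tiles, (448, 448))
        assert masks[CONNECTIVE_GROUP][1, 1] and masks[CONNECTIVE_GROUP][2, 2]

    def test_unknown_tile_and_out_of_bounds_origin_rejected(self):
        with pytest.raises(ValueError, match="unknown tile"):
            stitch({"nope": [_point_pred(0, 0, "necrosis", "nope")]},
                   [_tile(0, 0)], (448, 448))
        with pytest.raises(ValueError, match="outside"):
            stitch({"s_r1_c0": [_point_pred(0, 0, "necrosis", "s_r1_c0")]},
                   [_tile(1, 0)], (448, 448))


def _masks(shape, **groups):
    out = {g: np.zeros(shape, bool) for g in DEFAULT_SCHEME.priority}
    for g, coords in groups.items():
        for r, c in coords:
            out[g][r, c] = True
    return out


class TestResolveOverlaps:
    def test_printed_priority_orderings_hold(self):
        shape = (4, 4)
        lm = resolve_overlaps(
            _masks(
                shape,
                necrosis=[(0, 0)],
                vacuolation=[(0, 0), (1, 1)],
                infiltration=[(2, 2)],
                portal_area=[(2, 2)],
            )
        )
        assert lm.labels[0, 0] == DEFAULT_SCHEME.label_index("necrosis")
        assert lm.labels[1, 1] == DEFAULT_SCHEME.label_index("vacuolation")
        assert lm.labels[2, 2] == DEFAULT_SCHEME.label_index("infiltration")
        assert lm.labels[3, 3] == 0  # unclaimed stays background

    def test_necrosis_beats_all_vacuolation_loses_to_all(self):
        shape = (1, 1)
        for other in DEFAULT_SCHEME.priority[1:]:
            lm = resolve_overlaps(_masks(shape, necrosis=[(0, 0)], **{other: [(0, 0)]}))
            assert lm.labels[0, 0] == DEFAULT_SCHEME.label_index("necrosis")
        for other in DEFAULT_SCHEME.priority[:-1]:
            lm = resolve_overlaps(
                _masks(shape, vacuolation=[(0, 0)], **{other: [(0, 0)]})
            )
            assert lm.labels[0, 0] == DEFAULT_SCHEME.label_index(other)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_argmax_oracle(self, seed):
        rng = np.random.default_rng(seed)
        shape = (64, 64)
        masks = {
            g: rng.random(shape) < 0.3 for g in DEFAULT_SCHEME.priority
        }
        lm = resolve_overlaps(masks)
        # oracle: per pixel, first claiming group in priority order
        for r in range(0, 64, 7):
            for c in range(0, 64, 7):
                expect = 0
                for i, g in enumerate(DEFAULT_SCHEME.priority):
                    if masks[g][r, c]:
                        expect = i + 1
                        break
                assert lm.labels[r, c] == expect

    def test_idempotent_and_order_independent(self, rng):
        shape = (32, 32)
        masks = {g: rng.random(shape) < 0.4 for g in DEFAULT_SCHEME.priority}
        lm = resolve_overlaps(masks)
        again = resolve_overlaps(
            {g: lm.group_mask(g) for g in DEFAULT_SCHEME.priority}
        )
        assert np.array_equal(lm.labels, again.labels)
        reordered = resolve_overlaps(dict(reversed(list(masks.items()))))
        assert np.array_equal(lm.labels, reordered.labels)

    def test_lower_priority_claim_never_changes_labels(self, rng):
        shape = (32, 32)
        masks = {g: rng.random(shape) < 0.4 for g in DEFAULT_SCHEME.priority}
        before = resolve_overlaps(masks).labels
        claimed = before > 0
        extra = dict(masks)
        extra["vacuolation"] = masks["vacuolation"] | claimed
        after = resolve_overlaps(extra).labels
        assert np.array_equal(before[claimed], after[claimed])

    def test_pixel_conservation(self, rng):
        shape = (32, 32)
        masks = {g: rng.random(shape) < 0.4 for g in DEFAULT_SCHEME.priority}
        lm = resolve_overlaps(masks)
        counts = lm.counts()
        background = (lm.labels == 0).sum()
        assert sum(counts.values()) + background == 32 * 32


class TestAnnotationPath:
    def test_truth_goes_through_same_merge(self):
        square = Polygon(((0, 0), (10, 0), (10, 10), (0, 10)))
        ann = AnnotationSet(
            "s",
            448,
            448,
            [
                AnnotatedRegion(square, "fibrosis", "s"),
                AnnotatedRegion(square, "connective_tissue", "s"),
            ],
        )
        masks = annotation_group_masks(ann)
        assert masks[CONNECTIVE_GROUP].sum() == 100  # unioned, not doubled
        lm = merge_annotations(ann)
        assert lm.provenance == "annotation"
        assert lm.counts()[CONNECTIVE_GROUP] == 100


class TestRenderOverlay:
    def test_background_only_is_identity(self, rng):
        img = rng.integers(0, 255, (16, 16, 3), dtype=np.uint8)
        lm = LabelMask(np.zeros((16, 16), np.uint8), DEFAULT_SCHEME)
        assert np.array_equal(render_overlay(lm, img), img)

    def test_vacuolation_tinted_red_exactly_on_its_pixels(self, rng):
        img = rng.integers(0, 200, (16, 16, 3), dtype=np.uint8)
        labels = np.zeros((16, 16), np.uint8)
        labels[4:8, 4:8] = DEFAULT_SCHEME.label_index("vacuolation")
        out = render_overlay(LabelMask(labels, DEFAULT_SCHEME), img, alpha=1.0)
        assert (out[4:8, 4:8] == (255, 0, 0)).all()
        untouched = labels == 0
        assert np.array_equal(out[untouched], img[untouched])

    def test_dimension_mismatch_rejected(self, rng):
        img = rng.integers(0, 255, (8, 8, 3), dtype=np.uint8)
        lm = LabelMask(np.zeros((16, 16), np.uint8), DEFAULT_SCHEME)
        with pytest.raises(ValueError):
            render_overlay(lm, img)
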