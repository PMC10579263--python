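"""IoU, greedy matching, average precision, transformed mAP, area regression."""

import numpy as np
import pandas as pd
import pytest

from hepaseg.backend import InstancePrediction
from hepaseg.evaluation import (
    GroundTruthInstance,
    MatchResult,
    area_report,
    average_precision,
    evaluate,
    iou,
    match_instances,
    mean_ap,
    regress,
    regress_all,
)
from hepaseg.merge import LabelMask
from hepaseg.scheme import ClassScheme, DEFAULT_SCHEME


def _mask(coords, size=16):
    m = np.zeros((size, size), bool)
    for r, c in coords:
        m[r, c] = True
    return m


def _rect(r0, c0, h, w, size=16):
    m = np.zeros((size, size), bool)
    m[r0 : r0 + h, c0 : c0 + w] = True
    return m


class TestIoU:
    def test_identical_disjoint_partial(self):
        a = _rect(0, 0, 2, 2)
        assert iou(a, a) == 1.0
        assert iou(a, _rect(8, 8, 2, 2)) == 0.0
        # two 2x2 squares sharing a 1x2 strip: 2 / 6
        assert iou(_rect(0, 0, 2, 2), _rect(1, 0, 2, 2)) == pytest.approx(2 / 6)

    def test_symmetric(self, rng):
        a, b = rng.random((16, 16)) < 0.4, rng.random((16, 16)) < 0.4
        assert iou(a, b) == iou(b, a)

    def test_both_empty_undefined(self):
        with pytest.raises(ValueError, match="empty"):
            iou(np.zeros((4, 4), bool), np.zeros((4, 4), bool))

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            iou(np.zeros((4, 4), bool), np.zeros((5, 5), bool))


def _p(score, mask, finding="necrosis"):
    return InstancePrediction("t", finding, mask, score)


class TestMatchInstances:
    def test_iou_above_threshold_is_tp(self):
        gt = [GroundTruthInstance("necrosis", _rect(0, 0, 2, 5))]
        # overlap 8/10 px -> IoU 8/12 = 0.667... wait; use 7/10 overlap
        pred = _p(0.9, _rect(0, 0, 2, 4))  # IoU 8/10 = 0.8
        res = match_instances([pred], gt)
        assert (res.tp(), res.fp(), res.fn()) == (1, 0, 0)

    def test_iou_below_threshold_is_fp_plus_fn(self):
        gt = [GroundTruthInstance("necrosis", _rect(0, 0, 2, 5))]
        pred = _p(0.9, _rect(0, 0, 2, 3))  # IoU 6/10 = 0.6 < 0.667
        res = match_instances([pred], gt)
        assert (res.tp(), res.fp(), res.fn()) == (0, 1, 1)

    def test_class_mismatch_never_matches(self):
        gt = [GroundTruthInstance("vacuolation", _rect(0, 0, 2, 5))]
        res = match_instances([_p(0.9, _rect(0, 0, 2, 5))], gt)
        assert (res.tp(), res.fp(), res.fn()) == (0, 1, 1)

    def test_higher_score_wins_single_gt(self):
        gt = [GroundTruthInstance("necrosis", _rect(0, 0, 4, 4))]
        hi, lo = _p(0.9, _rect(0, 0, 4, 4)), _p(0.8, _rect(0, 0, 4, 3))
        for order in ([hi, lo], [lo, hi]):  # input order irrelevant
            res = match_instances(order, gt)
            by_score = {s: m is not None for s, _, m, _ in res.records}
            assert by_score == {0.9: True, 0.8: False}

    def test_greedy_matches_best_available_iou(self):
        gts = [
            GroundTruthInstance("necrosis", _rect(0, 0, 4, 4)),
            GroundTruthInstance("necrosis", _rect(8, 8, 4, 4)),
        ]
        preds = [_p(0.9, _rect(0, 0, 4, 4)), _p(0.8, _rect(8, 8, 4, 4))]
        res = match_instances(preds, gts)
        assert res.tp() == 2 and res.fn() == 0

    def test_each_gt_matched_at_most_once(self):
        gt = [GroundTruthInstance("necrosis", _rect(0, 0, 4, 4))]
        preds = [_p(0.9, _rect(0, 0, 4, 4)), _p(0.8, _rect(0, 0, 4, 4))]
        res = match_instances(preds, gt)
        assert (res.tp(), res.fp()) == (1, 1)


def _mr(rows, n_gt, image_id="i"):
    """Build a MatchResult from (score, cls, is_tp) rows."""
    records, k = [], 0
    for score, cls, is_tp in rows:
        records.append((score, cls, k if is_tp else None, 1.0 if is_tp else 0.0))
        if is_tp:
            k += 1
    return MatchResult(image_id=image_id, records=records, n_gt=dict(n_gt),
                       iou_threshold=0.667)


def _brute_force_ap(rows, n_gt):
    """Independent oracle: precision at every distinct score cutoff, then
    explicit monotone-envelope integration."""
    points = []
    for cutoff in sorted({s for s, _, _ in rows}, reverse=True):
        kept = [r for r in rows if r[0] >= cutoff]
        tp = sum(1 for r in kept if r[2])
        points.append((tp / n_gt, tp / len(kept)))
    ap, prev_r = 0.0, 0.0
    for r, _ in sorted(points):
        p_env = max(p2 for r2, p2 in points if r2 >= r)
        ap += (r - prev_r) * p_env
        prev_r = r
    return ap


class TestAveragePrecision:
    def test_perfect_detector(self):
        res = _mr([(0.9, "necrosis", True)], {"necrosis": 1})
        assert average_precision(res, "necrosis") == 1.0

    def test_tp_ranked_above_fp_full_recall_first(self):
        res = _mr([(0.9, "necrosis", True), (0.8, "necrosis", False)],
                  {"necrosis": 1})
        assert average_precision(res, "necrosis") == 1.0

    def test_fp_ranked_above_tp_halves_ap(self):
        res = _mr([(0.9, "necrosis", False), (0.8, "necrosis", True)],
                  {"necrosis": 1})
        assert average_precision(res, "necrosis") == 0.5

    def test_no_predictions_zero_ap(self):
        assert average_precision(_mr([], {"necrosis": 2}), "necrosis") == 0.0

    def test_no_ground_truth_rejected(self):
        with pytest.raises(ValueError, match="ground-truth"):
            average_precision(_mr([], {}), "necrosis")

    @pytest.mark.parametrize("seed", range(25))
    def test_equals_brute_force_all_cutoff_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_gt = int(rng.integers(1, 7))
        n_pred = int(rng.integers(1, 21))
        rows, tp_left = [], n_gt
        for _ in range(n_pred):
            score = round(float(rng.random()), 2)  # duplicates create ties
            is_tp = bool(rng.random() < 0.5) and tp_left > 0
            tp_left -= is_tp
            rows.append((score, "necrosis", is_tp))
        got = average_precision(_mr(rows, {"necrosis": n_gt}), "necrosis")
        assert got == pytest.approx(_brute_force_ap(rows, n_gt), abs=1e-12)

    def test_eleven_point_variant_close_to_all_point(self):
        res = _mr([(0.9, "necrosis", True), (0.7, "necrosis", False),
                   (0.6, "necrosis", True)], {"necrosis": 2})
        allp = average_precision(res, "necrosis")
        eleven = average_precision(res, "necrosis", interpolation="11point")
        assert 0 <= eleven <= 1 and abs(allp - eleven) < 0.2


class TestEvaluateAndTransformed:
    def test_perfect_images_give_equal_maps(self):
        results = [_mr([(1.0, "necrosis", True)], {"necrosis": 1}, f"i{k}")
                   for k in range(3)]
        res = evaluate(results)
        assert res.map == res.transformed_map == 1.0

    def test_image_with_fp_contributes_zero(self):
        good = _mr([(1.0, "necrosis", True)], {"necrosis": 1}, "a")
        bad = _mr([(1.0, "necrosis", True), (0.9, "necrosis", False)],
                  {"necrosis": 1}, "b")
        res = evaluate([good, bad])
        assert res.transformed_map == pytest.approx(0.5)
        assert res.map > res.transformed_map

    def test_all_images_flagged_gives_zero(self):
        bad = _mr([(0.9, "necrosis", False)], {"necrosis": 1})
        assert evaluate([bad, bad]).transformed_map == 0.0

    def test_transformed_never_exceeds_map(self, rng):
        for _ in range(30):
            results = []
            for i in range(int(rng.integers(1, 5))):
                rows, tp_left = [], 2
                for _ in range(int(rng.integers(0, 5))):
                    is_tp = bool(rng.random() < 0.6) and tp_left > 0
                    tp_left -= is_tp
                    rows.append((float(rng.random()), "necrosis", is_tp))
                results.append(_mr(rows, {"necrosis": 2}, f"i{i}"))
            res = evaluate(results)
            assert res.transformed_map <= res.map + 1e-12
            if all(not r.has_misprediction for r in results):
                assert res.transformed_map == pytest.approx(res.map)

    def test_class_without_ground_truth_excluded(self):
        res = evaluate(
            [_mr([(1.0, "necrosis", True)], {"necrosis": 1})],
            classes=["necrosis", "fibrosis"],
        )
        assert res.excluded_classes == ["fibrosis"]
        assert set(res.per_class_ap) == {"necrosis"}

    def test_mean_ap_is_unweighted_mean(self):
        assert mean_ap({"a": 1.0, "b": 0.5}) == pytest.approx(0.75)


def _label_mask(counts, scheme=DEFAULT_SCHEME, size=64):
    labels = np.zeros((size, size), np.uint8)
    col = 0
    for group, n in counts.items():
        idx = scheme.label_index(group)
        labels.flat[col : col + n] = idx
        col += n
    return LabelMask(labels, scheme)


class TestAreaReport:
    def test_identity_prediction(self):
        lm = _label_mask({"necrosis": 30, "vacuolation": 10})
        rep = area_report(lm, lm, "s1")
        assert (rep.annotated_pixels == rep.predicted_pixels).all()
        assert rep.loc[rep.group == "necrosis", "annotated_pixels"].item() == 30

    def test_empty_prediction(self):
        pred = LabelMask(np.zeros((64, 64), np.uint8), DEFAULT_SCHEME)
        rep = area_report(pred, _label_mask({"necrosis": 30}), "s1")
        assert (rep.predicted_pixels == 0).all()

    def test_scheme_mismatch_rejected(self):
        other = ClassScheme(priority=tuple(reversed(DEFAULT_SCHEME.priority)))
        with pytest.raises(ValueError, match="scheme"):
            area_report(
                _label_mask({"necrosis": 5}),
                _label_mask({"necrosis": 5}, scheme=other),
                "s1",
            )


class TestRegress:
    def _report(self, x, y, group="necrosis"):
        return pd.DataFrame(
            {
                "slide_id": [f"s{i}" for i in range(len(x))],
                "group": group,
                "annotated_pixels": x,
                "predicted_pixels": y,
            }
        )

    def test_identity_data(self):
        x = np.arange(10) * 100 + 50
        res = regress(self._report(x, x), "necrosis")
        assert res.slope == pytest.approx(1.0)
        assert res.intercept == pytest.approx(0.0, abs=1e-9)
        assert res.r_squared == pytest.approx(1.0)

    def test_exact_linear_map(self):
        x = np.arange(10) * 100 + 50
        res = regress(self._report(x, 2 * x), "necrosis")
        assert res.slope == pytest.approx(2.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_noise_r2_matches_closed_form(self):
        rng = np.random.default_rng(0)
        n, sd = 200, 50.0
        x = rng.uniform(0, 1000, n)
        y = x + rng.normal(0, sd, n)
        res = regress(self._report(x, y), "necrosis")
        expect = np.var(x) / (np.var(x) + sd**2)
        assert res.r_squared == pytest.approx(expect, abs=0.05)

    def test_too_few_slides_and_degenerate_variance_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            regress(self._report([1, 2], [1, 2]), "necrosis")
        with pytest.raises(ValueError, match="variance"):
            regress(self._report([5, 5, 5], [1, 2, 3]), "necrosis")

    def test_regress_all_covers_groups(self):
        x = np.arange(5) * 10 + 5.0
        rep = pd.concat(
            [self._report(x, x, "necrosis"), self._report(x, 3 * x, "vacuolation")],
            ignore_index=True,
        )
        table = regress_all(rep).set_index("group")
        assert table.loc["necrosis", "slope"] == pytest.approx(1.0)
        assert table.loc["vacuolation", "slope"] == pytest.approx(3.0)
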