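"""Tests of pixel/detection metrics and the detector losses."""
import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from orchardvision import (
    Box,
    Detection,
    Mask,
    average_precision,
    bce_loss,
    box_iou,
    ciou_loss,
    count_nwp,
    f1_score,
    map_over_classes,
    match_detections,
    pixel_eval,
    precision_recall_f1,
    promotion_ratio,
    rbp,
)
from orchardvision.image import ROAD, VEGETATION


def road_mask(arr):
    return Mask(np.where(np.asarray(arr) > 0, 255, 0).astype(np.uint8), ROAD)


def random_boxes(rng, n, span=20.0):
    out = []
    for _ in range(n):
        x0, y0 = rng.uniform(0, span, 2)
        out.append(Box(x0, y0, x0 + rng.uniform(1, 8), y0 + rng.uniform(1, 8)))
    return out


class TestPixelMetrics:
    def test_identical_masks_no_wrong_pixels(self, rng):
        m = road_mask(rng.random((8, 8)) < 0.5)
        assert count_nwp(m, m) == 0

    def test_full_vs_empty(self):
        full = road_mask(np.ones((6, 7)))
        empty = road_mask(np.zeros((6, 7)))
        assert count_nwp(full, empty) == 42
        assert count_nwp(empty, full) == 0
        assert count_nwp(empty, full, symmetric=True) == 42

    def test_matches_loop_oracle(self, rng):
        for _ in range(10):
            p = road_mask(rng.random((8, 8)) < 0.5)
            g = road_mask(rng.random((8, 8)) < 0.5)
            expect = sum(
                1
                for y in range(8)
                for x in range(8)
                if p.pixels[y, x] == 255 and g.pixels[y, x] == 0
            )
            assert count_nwp(p, g) == expect

    def test_shape_and_polarity_checked(self):
        with pytest.raises(ValueError):
            count_nwp(road_mask(np.zeros((4, 4))), road_mask(np.zeros((4, 5))))
        with pytest.raises(ValueError):
            count_nwp(
                road_mask(np.zeros((4, 4))),
                Mask(np.zeros((4, 4), np.uint8), VEGETATION),
            )

    @pytest.mark.parametrize(
        "nwp,nrp,expected",
        [(8506, 402668, 2.11), (194780, 402668, 48.37), (0, 10, 0.0)],
    )
    def test_rbp_values(self, nwp, nrp, expected):
        assert round(rbp(nwp, nrp), 2) == expected

    def test_rbp_guards(self):
        with pytest.raises(ValueError):
            rbp(1, 0)
        with pytest.raises(ValueError):
            rbp(11, 10)

    @given(st.integers(0, 1000), st.integers(0, 1000))
    def test_rbp_linear_and_bounded(self, a, b):
        nrp = 2000
        assert 0.0 <= rbp(a, nrp) <= 100.0
        assert rbp(a, nrp) + rbp(b, nrp) == pytest.approx(rbp(a + b, nrp))

    def test_pixel_eval_consistency(self, rng):
        p = road_mask(rng.random((10, 12)) < 0.4)
        g = road_mask(rng.random((10, 12)) < 0.4)
        pe = pixel_eval(p, g)
        assert pe.nrp == 120
        assert pe.rbp == pytest.approx(100.0 * pe.nwp / 120.0, abs=1e-9)


class TestBoxIoU:
    def test_identical(self):
        b = Box(0, 0, 4, 3)
        assert box_iou(b, b) == pytest.approx(1.0)

    def test_disjoint(self):
        assert box_iou(Box(0, 0, 1, 1), Box(5, 5, 6, 6)) == 0.0

    def test_half_overlapping_unit_squares(self):
        assert box_iou(Box(0, 0, 1, 1), Box(0.5, 0, 1.5, 1)) == pytest.approx(1 / 3)

    def test_degenerate_box_rejected(self):
        with pytest.raises(ValueError):
            Box(0, 0, 0, 1)


class TestMatching:
    def test_perfect_predictions(self):
        gts = [Box(0, 0, 2, 2), Box(5, 5, 7, 7)]
        preds = [Detection(b, 0.9) for b in gts]
        assert match_detections(preds, gts, 0.5) == (2, 0, 0)

    def test_no_predictions(self):
        assert match_detections([], [Box(0, 0, 1, 1)] * 0 + [Box(0, 0, 1, 1), Box(2, 2, 3, 3)], 0.5) == (0, 0, 2)

    def test_each_gt_matched_once(self):
        gt = [Box(0, 0, 2, 2)]
        preds = [Detection(Box(0, 0, 2, 2), 0.9), Detection(Box(0.1, 0, 2.1, 2), 0.8)]
        assert match_detections(preds, gt, 0.5) == (1, 1, 0)

    def test_greedy_small_case_oracle(self, rng):
        """Greedy confidence-descending matching equals a step-by-step
        re-enactment on random 3-pred / 2-gt instances."""
        for _ in range(50):
            gts = random_boxes(rng, 2)
            preds = [Detection(b, float(c)) for b, c in zip(random_boxes(rng, 3), rng.random(3))]
            tp, fp, fn = match_detections(preds, gts, 0.3)
            claimed = set()
            tp_oracle = 0
            for d in sorted(preds, key=lambda d: -d.confidence):
                cands = [
                    (box_iou(d.box, g), j)
                    for j, g in enumerate(gts)
                    if j not in claimed and box_iou(d.box, g) >= 0.3
                ]
                if cands:
                    best = max(cands, key=lambda t: (t[0], -t[1]))
                    claimed.add(best[1])
                    tp_oracle += 1
            assert (tp, fp, fn) == (tp_oracle, 3 - tp_oracle, 2 - tp_oracle)

    def test_threshold_validated(self):
        with pytest.raises(ValueError):
            match_detections([], [], 0.0)


class TestPrf:
    def test_rate_based_f1_at_reference_point(self):
        # P = 88.9%, R = 89.7% -> F1 = 89.3%
        assert round(100 * f1_score(0.889, 0.897), 1) == 89.3
        with pytest.raises(ValueError):
            f1_score(1.2, 0.5)

    def test_degenerate_counts(self):
        assert precision_recall_f1(0, 0, 0) == (0.0, 0.0, 0.0)

    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50))
    def test_f1_between_p_and_r(self, tp, fp, fn):
        p, r, f1 = precision_recall_f1(tp, fp, fn)
        assert min(p, r) - 1e-12 <= f1 <= max(p, r) + 1e-12

    def test_equal_p_r_gives_f1(self):
        p, r, f1 = precision_recall_f1(10, 5, 5)
        assert p == r == pytest.approx(f1)


class TestAveragePrecision:
    def test_all_correct(self):
        gts = [Box(0, 0, 2, 2), Box(5, 5, 7, 7)]
        preds = [Detection(gts[0], 0.3), Detection(gts[1], 0.9)]
        assert average_precision(preds, gts) == pytest.approx(1.0)

    def test_all_wrong(self):
        gts = [Box(0, 0, 2, 2)]
        preds = [Detection(Box(10, 10, 12, 12), 0.9)]
        assert average_precision(preds, gts) == 0.0

    def test_no_gts_flagged_nan(self):
        assert math.isnan(average_precision([Detection(Box(0, 0, 1, 1), 0.5)], []))

    def test_five_prediction_staircase(self):
        """Hand-computed PR staircase: flags (T,F,T,T,F) over 3 truths give
        AP = 1/3 * (1 + 3/4 + 3/4)."""
        gts = [Box(0, 0, 2, 2), Box(10, 0, 12, 2), Box(20, 0, 22, 2)]
        preds = [
            Detection(gts[0], 0.95),
            Detection(Box(40, 40, 41, 41), 0.9),
            Detection(gts[1], 0.85),
            Detection(gts[2], 0.8),
            Detection(Box(50, 50, 51, 51), 0.7),
        ]
        assert average_precision(preds, gts) == pytest.approx((1 + 0.75 + 0.75) / 3)

    def test_rank_by_rank_oracle(self, rng):
        """AP equals an explicit rank-by-rank PR computation on random
        instances."""
        for _ in range(30):
            gts = random_boxes(rng, int(rng.integers(1, 5)))
            preds = [
                Detection(b, float(c))
                for b, c in zip(random_boxes(rng, int(rng.integers(1, 7))), rng.random(7))
            ]
            got = average_precision(preds, gts, 0.3)

            order = sorted(preds, key=lambda d: -d.confidence)
            claimed = set()
            flags = []
            for d in order:
                cands = [
                    (box_iou(d.box, g), j)
                    for j, g in enumerate(gts)
                    if j not in claimed and box_iou(d.box, g) >= 0.3
                ]
                if cands:
                    best = max(cands, key=lambda t: (t[0], -t[1]))
                    claimed.add(best[1])
                    flags.append(True)
                else:
                    flags.append(False)
            # area under the interpolated staircase, point by point
            tp = 0
            points = []
            for k, f in enumerate(flags, start=1):
                tp += f
                points.append((tp / len(gts), tp / k))
            ap = 0.0
            prev_r = 0.0
            for r, _ in points:
                if r > prev_r:
                    p_max = max(pp for rr, pp in points if rr >= r)
                    ap += (r - prev_r) * p_max
                    prev_r = r
            assert got == pytest.approx(ap, abs=1e-12)

    def test_invariant_to_monotone_confidence_transform(self, rng):
        gts = random_boxes(rng, 3)
        preds = [
            Detection(b, float(c))
            for b, c in zip(random_boxes(rng, 6), np.linspace(0.2, 0.9, 6))
        ]
        base = average_precision(preds, gts, 0.3)
        squeezed = [Detection(d.box, d.confidence**3) for d in preds]
        assert average_precision(squeezed, gts, 0.3) == pytest.approx(base)

    def test_map_single_class_is_ap(self):
        assert map_over_classes({"fruit": 0.71}) == pytest.approx(0.71)
        assert map_over_classes({"a": 0.5, "b": 1.0}) == pytest.approx(0.75)
        with pytest.raises(ValueError):
            map_over_classes({})


class TestCiou:
    def test_identical_boxes_zero_loss(self):
        b = Box(3, 4, 10, 9)
        assert ciou_loss(b, b) == pytest.approx(0.0, abs=1e-12)

    def test_translated_equal_shape_reduces_to_distance_term(self):
        a = Box(0, 0, 4, 2)
        b = Box(6, 1, 10, 3)
        iou = box_iou(a, b)
        rho2 = (8 - 2) ** 2 + (2 - 1) ** 2
        c2 = 10**2 + 3**2
        assert ciou_loss(a, b) == pytest.approx(1 - iou + rho2 / c2, abs=1e-12)

    def test_concentric_aspect_mismatch_hand_value(self):
        # unit square vs concentric 2 x 1 box
        a = Box(-0.5, -0.5, 0.5, 0.5)
        b = Box(-1.0, -0.5, 1.0, 0.5)
        iou = 0.5
        ups = (4 / math.pi**2) * (math.atan(2.0) - math.atan(1.0)) ** 2
        alpha = ups / ((1 - iou) + ups)
        expected = 1 - iou + 0.0 + alpha * ups
        assert ciou_loss(a, b) == pytest.approx(expected, abs=1e-12)

    @given(st.floats(-5, 5), st.floats(-5, 5), st.floats(0.5, 6), st.floats(0.5, 6))
    def test_nonnegative(self, x, y, w, h):
        a = Box(0, 0, 3, 3)
        b = Box(x, y, x + w, y + h)
        assert ciou_loss(a, b) >= -1e-12


class TestBce:
    def test_perfect_predictions_near_zero(self):
        assert bce_loss([1.0, 0.0, 1.0], [1, 0, 1]) == pytest.approx(0.0, abs=1e-5)

    def test_uninformative_half(self):
        assert bce_loss([0.5] * 8, [1, 0, 1, 0, 1, 0, 1, 0]) == pytest.approx(math.log(2), abs=1e-12)

    def test_matches_loop_oracle(self, rng):
        x = rng.uniform(0.01, 0.99, 10)
        y = rng.integers(0, 2, 10)
        expect = -sum(
            yi * math.log(xi) + (1 - yi) * math.log(1 - xi) for xi, yi in zip(x, y)
        ) / 10
        assert bce_loss(x, y) == pytest.approx(expect, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bce_loss([], [])


class TestPromotionRatio:
    def test_no_change(self):
        assert promotion_ratio(5.0, 5.0) == 0.0

    @pytest.mark.parametrize("v_n,v_w,expected", [(100, 123.84, 23.84), (172, 213, 23.84)])
    def test_reported_gains(self, v_n, v_w, expected):
        assert round(100 * promotion_ratio(v_w, v_n), 2) == expected

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            promotion_ratio(1.0, 0.0)
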