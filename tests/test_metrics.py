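"""Dice, IoU, precision/recall, AP and paired comparison against oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pathaware.metrics import (APResult, ap_summary, average_precision,
                               box_iou, compare_methods, dice_score,
                               evaluate_segmentation, precision_recall)
from pathaware.types import BoxAnnotation, Detection


def B(x0, x1, y0, y1):
    return BoxAnnotation(x0, x1, y0, y1)


class TestDiceScore:
    def test_identical_masks(self):
        m = np.array([[1, 1, 0], [0, 1, 0]])
        assert dice_score(m, m, 1) == 1.0

    def test_disjoint_masks(self):
        a = np.array([[1, 0], [0, 0]])
        b = np.array([[0, 0], [0, 1]])
        assert dice_score(a, b, 1) == 0.0

    def test_pixel_counting_worked_example(self):
        # |gt| = 6, |pred| = 4, overlap 3 -> 2*3/10
        gt = np.zeros((2, 6), int)
        gt[0, :6] = 1
        pred = np.zeros((2, 6), int)
        pred[0, 3:6] = 1
        pred[1, 0] = 1
        assert dice_score(pred, gt, 1) == pytest.approx(0.6)

    def test_symmetry_and_absent_class_sentinel(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 3, (8, 8))
        b = rng.integers(0, 3, (8, 8))
        assert dice_score(a, b, 2) == dice_score(b, a, 2)
        assert np.isnan(dice_score(np.zeros((4, 4), int),
                                   np.zeros((4, 4), int), 1))

    def test_region_restriction(self):
        gt = np.ones((2, 4), int)
        pred = np.ones((2, 4), int)
        pred[:, 2:] = 0          # wrong only in the excluded region
        region = np.zeros((2, 4))
        region[:, :2] = 1
        assert dice_score(pred, gt, 1, region) == 1.0

    def test_monotone_in_true_overlap(self):
        gt = np.zeros((1, 10), int)
        gt[0, :6] = 1
        scores = []
        for k in range(1, 7):
            pred = np.zeros((1, 10), int)
            pred[0, :k] = 1
            scores.append(dice_score(pred, gt, 1))
        assert all(b >= a for a, b in zip(scores, scores[1:]))


class TestBoxIoU:
    def test_identical(self):
        assert box_iou(B(0, 10, 0, 10), B(0, 10, 0, 10)) == 1.0

    def test_disjoint(self):
        assert box_iou(B(0, 10, 0, 10), B(20, 30, 0, 10)) == 0.0

    def test_worked_overlap(self):
        # [0,10)x[0,10) vs [5,15)x[0,10): 50 / 150
        assert box_iou(B(0, 10, 0, 10), B(5, 15, 0, 10)) == pytest.approx(1 / 3)


class TestPrecisionRecall:
    def _scenario(self):
        """12 GT boxes; 10 confident detections: 9 TPs and 1 FP."""

        gts = {i: [B(0, 10, 0, 10)] for i in range(12)}
        dets = [Detection(B(0, 10, 0, 10), 0.9, image_id=i) for i in range(9)]
        dets.append(Detection(B(50, 60, 0, 10), 0.8, image_id=9))
        return dets, gts

    def test_eq7_eq8_arithmetic(self):
        dets, gts = self._scenario()
        pr = precision_recall(dets, gts, iou_threshold=0.5)
        assert (pr.tp, pr.fp, pr.fn) == (9, 1, 3)
        assert pr.precision == pytest.approx(0.9)
        assert pr.recall == pytest.approx(0.75)

    def test_all_correct(self):
        gts = {0: [B(0, 10, 0, 10)]}
        dets = [Detection(B(0, 10, 0, 10), 0.99, image_id=0)]
        pr = precision_recall(dets, gts, 0.5)
        assert (pr.precision, pr.recall) == (1.0, 1.0)

    def test_no_detections_with_gt(self):
        gts = {0: [B(0, 10, 0, 10)]}
        pr = precision_recall([], gts, 0.5)
        assert pr.recall == 0.0 and pr.precision == 1.0

    def test_vacuous_case(self):
        pr = precision_recall([], {}, 0.5)
        assert pr.precision == 1.0 and pr.recall == 1.0

    def test_confidence_threshold_filters(self):
        gts = {0: [B(0, 10, 0, 10)]}
        dets = [Detection(B(0, 10, 0, 10), 0.4, image_id=0)]
        assert precision_recall(dets, gts, 0.5).tp == 0


class TestAveragePrecision:
    def test_perfect_single_detection_saturates(self):
        gts = {0: [B(0, 20, 0, 20)]}
        dets = [Detection(B(1, 20, 0, 20), 0.9, image_id=0)]
        assert box_iou(dets[0].box, gts[0][0]) > 0.9
        assert average_precision(dets, gts, 0.5) == 100.0

    def test_below_threshold_scores_zero(self):
        gts = {0: [B(0, 20, 0, 20)]}
        dets = [Detection(B(12, 32, 0, 20), 0.9, image_id=0)]  # IoU 0.25
        assert average_precision(dets, gts, 0.5) == 0.0

    def test_two_detection_hand_ranking(self):
        # FP at conf 0.95 ranks first, TP at 0.9 second: the PR sequence is
        # (p=0, r=0) then (p=0.5, r=1); interpolated precision is 0.5 at
        # every recall point, so AP = 50.
        gts = {0: [B(0, 20, 0, 20)]}
        dets = [Detection(B(100, 120, 0, 20), 0.95, image_id=0),
                Detection(B(0, 20, 0, 20), 0.90, image_id=0)]
        assert average_precision(dets, gts, 0.5) == pytest.approx(50.0)

    def test_no_ground_truth_raises(self):
        with pytest.raises(ValueError, match="no ground-truth"):
            average_precision([], {}, 0.5)

    def test_monotone_rescaling_invariance(self):
        rng = np.random.default_rng(3)
        gts = {i: [B(10 * i, 10 * i + 20, 0, 20)] for i in range(5)}
        dets = []
        for i in range(5):
            x = 10 * i + rng.integers(-8, 8)
            dets.append(Detection(B(max(x, 0), max(x, 0) + 20, 0, 20),
                                  float(rng.uniform(0.1, 0.9)), image_id=i))
        base = average_precision(dets, gts, 0.5)
        squeezed = [Detection(d.box, float(d.score ** 3), d.image_id)
                    for d in dets]
        assert average_precision(squeezed, gts, 0.5) == base

    def test_ap_summary_schema(self):
        gts = {0: [B(0, 20, 0, 20)]}
        dets = [Detection(B(0, 20, 0, 20), 0.9, image_id=0)]
        res = ap_summary(dets, gts)
        assert isinstance(res, APResult)
        assert len(res.per_threshold) == 10
        assert res.ap50 == 100.0 and res.map == pytest.approx(100.0)

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 5000))
    def test_greedy_matching_equals_exhaustive_on_small_sets(self, seed):
        """On <=4 detections, greedy-by-confidence equals the best
        assignment under the AP matching protocol (match in confidence
        order, each detection to the highest-IoU free GT above threshold)."""

        rng = np.random.default_rng(seed)
        n_det, n_gt = rng.integers(1, 5), rng.integers(1, 4)
        gts = [B(int(x), int(x) + 20, 0, 20)
               for x in rng.integers(0, 80, n_gt)]
        dets = sorted((Detection(B(int(x), int(x) + 20, 0, 20),
                                 float(s), image_id=0)
                       for x, s in zip(rng.integers(0, 80, n_det),
                                       rng.uniform(0.1, 1.0, n_det))),
                      key=lambda d: -d.score)

        from pathaware.metrics import _greedy_match

        flags, _ = _greedy_match(dets, {0: gts}, 0.5)

        # oracle: sequential exhaustive matching in confidence order
        free = set(range(n_gt))
        expected = []
        for d in dets:
            best = max(free, key=lambda j: box_iou(d.box, gts[j]),
                       default=None)
            if best is not None and box_iou(d.box, gts[best]) >= 0.5:
                free.remove(best)
                expected.append(True)
            else:
                expected.append(False)
        assert flags == expected


class TestEvaluateSegmentation:
    def test_perfect_predictions(self):
        rng = np.random.default_rng(0)
        gts = [rng.integers(0, 6, (10, 10)) for _ in range(3)]
        report = evaluate_segmentation(gts, gts, "sublayer")
        assert (report.summary["mean"] == 1.0).all()
        assert (report.summary["sd"].fillna(0.0) == 0.0).all()

    def test_schema_has_five_layers_plus_overall(self):
        gt = [np.ones((4, 4), int)]
        report = evaluate_segmentation(gt, gt, "sublayer")
        assert list(report.summary.index) == \
            ["IR", "ONL", "PR-IS", "PR-OS", "RPE", "Overall"]

    def test_two_image_manual_means(self):
        gt1 = np.zeros((1, 10), int); gt1[0, :6] = 1
        pr1 = np.zeros((1, 10), int); pr1[0, 3:7] = 1   # dice 0.6
        gt2 = np.zeros((1, 10), int); gt2[0, :4] = 1
        pr2 = gt2.copy()                                 # dice 1.0
        report = evaluate_segmentation([pr1, pr2], [gt1, gt2], "total")
        assert report.per_image["Total retina"].tolist() == \
            pytest.approx([0.6, 1.0])
        assert report.summary.loc["Total retina", "mean"] == pytest.approx(0.8)
        assert report.summary.loc["Total retina", "sd"] == \
            pytest.approx(np.std([0.6, 1.0], ddof=1))

    def test_box_exclusion_in_sublayer_mode(self):
        gt = np.zeros((4, 10), int)
        gt[1] = 1
        pred = gt.copy()
        pred[:, 6:] = 3          # garbage confined to the box columns
        box = BoxAnnotation(6, 10, 0, 4)
        report = evaluate_segmentation([pred], [gt], "sublayer", [box])
        assert report.per_image.loc[0, "IR"] == 1.0

    def test_empty_test_set_raises(self):
        with pytest.raises(ValueError, match="empty"):
            evaluate_segmentation([], [], "total")


class TestCompareMethods:
    def test_identical_vectors_degenerate_t0(self):
        res = compare_methods([0.9, 0.8, 0.7], [0.9, 0.8, 0.7])
        assert res.t == 0.0 and res.p == 1.0 and res.degenerate

    def test_constant_positive_difference(self):
        res = compare_methods([1.0, 0.75, 0.5], [0.75, 0.5, 0.25])
        assert res.t == float("inf") and res.p == 0.0 and res.degenerate

    def test_five_pair_fixture_matches_scipy(self):
        a = [0.91, 0.88, 0.95, 0.84, 0.90]
        b = [0.80, 0.82, 0.88, 0.79, 0.85]
        ours = compare_methods(a, b)
        ref = stats.ttest_rel(a, b)
        assert ours.t == pytest.approx(ref.statistic, rel=1e-12)
        assert ours.p == pytest.approx(ref.pvalue, rel=1e-12)
        assert ours.dof == 4

    def test_p_shrinks_with_n_for_noisy_constant_shift(self):
        rng = np.random.default_rng(0)
        ps = []
        for n in (5, 20, 80):
            b = rng.normal(0.8, 0.02, n)
            a = b + 0.05 + rng.normal(0, 0.005, n)
            ps.append(compare_methods(a, b).p)
        assert ps[0] > ps[1] > ps[2]
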