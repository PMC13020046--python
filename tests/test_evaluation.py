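"""Metric correctness: IoU, greedy matching, PR/AP, mAP aggregation, F1
curves and the normalized confusion matrix — each checked against hand
computations or independent brute-force references."""

import numpy as np
import pytest

from fracdet.evaluation import (DetectionRecord, IOU_GRID,
                                average_precision, confusion_matrix_normalized,
                                evaluate, f1_vs_confidence, iou_xyxy,
                                map_summary, match_detections, pr_curve)
from oracles import oracle_ap, oracle_match, random_scene

# ------------------------------------------------------------------- tests


class TestIou:
    def test_identical_boxes(self):
        assert iou_xyxy((0, 0, 4, 4), (0, 0, 4, 4)) == 1.0

    def test_disjoint_boxes(self):
        assert iou_xyxy((0, 0, 1, 1), (5, 5, 6, 6)) == 0.0

    def test_analytic_overlap(self):
        assert iou_xyxy((0, 0, 2, 2), (1, 0, 3, 2)) == pytest.approx(1 / 3)

    def test_symmetry(self, rng):
        for _ in range(20):
            a = tuple(np.sort(rng.uniform(0, 10, 2))) + (10.1, 11.0)
            a = (a[0], a[1], a[0] + 2, a[1] + 3)
            b = (a[0] + 1, a[1] - 1, a[2] + 2, a[3] + 1)
            assert iou_xyxy(a, b) == pytest.approx(iou_xyxy(b, a))

    def test_degenerate_box_rejected(self):
        with pytest.raises(ValueError):
            iou_xyxy((0, 0, 0, 4), (0, 0, 4, 4))


class TestMatching:
    def test_exact_hit(self):
        m = match_detections([(0, (0, 0, 10, 10), 0.9)], [(0, (0, 0, 10, 10))], 0.5)
        assert m.tp.sum() == 1 and m.fn == 0

    def test_duplicate_detection_counts_one_tp_one_fp(self):
        dets = [(0, (0, 0, 10, 10), 0.9), (0, (0.5, 0, 10, 10), 0.8)]
        m = match_detections(dets, [(0, (0, 0, 10, 10))], 0.5)
        assert m.tp.tolist() == [True, False]

    def test_class_strict(self):
        m = match_detections([(1, (0, 0, 10, 10), 0.9)], [(0, (0, 0, 10, 10))], 0.5)
        assert m.tp.sum() == 0 and m.fn == 1

    def test_invariants_on_random_scenes(self, rng):
        for _ in range(200):
            dets, gts = random_scene(rng)
            m = match_detections(dets, gts, 0.5)
            assert m.tp.sum() <= len(gts)
            assert m.tp.sum() + (~m.tp).sum() == len(dets)
            assert m.matched_gt.sum() == m.tp.sum()

    def test_agrees_with_bruteforce_oracle(self, rng):
        for _ in range(300):
            dets, gts = random_scene(rng)
            thresh = float(rng.choice([0.3, 0.5, 0.7]))
            m = match_detections(dets, gts, thresh)
            assert m.tp.tolist() == oracle_match(dets, gts, thresh)


class TestPrCurve:
    def test_hand_computed_cumulative_values(self):
        c = pr_curve([True, False, True], [0.9, 0.8, 0.7], n_gt=2)
        np.testing.assert_allclose(c.precision, [1, 0.5, 2 / 3])
        np.testing.assert_allclose(c.recall, [0.5, 0.5, 1.0])

    def test_all_tp_reaches_perfect_corner(self):
        c = pr_curve([True] * 4, [0.9, 0.8, 0.7, 0.6], n_gt=4)
        assert c.precision[-1] == 1.0 and c.recall[-1] == 1.0

    def test_precision_formula(self):
        c = pr_curve([True] * 8 + [False] * 2, np.linspace(0.9, 0.5, 10), n_gt=20)
        assert c.precision[-1] == pytest.approx(0.8)

    def test_tp_without_gt_rejected(self):
        with pytest.raises(ValueError):
            pr_curve([True], [0.9], n_gt=0)


class TestAveragePrecision:
    def test_perfect_detector_scores_one(self):
        assert average_precision(pr_curve([True] * 5, np.linspace(0.9, 0.5, 5), 5)) == 1.0

    def test_single_false_positive_scores_zero(self):
        assert average_precision(pr_curve([False], [0.9], n_gt=1)) == 0.0

    def test_worked_example_matches_independent_oracle(self):
        flags = [True, False, True]
        got = average_precision(pr_curve(flags, [0.9, 0.8, 0.7], n_gt=2))
        assert got == pytest.approx(oracle_ap(flags, 2))

    def test_random_flag_sequences_match_oracle(self, rng):
        for _ in range(100):
            n_gt = int(rng.integers(1, 8))
            n = int(rng.integers(0, 10))
            flags = list(rng.random(n) < 0.5)
            while sum(flags) > n_gt:
                flags[flags.index(True)] = False
            got = average_precision(pr_curve(flags, np.sort(rng.random(n))[::-1], n_gt))
            assert got == pytest.approx(oracle_ap(flags, n_gt))

    def test_rank_only_dependence(self, rng):
        flags = [True, False, True, True, False]
        conf = np.array([0.9, 0.7, 0.6, 0.4, 0.2])
        a = average_precision(pr_curve(flags, conf, 4))
        b = average_precision(pr_curve(flags, conf**3, 4))  # monotone transform
        assert a == b

    def test_trailing_fp_never_increases_ap(self, rng):
        for _ in range(30):
            n_gt = 5
            flags = list(rng.random(6) < 0.6)
            base = average_precision(pr_curve(flags, np.linspace(0.9, 0.4, 6), n_gt))
            worse = average_precision(pr_curve(flags + [False],
                                               np.linspace(0.9, 0.35, 7), n_gt))
            assert worse <= base + 1e-12

    def test_leading_tp_never_decreases_ap(self, rng):
        for _ in range(30):
            n_gt = 6
            flags = list(rng.random(6) < 0.5)
            base = average_precision(pr_curve(flags, np.linspace(0.9, 0.4, 6), n_gt))
            better = average_precision(pr_curve([True] + flags,
                                                np.linspace(0.95, 0.4, 7), n_gt))
            assert better >= base - 1e-12


class TestMapSummary:
    def test_three_class_triplets_reproduce_overall_means(self):
        # per-class AP50 values of the two model rows aggregate to the
        # printed overall numbers
        assert map_summary([0.773, 0.868, 0.810])["mAP50"] == pytest.approx(0.817)
        assert map_summary([0.772, 0.867, 0.776])["mAP50"] == pytest.approx(0.805)

    def test_single_class_map_is_that_ap(self):
        assert map_summary([0.642])["mAP50"] == pytest.approx(0.642)

    def test_nan_classes_excluded(self):
        assert map_summary([0.5, float("nan")])["mAP50"] == pytest.approx(0.5)

    def test_no_defined_ap_rejected(self):
        with pytest.raises(ValueError):
            map_summary([float("nan")])


class TestF1:
    def test_balanced_precision_recall(self):
        f1 = 2 * 0.8 * 0.8 / 1.6
        assert f1 == pytest.approx(0.8)

    def test_f1_curve_values(self):
        # one TP at conf 0.9, one FP at 0.4, single GT
        curve = pr_curve([True, False], [0.9, 0.4], n_gt=1)
        f1s, grid, best = f1_vs_confidence({"c": curve}, grid=np.array([0.2, 0.5, 0.95]))
        # at 0.2: P=0.5, R=1 -> 2/3 ; at 0.5: P=1, R=1 -> 1 ; at 0.95: nothing kept
        np.testing.assert_allclose(f1s["c"], [2 / 3, 1.0, 0.0])
        assert best == pytest.approx(0.5)

    def test_hand_computed_harmonic_mean(self):
        p, r = 0.9, 0.6
        assert 2 * p * r / (p + r) == pytest.approx(0.72)


class TestConfusionMatrix:
    def test_all_correct_gives_identity_block(self):
        dets, gts = [], {}
        for i in range(3):
            img = f"im{i}"
            box = (0, 0, 10, 10)
            dets.append((img, i, box, 0.9))
            gts[img] = [(i, box)]
        cm = confusion_matrix_normalized(dets, gts, 3)
        np.testing.assert_allclose(cm[:3, :3], np.eye(3))

    def test_no_detections_puts_mass_in_background_row(self):
        gts = {"a": [(0, (0, 0, 5, 5))], "b": [(2, (0, 0, 5, 5))]}
        cm = confusion_matrix_normalized([], gts, 3)
        assert cm[3, 0] == 1.0 and cm[3, 2] == 1.0

    def test_mixed_scene_matches_hand_enumeration(self):
        # one image: 3 GT (classes 0,1,2), 4 detections:
        #  - correct hit on GT0, misclassified hit on GT1 (pred 2),
        #  - stray FP (class 1), duplicate on GT0 (unmatched -> FP)
        gts = {"im": [(0, (0, 0, 10, 10)), (1, (20, 0, 30, 10)), (2, (40, 0, 50, 10))]}
        dets = [
            ("im", 0, (0, 0, 10, 10), 0.95),
            ("im", 2, (20, 0, 30, 10), 0.90),
            ("im", 1, (70, 70, 80, 80), 0.85),
            ("im", 0, (1, 0, 10, 10), 0.80),
        ]
        cm = confusion_matrix_normalized(dets, gts, 3, conf_thresh=0.25, iou_thresh=0.45)
        expected = np.zeros((4, 4))
        expected[0, 0] = 1.0       # GT0 -> pred 0
        expected[2, 1] = 1.0       # GT1 -> pred 2 (confusion)
        expected[3, 2] = 1.0       # GT2 missed
        # background column: stray FP (cls 1) + duplicate (cls 0)
        expected[1, 3] = 0.5
        expected[0, 3] = 0.5
        np.testing.assert_allclose(cm, expected)

    def test_columns_with_support_sum_to_one(self, rng):
        for _ in range(30):
            dets_raw, gts_raw = random_scene(rng)
            gts = {"x": gts_raw}
            dets = [("x", c, b, s) for c, b, s in dets_raw]
            cm = confusion_matrix_normalized(dets, gts, 3)
            counts_per_col = cm.sum(axis=0)
            for j in range(4):
                assert counts_per_col[j] == pytest.approx(1.0) or counts_per_col[j] == 0.0


class TestEndToEndEvaluate:
    def test_summary_consistency_on_random_scenes(self, rng):
        gts, dets = {}, []
        for i in range(12):
            d, g = random_scene(rng, max_boxes=6)
            gts[f"im{i}"] = g
            dets.extend((f"im{i}", c, b, s) for c, b, s in d)
        summary = evaluate(dets, gts, 3, class_names=["A1", "A2", "A3"])
        per_ap = [v["ap50"] for v in summary.per_class.values()
                  if not np.isnan(v.get("ap50", float("nan")))]
        assert summary.map50 == pytest.approx(np.mean(per_ap))
        assert 0 <= summary.map50_95 <= summary.map50 + 1e-9
        assert summary.confusion.shape == (4, 4)

    def test_detection_record_validation(self):
        with pytest.raises(ValueError):
            DetectionRecord("im", 0, (5, 5, 4, 9), 0.5)
        with pytest.raises(ValueError):
            DetectionRecord("im", 0, (0, 0, 5, 5), 1.5)

    def test_iou_grid_is_half_to_ninety_five(self):
        np.testing.assert_allclose(IOU_GRID, np.arange(0.50, 0.96, 0.05))
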