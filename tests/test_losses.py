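"""Training objective: class weighting, loss closed forms, target
assignment and the learning-rate schedule."""

import math

import numpy as np
import pytest

from fracdet.arch import ConfigurationError, ModelConfig, assemble_model
from fracdet.nn import Tensor
from fracdet.training import (ClassWeights, DetectionLoss, TrainConfig,
                              assign_targets, box_and_dfl_loss,
                              class_weights_from_counts, classification_loss,
                              lr_schedule, train_loop)


class TestClassWeights:
    def test_study_counts_order_minority_up(self):
        w = class_weights_from_counts((261, 579, 136)).weights
        # A3 (rarest) > A1 > A2 (most frequent)
        assert w[2] > w[0] > w[1]
        assert w.mean() == pytest.approx(1.0)

    def test_uniform_counts_give_unit_weights(self):
        np.testing.assert_allclose(class_weights_from_counts((100, 100, 100)).weights, 1.0)

    def test_two_class_hand_computation(self):
        np.testing.assert_allclose(class_weights_from_counts((1, 2)).weights, [4 / 3, 2 / 3])

    def test_scale_invariance(self):
        a = class_weights_from_counts((261, 579, 136)).weights
        b = class_weights_from_counts((522, 1158, 272)).weights
        np.testing.assert_allclose(a, b)

    def test_zero_count_rejected(self):
        with pytest.raises(ConfigurationError):
            class_weights_from_counts((5, 0, 3))


class TestClassificationLoss:
    def test_zero_logits_give_ln2_per_element(self, rng):
        logits = Tensor(np.zeros((4, 3)), requires_grad=True)
        targets = rng.integers(0, 2, (4, 3)).astype(float)
        loss = classification_loss(logits, targets, ClassWeights(np.ones(3)), norm=1.0)
        assert loss.item() == pytest.approx(12 * math.log(2))

    def test_saturated_correct_predictions_vanish(self):
        targets = np.eye(3)
        logits = Tensor(40.0 * (2 * targets - 1))
        loss = classification_loss(logits, targets, ClassWeights(np.ones(3)), norm=1.0)
        assert loss.item() == pytest.approx(0.0, abs=1e-12)

    def test_doubling_a_class_weight_doubles_its_contribution(self, rng):
        logits_arr = rng.standard_normal((5, 3))
        targets = rng.integers(0, 2, (5, 3)).astype(float)

        def term(weights):
            return classification_loss(Tensor(logits_arr), targets,
                                       ClassWeights(np.array(weights)), norm=1.0).item()

        only_c1 = term([1e-12, 1.0, 1e-12])
        doubled = term([1e-12, 2.0, 1e-12])
        assert doubled == pytest.approx(2 * only_c1)

    def test_targets_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            classification_loss(Tensor(np.zeros((1, 3))), np.array([[0.0, 2.0, 0.0]]),
                                ClassWeights(np.ones(3)))


class TestBoxAndDflLoss:
    def _call(self, pred_boxes, pred_dists, targets, anchors, strides):
        return box_and_dfl_loss(Tensor(pred_boxes, requires_grad=True),
                                Tensor(pred_dists, requires_grad=True),
                                targets, anchors, strides, reg_max=16)

    def test_identical_boxes_give_zero_box_loss(self):
        box = np.array([[10.0, 10.0, 50.0, 50.0]])
        anchors = np.array([[30.0, 30.0]])
        strides = np.array([8.0])
        dists = np.zeros((1, 64))
        box_loss, _ = self._call(box, dists, box, anchors, strides)
        assert box_loss.item() == pytest.approx(0.0, abs=1e-6)

    def test_one_hot_at_integer_target_distance_kills_dfl(self):
        # anchor at (20, 20), stride 8; target box edges exactly 2 bins away
        anchors = np.array([[20.0, 20.0]])
        strides = np.array([8.0])
        target = np.array([[20.0 - 16, 20.0 - 16, 20.0 + 16, 20.0 + 16]])
        dists = np.full((1, 4, 16), -40.0)
        dists[:, :, 2] = 40.0
        _, dfl = self._call(target, dists.reshape(1, 64), target, anchors, strides)
        assert dfl.item() == pytest.approx(0.0, abs=1e-6)

    def test_uniform_distribution_costs_ln_16(self):
        anchors = np.array([[20.0, 20.0]])
        strides = np.array([8.0])
        target = np.array([[4.0, 4.0, 36.0, 36.0]])  # integer distances (2 bins)
        dists = np.zeros((1, 64))
        _, dfl = self._call(target, dists, target, anchors, strides)
        assert dfl.item() == pytest.approx(math.log(16), rel=1e-6)

    def test_degenerate_target_box_rejected(self):
        with pytest.raises(ValueError):
            self._call(np.array([[0.0, 0.0, 1.0, 1.0]]), np.zeros((1, 64)),
                       np.array([[5.0, 5.0, 5.0, 9.0]]),
                       np.array([[2.0, 2.0]]), np.array([8.0]))


def brute_force_assign(scores, boxes, gts, gt_cls, anchors, topk=10, alpha=0.5, beta=6.0):
    """Reference assignment: explicit loops, no vectorization."""
    from fracdet.evaluation import iou_xyxy

    a = len(anchors)
    m = len(gts)
    align = np.zeros((a, m))
    iou = np.zeros((a, m))
    inside = np.zeros((a, m), bool)
    for i in range(a):
        for g in range(m):
            x, y = anchors[i]
            x1, y1, x2, y2 = gts[g]
            inside[i, g] = x1 <= x < x2 and y1 <= y < y2
            try:
                iou[i, g] = iou_xyxy(boxes[i], gts[g])
            except ValueError:
                iou[i, g] = 0.0
            if inside[i, g]:
                align[i, g] = max(scores[i, gt_cls[g]], 1e-9) ** alpha * max(iou[i, g], 0) ** beta
    chosen = np.zeros((a, m), bool)
    for g in range(m):
        cand = [i for i in range(a) if inside[i, g]]
        ranked = sorted(cand, key=lambda i: -align[i, g])[:topk]
        hits = [i for i in ranked if align[i, g] > 0]
        if hits:
            for i in hits:
                chosen[i, g] = True
        elif cand:
            chosen[max(cand, key=lambda i: iou[i, g]), g] = True
    for i in range(a):
        gs = np.flatnonzero(chosen[i])
        if gs.size > 1:
            best = gs[np.argmax(iou[i, gs])]
            chosen[i, :] = False
            chosen[i, best] = True
    return chosen


class TestAssignment:
    def test_no_ground_truth_gives_empty_assignment(self):
        anchors = np.array([[4.0, 4.0], [12.0, 4.0]])
        asn = assign_targets(np.full((2, 3), 0.5), np.tile([0, 0, 8, 8.0], (2, 1)),
                             np.zeros((0, 4)), np.zeros(0, int), anchors, 3)
        assert not asn.fg_mask.any()
        assert (asn.target_scores == 0).all()

    def test_single_covered_cell_is_assigned(self):
        anchors = np.array([[4.0, 4.0], [100.0, 100.0]])
        boxes = np.array([[0, 0, 8, 8.0], [96, 96, 104, 104.0]])
        gt = np.array([[2.0, 2.0, 7.0, 7.0]])
        asn = assign_targets(np.full((2, 3), 0.5), boxes, gt, np.array([1]), anchors, 3)
        assert asn.fg_mask.tolist() == [True, False]
        assert asn.gt_index[0] == 0
        assert asn.target_scores[0, 1] > 0

    def test_conflicting_cells_match_brute_force(self, rng):
        # 4x4 grid of anchors, stride 8; two overlapping ground-truth boxes
        xs, ys = np.meshgrid(np.arange(4) * 8 + 4.0, np.arange(4) * 8 + 4.0)
        anchors = np.stack([xs.ravel(), ys.ravel()], axis=1)
        for trial in range(20):
            scores = rng.random((16, 3))
            pred = np.concatenate([anchors - rng.uniform(2, 10, (16, 2)),
                                   anchors + rng.uniform(2, 10, (16, 2))], axis=1)
            gts = np.array([[0.0, 0.0, 20.0, 20.0], [8.0, 8.0, 30.0, 30.0]])
            gt_cls = np.array([0, 2])
            asn = assign_targets(scores, pred, gts, gt_cls, anchors, 3)
            ref = brute_force_assign(scores, pred, gts, gt_cls, anchors)
            got = np.zeros_like(ref)
            got[asn.fg_mask, asn.gt_index[asn.fg_mask]] = True
            np.testing.assert_array_equal(got, ref)


class TestLrSchedule:
    def _cfg(self, epochs=200):
        return TrainConfig(epochs=epochs)

    def test_initial_rate(self):
        assert lr_schedule(0, self._cfg()) == pytest.approx(0.01)

    def test_final_rate_is_lr0_times_lrf(self):
        assert lr_schedule(199, self._cfg()) == pytest.approx(0.01 * 0.01)

    def test_cosine_midpoint(self):
        cfg = self._cfg(epochs=201)
        assert lr_schedule(100, cfg) == pytest.approx((0.01 + 0.0001) / 2)

    def test_monotone_non_increasing(self):
        cfg = self._cfg(epochs=50)
        rates = [lr_schedule(e, cfg) for e in range(50)]
        assert all(a >= b for a, b in zip(rates, rates[1:]))

    def test_out_of_range_epoch_rejected(self):
        with pytest.raises(ValueError):
            lr_schedule(200, self._cfg())

    def test_zero_epochs_rejected(self):
        with pytest.raises(ConfigurationError):
            TrainConfig(epochs=0)


class TestTraining:
    def test_loss_finite_and_gradients_flow(self, tiny_phantoms):
        items, _ = tiny_phantoms
        model = assemble_model(ModelConfig(replacement_set=("P4",)), seed=0)
        model.train()
        images = np.stack([items[i][0] for i in range(2)]).astype(np.float32)
        targets = [items[i][1] for i in range(2)]
        criterion = DetectionLoss(3)
        total, breakdown = criterion(model(Tensor(images)), targets)
        assert np.isfinite(total.data)
        assert breakdown.total == pytest.approx(
            7.5 * breakdown.box_loss + 0.5 * breakdown.cls_loss + 1.5 * breakdown.dfl_loss)
        assert min(breakdown.box_loss, breakdown.cls_loss, breakdown.dfl_loss) >= 0
        total.backward()
        grads = [p.grad for p in model.parameters() if p.grad is not None]
        assert grads, "no gradients reached the parameters"
        assert all(np.isfinite(g).all() for g in grads)

    def test_same_seed_reproduces_loss_sequence(self, tiny_phantoms):
        items, _ = tiny_phantoms
        cfg = TrainConfig(batch_size=2, epochs=2, imgsz=160, seed=4,
                          warmup_epochs=0.5, max_iters=4)
        runs = []
        for _ in range(2):
            model = assemble_model(ModelConfig(replacement_set=("P4", "P5")), seed=9)
            hist = train_loop(model, items[:4], cfg)
            runs.append(hist["iter_total"])
        assert runs[0] == runs[1]

    def test_empty_dataset_rejected(self):
        model = assemble_model(ModelConfig())
        with pytest.raises(ConfigurationError):
            train_loop(model, [], TrainConfig(epochs=1))
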