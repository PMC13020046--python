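"""Training objective and loop: class-weighted detection loss, task-aligned
target assignment, cosine learning-rate schedule and seeded SGD training.

The composite loss has three parts, combined as
``total = w_box·box + w_cls·cls + w_dfl·dfl`` (defaults 7.5 / 0.5 / 1.5):

* classification — per-class-weighted binary cross-entropy on logits
  against soft alignment targets, summed and normalized by the sum of
  assigned target scores.  The per-class weights come from inverse class
  frequencies so minority fracture grades carry a larger loss penalty.
* box — ``1 − CIoU`` between decoded predictions and ground truth over
  assigned anchor cells (complete IoU: overlap + center distance + aspect
  term).
* dfl — distribution focal loss: cross-entropy of each edge-distance
  distribution against the two integer bins bracketing the target
  distance, linearly weighted.

Assignment is task-aligned: each ground-truth box selects its top-k
(k = 10) candidate cells among those whose centers it contains, scored by
``score^α · IoU^β`` with α = 0.5, β = 6; a cell claimed by several boxes
goes to the one with the higher IoU.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nn
from .nn import Tensor
from .arch import (ConfigurationError, DetectionModel, RawPrediction,
                   anchor_grid, save_checkpoint)
from .evaluation import iou_matrix


@dataclass
class TrainConfig:
    lr0: float = 0.01
    lrf: float = 0.01
    batch_size: int = 16
    epochs: int = 200
    weight_decay: float = 5e-4
    momentum: float = 0.937
    optimizer: str = "sgd"
    seed: int = 0
    box_weight: float = 7.5
    cls_weight: float = 0.5
    dfl_weight: float = 1.5
    warmup_epochs: float = 3.0
    imgsz: int = 640
    max_iters: int | None = None          # optional hard cap on iterations
    stop_loss_ratio: float | None = None  # stop once loss falls to this ×first

    def __post_init__(self):
        if self.lr0 <= 0:
            raise ConfigurationError("lr0 must be > 0")
        if not 0 < self.lrf <= 1:
            raise ConfigurationError("lrf must lie in (0, 1]")
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")
        if self.optimizer.lower() != "sgd":
            raise ConfigurationError(f"unsupported optimizer {self.optimizer!r}")


@dataclass
class ClassWeights:
    weights: np.ndarray

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if (self.weights <= 0).any():
            raise ConfigurationError("class weights must be positive")


@dataclass
class LossBreakdown:
    cls_loss: float
    box_loss: float
    dfl_loss: float
    box_weight: float = 7.5
    cls_weight: float = 0.5
    dfl_weight: float = 1.5

    @property
    def total(self) -> float:
        return (self.box_weight * self.box_loss + self.cls_weight * self.cls_loss
                + self.dfl_weight * self.dfl_loss)


def class_weights_from_counts(counts) -> ClassWeights:
    """Inverse-frequency class weights, normalized to mean 1."""
    counts = np.asarray(counts, dtype=float)
    if (counts <= 0).any():
        raise ConfigurationError("all class counts must be > 0")
    w = 1.0 / counts
    return ClassWeights(w / w.mean())


def lr_schedule(epoch: int, config: TrainConfig) -> float:
    """Cosine annealing from lr0 (epoch 0) to lr0·lrf (final epoch)."""
    if not 0 <= epoch < config.epochs:
        raise ValueError(f"epoch {epoch} outside [0, {config.epochs})")
    if config.epochs == 1:
        return config.lr0
    t = epoch / (config.epochs - 1)
    factor = config.lrf + (1 - config.lrf) * 0.5 * (1 + math.cos(math.pi * t))
    return config.lr0 * factor


# ------------------------------------------------------------- assignment


@dataclass
class Assignment:
    fg_mask: np.ndarray        # (A,) bool
    gt_index: np.ndarray       # (A,) int, -1 for background
    target_scores: np.ndarray  # (A, nc) soft classification targets
    target_boxes: np.ndarray   # (A, 4) xyxy pixels (rows valid where fg)


def assign_targets(pred_scores, pred_boxes, gt_boxes, gt_classes, anchors,
                   num_classes: int, topk: int = 10, alpha: float = 0.5,
                   beta: float = 6.0) -> Assignment:
    """Task-aligned assignment of ground truth to anchor cells (one image)."""
    a = anchors.shape[0]
    gt_boxes = np.asarray(gt_boxes, dtype=float).reshape(-1, 4)
    gt_classes = np.asarray(gt_classes, dtype=int)
    m = gt_boxes.shape[0]
    out = Assignment(np.zeros(a, bool), np.full(a, -1), np.zeros((a, num_classes)), np.zeros((a, 4)))
    if m == 0:
        return out
    inside = ((anchors[:, 0] >= gt_boxes[:, None, 0]) & (anchors[:, 0] < gt_boxes[:, None, 2])
              & (anchors[:, 1] >= gt_boxes[:, None, 1]) & (anchors[:, 1] < gt_boxes[:, None, 3])).T
    # inside: (A, M); alignment metric over candidate cells
    iou = iou_matrix(pred_boxes, gt_boxes)                        # (A, M)
    score = np.take(pred_scores, gt_classes, axis=1)              # (A, M)
    align = np.where(inside, np.clip(score, 1e-9, None) ** alpha * np.clip(iou, 0, None) ** beta, 0.0)
    chosen = np.zeros((a, m), dtype=bool)
    for g in range(m):
        cand = np.flatnonzero(inside[:, g])
        if cand.size == 0:
            continue
        k = min(topk, cand.size)
        top = cand[np.argsort(-align[cand, g], kind="stable")[:k]]
        chosen[top[align[top, g] > 0], g] = True
        if not chosen[:, g].any():  # degenerate scores: keep best-IoU cell
            chosen[cand[np.argmax(iou[cand, g])], g] = True
    # resolve conflicts: a cell serves at most one box (highest IoU wins)
    multi = chosen.sum(axis=1) > 1
    if multi.any():
        best = iou.argmax(axis=1)
        for i in np.flatnonzero(multi):
            keep = best[i] if chosen[i, best[i]] else np.flatnonzero(chosen[i])[
                np.argmax(iou[i, chosen[i]])]
            chosen[i] = False
            chosen[i, keep] = True
    fg = chosen.any(axis=1)
    gt_idx = np.where(fg, chosen.argmax(axis=1), -1)
    # normalized soft targets: align scaled per box to its best IoU
    tscores = np.zeros((a, num_classes))
    for g in range(m):
        cells = np.flatnonzero(chosen[:, g])
        if cells.size == 0:
            continue
        amax = align[cells, g].max()
        imax = iou[cells, g].max()
        t = align[cells, g] / max(amax, 1e-9) * max(imax, 0.0)
        tscores[cells, gt_classes[g]] = t
    tboxes = np.zeros((a, 4))
    tboxes[fg] = gt_boxes[gt_idx[fg]]
    return Assignment(fg, gt_idx, tscores, tboxes)


# ------------------------------------------------------------------ losses


def classification_loss(pred_logits: Tensor, target_scores: np.ndarray,
                        weights: ClassWeights, norm: float | None = None):
    """Per-class-weighted BCE, summed, normalized by target-score sum."""
    t = np.asarray(target_scores)
    if t.min() < 0 or t.max() > 1:
        raise ValueError("target scores must lie in [0, 1]")
    if norm is None:
        norm = max(t.sum(), 1.0)
    w = weights.weights.reshape(*([1] * (t.ndim - 1)), -1)
    elem = pred_logits.bce_with_logits(t)
    return (elem * Tensor(w.astype(elem.dtype))).sum() / norm


def _ciou(pred: Tensor, target: np.ndarray, eps: float = 1e-7) -> Tensor:
    """Complete IoU between predicted (autograd) and target (constant) boxes."""
    tb = np.asarray(target, dtype=float)
    if (tb[:, 2] <= tb[:, 0]).any() or (tb[:, 3] <= tb[:, 1]).any():
        raise ValueError("degenerate target box")
    px1, py1, px2, py2 = pred[:, 0], pred[:, 1], pred[:, 2], pred[:, 3]
    tx1, ty1, tx2, ty2 = tb[:, 0], tb[:, 1], tb[:, 2], tb[:, 3]
    iw = (px2.minimum(tx2) - px1.maximum(tx1)).maximum(0.0)
    ih = (py2.minimum(ty2) - py1.maximum(ty1)).maximum(0.0)
    inter = iw * ih
    pw, ph = px2 - px1, py2 - py1
    area_t = (tx2 - tx1) * (ty2 - ty1)
    union = pw * ph + area_t - inter + eps
    iou = inter / union
    cw = px2.maximum(tx2) - px1.minimum(tx1)
    ch = py2.maximum(ty2) - py1.minimum(ty1)
    c2 = cw**2 + ch**2 + eps
    rho2 = ((tx1 + tx2) / 2 - (px1 + px2) / 2) ** 2 + ((ty1 + ty2) / 2 - (py1 + py2) / 2) ** 2
    tv = np.arctan((tx2 - tx1) / (ty2 - ty1 + eps))
    v = (4 / math.pi**2) * (Tensor(tv) - (pw / (ph + eps)).atan()) ** 2
    with_alpha = v.data / (v.data - iou.data + 1 + eps)  # treated as constant
    return iou - rho2 / c2 - v * Tensor(with_alpha)


def box_and_dfl_loss(pred_boxes: Tensor, pred_dists: Tensor, target_boxes: np.ndarray,
                     anchors: np.ndarray, strides: np.ndarray, reg_max: int,
                     cell_weights: np.ndarray | None = None, norm: float | None = None):
    """CIoU box loss and distribution focal loss over assigned cells.

    ``pred_boxes``: (K, 4) decoded xyxy pixels; ``pred_dists``: (K, 4·reg_max)
    logits; targets in pixels.  Both terms are weighted per cell by the
    assigned target score and normalized by the score sum.
    """
    k = pred_boxes.shape[0]
    if cell_weights is None:
        cell_weights = np.ones(k)
    if norm is None:
        norm = max(cell_weights.sum(), 1.0)
    ciou = _ciou(pred_boxes, target_boxes)
    box_loss = ((1.0 - ciou) * Tensor(cell_weights.astype(ciou.dtype))).sum() / norm

    # target edge distances in bin (stride) units, clipped inside the support
    tb = np.asarray(target_boxes, dtype=float)
    d = np.stack([
        anchors[:, 0] - tb[:, 0], anchors[:, 1] - tb[:, 1],
        tb[:, 2] - anchors[:, 0], tb[:, 3] - anchors[:, 1],
    ], axis=1) / strides[:, None]
    d = np.clip(d, 0, reg_max - 1 - 0.01)
    tl = np.floor(d).astype(int)
    tr = tl + 1
    wl = tr - d
    wr = d - tl
    logp = pred_dists.reshape(k, 4, reg_max).log_softmax(axis=-1)
    ii = np.arange(k)[:, None].repeat(4, axis=1)
    jj = np.arange(4)[None, :].repeat(k, axis=0)
    ce = -(logp[ii, jj, tl] * Tensor(wl.astype(logp.dtype))
           + logp[ii, jj, np.minimum(tr, reg_max - 1)] * Tensor(wr.astype(logp.dtype)))
    dfl_loss = (ce.mean(axis=1) * Tensor(cell_weights.astype(ce.dtype))).sum() / norm
    return box_loss, dfl_loss


class DetectionLoss:
    """Composite detection loss over a batch of raw predictions."""

    def __init__(self, num_classes: int, reg_max: int = 16,
                 class_weights: ClassWeights | None = None,
                 box_weight: float = 7.5, cls_weight: float = 0.5,
                 dfl_weight: float = 1.5):
        self.nc = num_classes
        self.reg_max = reg_max
        self.class_weights = class_weights or ClassWeights(np.ones(num_classes))
        self.box_weight, self.cls_weight, self.dfl_weight = box_weight, cls_weight, dfl_weight
        self._proj = np.arange(reg_max, dtype=np.float32)

    def __call__(self, raw: RawPrediction, targets):
        """targets: per image, (gt_classes (M,), gt_boxes (M, 4) xyxy pixels)."""
        box_t, cls_t, hw = [], [], []
        for b, c in zip(raw.box_logits, raw.cls_logits):
            n, k4, h, w = b.shape
            hw.append((h, w))
            box_t.append(b.reshape(n, k4, h * w).transpose(0, 2, 1))
            cls_t.append(c.reshape(n, c.shape[1], h * w).transpose(0, 2, 1))
        box_l = nn.concat(box_t, axis=1)   # (N, A, 4*reg_max)
        cls_l = nn.concat(cls_t, axis=1)   # (N, A, nc)
        anchors, strides = anchor_grid(hw, raw.strides)
        n, a = cls_l.shape[0], cls_l.shape[1]

        # decode all boxes (needed detached for assignment)
        dist = (box_l.reshape(n, a, 4, self.reg_max).softmax(axis=-1)
                * Tensor(self._proj)).sum(axis=-1)
        sd = strides[None, :, None].astype(np.float32)
        cx = anchors[None, :, 0, None].astype(np.float32)
        cy = anchors[None, :, 1, None].astype(np.float32)
        px1 = cx - dist[:, :, 0:1] * sd
        py1 = cy - dist[:, :, 1:2] * sd
        px2 = cx + dist[:, :, 2:3] * sd
        py2 = cy + dist[:, :, 3:4] * sd
        pred_boxes = nn.concat([px1, py1, px2, py2], axis=2)  # (N, A, 4)
        scores = 1.0 / (1.0 + np.exp(-cls_l.data))

        tscore = np.zeros((n, a, self.nc), dtype=np.float32)
        fg_img, fg_anchor = [], []
        tbox_list, w_list = [], []
        for i in range(n):
            gt_cls, gt_box = targets[i]
            asn = assign_targets(scores[i], pred_boxes.data[i], gt_box, gt_cls,
                                 anchors, self.nc)
            tscore[i] = asn.target_scores
            idx = np.flatnonzero(asn.fg_mask)
            fg_img.extend([i] * idx.size)
            fg_anchor.extend(idx)
            tbox_list.append(asn.target_boxes[idx])
            w_list.append(asn.target_scores[idx].sum(axis=1))

        ts_sum = max(float(tscore.sum()), 1.0)
        cls_loss = classification_loss(cls_l, tscore, self.class_weights, norm=ts_sum)
        if fg_img:
            fi = np.asarray(fg_img)
            fa = np.asarray(fg_anchor)
            pb = pred_boxes[fi, fa]
            pd = box_l[fi, fa]
            tb = np.concatenate(tbox_list)
            cw = np.concatenate(w_list)
            box_loss, dfl_loss = box_and_dfl_loss(
                pb, pd, tb, anchors[fa], strides[fa], self.reg_max,
                cell_weights=cw, norm=ts_sum)
        else:
            box_loss = Tensor(np.zeros(()))
            dfl_loss = Tensor(np.zeros(()))
        total = (self.box_weight * box_loss + self.cls_weight * cls_loss
                 + self.dfl_weight * dfl_loss)
        breakdown = LossBreakdown(
            cls_loss=float(cls_loss.data), box_loss=float(box_loss.data),
            dfl_loss=float(dfl_loss.data), box_weight=self.box_weight,
            cls_weight=self.cls_weight, dfl_weight=self.dfl_weight)
        return total, breakdown


# -------------------------------------------------------------- optimizer


def build_optimizer(model: DetectionModel, config: TrainConfig) -> nn.SGD:
    decay, no_decay = [], []
    for name, p in model.named_parameters():
        (no_decay if name.rsplit(".", 1)[-1] in ("gamma", "beta", "bias") else decay).append(p)
    return nn.SGD(
        [{"params": decay, "weight_decay": config.weight_decay},
         {"params": no_decay, "weight_decay": 0.0}],
        lr=config.lr0, momentum=config.momentum)


# ------------------------------------------------------------- train loop


def train_loop(model: DetectionModel, dataset, config: TrainConfig,
               class_counts=None, out_dir=None, log_every: int = 10):
    """Seeded SGD training over an in-memory dataset.

    ``dataset``: list of (chw float image in [0,1], (gt_classes, gt_boxes_px)).
    Returns a history dict with per-iteration losses and per-epoch records;
    writes ``best.npz``/``last.npz`` checkpoints when ``out_dir`` is given.
    """
    if len(dataset) == 0:
        raise ConfigurationError("training dataset is empty")
    rng = np.random.default_rng(config.seed)
    weights = (class_weights_from_counts(class_counts)
               if class_counts is not None else ClassWeights(np.ones(model.config.num_classes)))
    criterion = DetectionLoss(model.config.num_classes, model.config.reg_max,
                              class_weights=weights, box_weight=config.box_weight,
                              cls_weight=config.cls_weight, dfl_weight=config.dfl_weight)
    opt = build_optimizer(model, config)
    iters_per_epoch = max(1, math.ceil(len(dataset) / config.batch_size))
    warmup_iters = max(round(config.warmup_epochs * iters_per_epoch), 1)
    history = {"iter_total": [], "epochs": []}
    best = math.inf
    it = 0
    first_loss = None
    stop = False
    model.train()
    for epoch in range(config.epochs):
        lr_e = lr_schedule(epoch, config)
        order = rng.permutation(len(dataset))
        ep_losses = []
        for bstart in range(0, len(order), config.batch_size):
            idx = order[bstart : bstart + config.batch_size]
            images = np.stack([np.asarray(dataset[i][0], dtype=np.float32) for i in idx])
            targets = [dataset[i][1] for i in idx]
            if config.warmup_epochs > 0 and it < warmup_iters:
                opt.lr = lr_e * (it + 1) / warmup_iters
            else:
                opt.lr = lr_e
            raw = model(Tensor(images))
            total, breakdown = criterion(raw, targets)
            opt.zero_grad()
            total.backward()
            opt.step()
            history["iter_total"].append(breakdown.total)
            if first_loss is None:
                first_loss = breakdown.total
            ep_losses.append(breakdown)
            it += 1
            if config.stop_loss_ratio is not None and len(history["iter_total"]) >= 3:
                recent = float(np.mean(history["iter_total"][-3:]))
                if recent <= config.stop_loss_ratio * first_loss:
                    stop = True
            if config.max_iters is not None and it >= config.max_iters:
                stop = True
            if stop:
                break
        mean_bd = LossBreakdown(
            cls_loss=float(np.mean([b.cls_loss for b in ep_losses])),
            box_loss=float(np.mean([b.box_loss for b in ep_losses])),
            dfl_loss=float(np.mean([b.dfl_loss for b in ep_losses])),
            box_weight=config.box_weight, cls_weight=config.cls_weight,
            dfl_weight=config.dfl_weight)
        history["epochs"].append({"epoch": epoch, "lr": opt.lr,
                                  "box_loss": mean_bd.box_loss,
                                  "cls_loss": mean_bd.cls_loss,
                                  "dfl_loss": mean_bd.dfl_loss,
                                  "total": mean_bd.total})
        if out_dir is not None:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            save_checkpoint(model, out / "last.npz")
            if mean_bd.total < best:
                best = mean_bd.total
                save_checkpoint(model, out / "best.npz")
        if stop:
            break
    model.eval()
    return history
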