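"""Detection metrics: precision, recall, AP, mAP50, mAP50:95, F1–confidence
curves and the ground-truth-normalized confusion matrix.

Definitions follow the standard object-detection conventions:

* P = TP/(TP+FP), R = TP/(TP+FN), accumulated over detections sorted by
  descending confidence.
* Matching is greedy and one-to-one: each detection claims the highest-IoU
  unmatched ground-truth box of the *same class* with IoU ≥ threshold.
* AP is the area under the precision-envelope PR curve evaluated by
  101-point interpolation (recall grid 0, 0.01, …, 1).
* mAP50 averages per-class AP at IoU 0.5; mAP50:95 additionally averages
  over IoU thresholds 0.5, 0.55, …, 0.95.  Classes without ground truth
  have undefined AP and are excluded from the means.
* The confusion matrix has one extra background row/column; unmatched
  ground truth counts as (background, gt_class), unmatched detections as
  (pred_class, background); columns (ground-truth conditional) are
  normalized to sum to 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

IOU_GRID = np.round(np.arange(0.5, 1.0, 0.05), 2)  # 0.50:0.05:0.95


@dataclass(frozen=True)
class DetectionRecord:
    """A scored prediction in pixel space (xyxy, half-open)."""

    image_id: str
    class_id: int
    box: tuple[float, float, float, float]
    confidence: float

    def __post_init__(self):
        x1, y1, x2, y2 = self.box
        if not (x1 < x2 and y1 < y2):
            raise ValueError(f"degenerate box {self.box}")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")


@dataclass
class MatchResult:
    tp: np.ndarray          # per-detection flag (confidence-sorted order)
    confidences: np.ndarray
    n_gt: int
    matched_gt: np.ndarray  # per-GT matched flag

    @property
    def fn(self) -> int:
        return int(self.n_gt - self.matched_gt.sum())


@dataclass
class PRCurve:
    precision: np.ndarray
    recall: np.ndarray
    confidences: np.ndarray
    n_gt: int


@dataclass
class EvalSummary:
    class_names: list[str]
    per_class: dict        # name -> {precision, recall, ap50, ap50_95}
    mean_precision: float
    mean_recall: float
    map50: float
    map50_95: float
    confusion: "np.ndarray | None" = None

    def as_dict(self) -> dict:
        out = {
            "per_class": {k: dict(v) for k, v in self.per_class.items()},
            "precision": self.mean_precision,
            "recall": self.mean_recall,
            "mAP50": self.map50,
            "mAP50_95": self.map50_95,
        }
        if self.confusion is not None:
            out["confusion_matrix"] = self.confusion.tolist()
        return out


def iou_xyxy(a, b) -> float:
    """Intersection-over-union of two xyxy boxes."""
    ax1, ay1, ax2, ay2 = a
    bx1, by1, bx2, by2 = b
    if ax1 >= ax2 or ay1 >= ay2 or bx1 >= bx2 or by1 >= by2:
        raise ValueError("degenerate box")
    iw = min(ax2, bx2) - max(ax1, bx1)
    ih = min(ay2, by2) - max(ay1, by1)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    union = (ax2 - ax1) * (ay2 - ay1) + (bx2 - bx1) * (by2 - by1) - inter
    return inter / union


def iou_matrix(boxes_a: np.ndarray, boxes_b: np.ndarray) -> np.ndarray:
    """(n, m) pairwise IoU of two xyxy box arrays."""
    a = np.asarray(boxes_a, dtype=float).reshape(-1, 4)
    b = np.asarray(boxes_b, dtype=float).reshape(-1, 4)
    iw = np.minimum(a[:, None, 2], b[None, :, 2]) - np.maximum(a[:, None, 0], b[None, :, 0])
    ih = np.minimum(a[:, None, 3], b[None, :, 3]) - np.maximum(a[:, None, 1], b[None, :, 1])
    inter = np.clip(iw, 0, None) * np.clip(ih, 0, None)
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    return inter / np.maximum(area_a[:, None] + area_b[None, :] - inter, 1e-12)


def match_detections(dets, gts, iou_thresh: float = 0.5) -> MatchResult:
    """Greedy one-to-one matching of detections to same-class ground truth.

    ``dets``: iterable of (class_id, box, confidence); ``gts``: iterable of
    (class_id, box).  Detections are processed in descending confidence
    (ties broken by input order); each claims the highest-IoU unmatched
    ground truth of its class with IoU ≥ ``iou_thresh`` (IoU ties broken by
    first ground-truth index).
    """
    dets = list(dets)
    gts = list(gts)
    conf = np.array([d[2] for d in dets], dtype=float)
    order = np.argsort(-conf, kind="stable")
    tp = np.zeros(len(dets), dtype=bool)
    matched = np.zeros(len(gts), dtype=bool)
    for rank, di in enumerate(order):
        cls, box, _ = dets[di]
        best_iou, best_g = iou_thresh, -1
        for gi, (gcls, gbox) in enumerate(gts):
            if matched[gi] or gcls != cls:
                continue
            v = iou_xyxy(box, gbox)
            if v > best_iou or (v == best_iou and v >= iou_thresh and best_g == -1):
                best_iou, best_g = v, gi
        if best_g >= 0:
            matched[best_g] = True
            tp[rank] = True
    return MatchResult(tp=tp, confidences=conf[order], n_gt=len(gts), matched_gt=matched)


def pr_curve(tp_flags: np.ndarray, confidences: np.ndarray, n_gt: int) -> PRCurve:
    """Cumulative precision/recall over confidence-sorted match flags."""
    tp_flags = np.asarray(tp_flags, dtype=bool)
    if n_gt < 0:
        raise ValueError("n_gt must be >= 0")
    if n_gt == 0 and tp_flags.any():
        raise ValueError("true positives reported with zero ground truth")
    tp_cum = np.cumsum(tp_flags)
    fp_cum = np.cumsum(~tp_flags)
    precision = tp_cum / np.maximum(tp_cum + fp_cum, 1)
    recall = tp_cum / n_gt if n_gt > 0 else np.zeros_like(precision)
    return PRCurve(precision, recall, np.asarray(confidences, dtype=float), n_gt)


def average_precision(curve: PRCurve) -> float:
    """Area under the precision envelope, 101-point interpolation."""
    if curve.n_gt == 0:
        return float("nan")
    if len(curve.precision) == 0:
        return 0.0
    env = np.maximum.accumulate(curve.precision[::-1])[::-1]  # precision envelope
    grid = np.linspace(0, 1, 101)
    # interpolated precision at recall g: envelope at the first curve point
    # reaching recall >= g; zero beyond the maximum achieved recall
    idx = np.searchsorted(curve.recall, grid, side="left")
    interp = np.where(idx < len(env), env[np.minimum(idx, len(env) - 1)], 0.0)
    return float(interp.mean())


def evaluate(detections, ground_truths, num_classes: int,
             class_names=None, conf_thresh_cm: float = 0.25,
             iou_thresh_cm: float = 0.45) -> EvalSummary:
    """Full evaluation over a dataset.

    ``detections``: list of :class:`DetectionRecord` (or tuples with
    image_id, class_id, box, confidence); ``ground_truths``: dict
    image_id -> list of (class_id, box).  Reported per-class precision and
    recall are taken at the confidence maximizing the class F1 score.
    """
    class_names = list(class_names) if class_names else [str(i) for i in range(num_classes)]
    dets_by_img: dict[str, list] = {k: [] for k in ground_truths}
    for d in detections:
        if isinstance(d, DetectionRecord):
            img, cls, box, conf = d.image_id, d.class_id, d.box, d.confidence
        else:
            img, cls, box, conf = d
        dets_by_img.setdefault(img, []).append((cls, tuple(box), conf))

    per_class = {}
    ap50s, ap5095s, precisions, recalls = [], [], [], []
    for ci in range(num_classes):
        n_gt = sum(sum(1 for g in gl if g[0] == ci) for gl in ground_truths.values())
        flags_at_iou, confs = _matched_flags_per_iou(dets_by_img, ground_truths, ci)
        aps = []
        for t_i in range(len(IOU_GRID)):
            aps.append(average_precision(pr_curve(flags_at_iou[t_i], confs, n_gt)))
        entry = {"n_gt": n_gt}
        if n_gt == 0:
            entry.update(precision=float("nan"), recall=float("nan"),
                         ap50=float("nan"), ap50_95=float("nan"))
        else:
            curve = pr_curve(flags_at_iou[0], confs, n_gt)
            f1, best_t, p_best, r_best = _f1_argmax(curve)
            entry.update(precision=p_best, recall=r_best,
                         ap50=aps[0], ap50_95=float(np.mean(aps)),
                         f1=f1, f1_confidence=best_t)
            ap50s.append(aps[0])
            ap5095s.append(float(np.mean(aps)))
            precisions.append(p_best)
            recalls.append(r_best)
        per_class[class_names[ci]] = entry

    if not ap50s:
        raise ValueError("no class has ground truth; mAP undefined")
    cm = confusion_matrix_normalized(
        [(img, c, b, s) for img, dl in dets_by_img.items() for (c, b, s) in dl],
        ground_truths, num_classes, conf_thresh_cm, iou_thresh_cm)
    return EvalSummary(
        class_names=class_names,
        per_class=per_class,
        mean_precision=float(np.mean(precisions)),
        mean_recall=float(np.mean(recalls)),
        map50=float(np.mean(ap50s)),
        map50_95=float(np.mean(ap5095s)),
        confusion=cm,
    )


def _matched_flags_per_iou(dets_by_img, gts_by_img, class_id):
    """Per-IoU-threshold TP flags for one class, globally confidence-sorted."""
    all_flags = [[] for _ in IOU_GRID]
    all_conf = []
    for img, gl in gts_by_img.items():
        dl = [d for d in dets_by_img.get(img, []) if d[0] == class_id]
        gl_c = [g for g in gl if g[0] == class_id]
        for t_i, t in enumerate(IOU_GRID):
            m = match_detections(dl, gl_c, t)
            all_flags[t_i].extend(zip(m.confidences, m.tp))
        all_conf.extend(d[2] for d in dl)
    order_flags = []
    for t_i in range(len(IOU_GRID)):
        pairs = all_flags[t_i]
        pairs.sort(key=lambda p: -p[0])
        order_flags.append(np.array([f for _, f in pairs], dtype=bool))
    return order_flags, np.array(sorted(all_conf, reverse=True))


def map_summary(per_class_ap50, per_class_ap5095=None):
    """Aggregate per-class APs: overall mAP is their arithmetic mean."""
    ap50 = np.asarray(per_class_ap50, dtype=float)
    ap50 = ap50[~np.isnan(ap50)]
    if ap50.size == 0:
        raise ValueError("no defined per-class AP values")
    out = {"mAP50": float(ap50.mean())}
    if per_class_ap5095 is not None:
        a = np.asarray(per_class_ap5095, dtype=float)
        a = a[~np.isnan(a)]
        out["mAP50_95"] = float(a.mean())
    return out


def _f1_argmax(curve: PRCurve, grid=None):
    if grid is None:
        grid = np.linspace(0, 1, 1000)
    p, r = _pr_at_confidence(curve, grid)
    denom = p + r
    f1 = np.where(denom > 0, 2 * p * r / np.maximum(denom, 1e-12), 0.0)
    i = int(np.argmax(f1))
    return float(f1[i]), float(grid[i]), float(p[i]), float(r[i])


def _pr_at_confidence(curve: PRCurve, grid):
    """Precision/recall of the detection set thresholded at each confidence."""
    # curve arrays are sorted by descending confidence; thresholding at t
    # keeps the first k detections where confidences[k-1] >= t
    grid = np.asarray(grid)
    conf = curve.confidences
    if conf.size == 0:  # no detections at all: vacuous precision, zero recall
        return np.ones_like(grid, dtype=float), np.zeros_like(grid, dtype=float)
    k = np.searchsorted(-conf, -grid, side="right")
    p = np.where(k > 0, curve.precision[np.maximum(k - 1, 0)], 1.0)
    r = np.where(k > 0, curve.recall[np.maximum(k - 1, 0)], 0.0)
    return p, r


def f1_vs_confidence(curves: dict, grid=None):
    """Per-class F1(confidence) arrays plus the best overall threshold.

    ``curves``: class name -> :class:`PRCurve`.  The overall F1 at each grid
    point is the mean of the per-class F1 values; returns (per-class F1
    arrays, grid, best threshold).
    """
    if grid is None:
        grid = np.linspace(0, 1, 1000)
    grid = np.asarray(grid, dtype=float)
    f1s = {}
    for name, curve in curves.items():
        p, r = _pr_at_confidence(curve, grid)
        denom = p + r
        f1s[name] = np.where(denom > 0, 2 * p * r / np.maximum(denom, 1e-12), 0.0)
    mean_f1 = np.mean(np.stack(list(f1s.values())), axis=0)
    return f1s, grid, float(grid[int(np.argmax(mean_f1))])


def confusion_matrix_normalized(detections, ground_truths, num_classes: int,
                                conf_thresh: float = 0.25,
                                iou_thresh: float = 0.45) -> np.ndarray:
    """(nc+1)×(nc+1) column-normalized confusion matrix with background.

    Rows are predictions, columns ground truth; the last index is
    background.  Matching here is class-agnostic (cross-class confusions
    are exactly what the matrix records), greedy by confidence.
    """
    if not (0 <= conf_thresh <= 1 and 0 <= iou_thresh <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    nc = num_classes
    counts = np.zeros((nc + 1, nc + 1), dtype=float)
    dets_by_img: dict[str, list] = {k: [] for k in ground_truths}
    for img, cls, box, conf in detections:
        if conf >= conf_thresh:
            dets_by_img.setdefault(img, []).append((cls, tuple(box), conf))
    for img, gl in ground_truths.items():
        dl = sorted(dets_by_img.get(img, []), key=lambda d: -d[2])
        matched_g = np.zeros(len(gl), dtype=bool)
        for cls, box, _ in dl:
            best_iou, best_g = iou_thresh, -1
            for gi, (gcls, gbox) in enumerate(gl):
                if matched_g[gi]:
                    continue
                v = iou_xyxy(box, gbox)
                if v > best_iou:
                    best_iou, best_g = v, gi
            if best_g >= 0:
                matched_g[best_g] = True
                counts[cls, gl[best_g][0]] += 1
            else:
                counts[cls, nc] += 1  # false positive vs background
        for gi, (gcls, _) in enumerate(gl):
            if not matched_g[gi]:
                counts[nc, gcls] += 1  # missed ground truth
    col_sums = counts.sum(axis=0)
    norm = counts.copy()
    nzero = col_sums > 0
    norm[:, nzero] /= col_sums[nzero]
    return norm
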