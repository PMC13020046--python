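"""Independent brute-force reference implementations used to validate the
metric pipeline (kept free of any code from the package's own matching/AP
path beyond the elementary IoU formula)."""

import numpy as np


def iou_ref(a, b):
    ax1, ay1, ax2, ay2 = a
    bx1, by1, bx2, by2 = b
    iw = min(ax2, bx2) - max(ax1, bx1)
    ih = min(ay2, by2) - max(ay1, by1)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    return inter / ((ax2 - ax1) * (ay2 - ay1) + (bx2 - bx1) * (by2 - by1) - inter)


def oracle_match(dets, gts, thresh):
    """Naive reference: greedy by confidence, one-to-one, class-strict."""
    order = sorted(range(len(dets)), key=lambda i: -dets[i][2])
    used = set()
    flags = []
    for i in order:
        cls, box, _ = dets[i]
        best, best_iou = None, thresh
        for g, (gcls, gbox) in enumerate(gts):
            if g in used or gcls != cls:
                continue
            v = iou_ref(box, gbox)
            if v > best_iou or (v == best_iou and v >= thresh and best is None):
                best, best_iou = g, v
        if best is not None:
            used.add(best)
            flags.append(True)
        else:
            flags.append(False)
    return flags


def oracle_ap(tp_flags, n_gt):
    """Exhaustive 101-point interpolation: max precision at recall >= g."""
    tp_flags = list(tp_flags)
    if n_gt == 0:
        return float("nan")
    pts = []
    tp = fp = 0
    for f in tp_flags:
        tp += bool(f)
        fp += not f
        pts.append((tp / n_gt, tp / (tp + fp)))
    total = 0.0
    for g in np.linspace(0, 1, 101):
        candidates = [p for r, p in pts if r >= g]
        total += max(candidates) if candidates else 0.0
    return total / 101


def random_scene(rng, max_boxes=10):
    n_det = rng.integers(0, max_boxes + 1)
    n_gt = rng.integers(0, max_boxes + 1)

    def rand_box():
        x1, y1 = rng.uniform(0, 80, 2)
        w, h = rng.uniform(2, 40, 2)
        return (x1, y1, x1 + w, y1 + h)

    dets = [(int(rng.integers(0, 3)), rand_box(), float(np.round(rng.random(), 3)))
            for _ in range(n_det)]
    gts = [(int(rng.integers(0, 3)), rand_box()) for _ in range(n_gt)]
    return dets, gts
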