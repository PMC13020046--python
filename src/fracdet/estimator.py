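"""Scikit-learn style estimator facade over the detection pipeline.

:class:`FractureDetector` wraps model assembly, training and inference in
the familiar ``fit`` / ``predict`` / ``score`` interface so it composes
with sklearn tooling (``get_params``/``set_params``, ``clone``).  ``X`` is
a list of grayscale (or RGB) image arrays; ``y`` is a list of per-image
label lists (:class:`~fracdet.data.BoxLabel`, normalized coordinates).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .arch import DEFAULT_REPLACEMENT_SET, ModelConfig, assemble_model
from .data import BoxLabel, preprocess
from .evaluation import evaluate
from .inference import predict_images
from .training import TrainConfig, train_loop


class FractureDetector(BaseEstimator):
    """Anchor-free single-stage fracture detector (ADown variant by default).

    Parameters
    ----------
    replacement_sites : tuple of str or None
        Downsample sites realized as ADown blocks; ``None`` gives the plain
        convolutional baseline.
    imgsz : int
        Square network input size (divisible by 32).
    epochs, batch_size, lr0, lrf, momentum, weight_decay, warmup_epochs
        Training schedule (SGD with cosine annealing).
    class_weighted : bool
        Scale the classification loss by inverse class frequencies.
    conf_thresh, iou_thresh : float
        Decoding thresholds used by :meth:`predict`.
    max_iters : int or None
        Optional hard cap on training iterations (small-scale runs).

    Attributes
    ----------
    model_ : DetectionModel
        The trained network.
    history_ : dict
        Per-iteration and per-epoch loss records from training.
    classes_ : ndarray
        Class indices seen during fit.
    """

    def __init__(self, replacement_sites=DEFAULT_REPLACEMENT_SET, num_classes=3,
                 imgsz=640, epochs=200, batch_size=16, lr0=0.01, lrf=0.01,
                 momentum=0.937, weight_decay=5e-4, warmup_epochs=3.0,
                 class_weighted=True, conf_thresh=0.25, iou_thresh=0.45,
                 max_iters=None, seed=0):
        self.replacement_sites = replacement_sites
        self.num_classes = num_classes
        self.imgsz = imgsz
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr0 = lr0
        self.lrf = lrf
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.warmup_epochs = warmup_epochs
        self.class_weighted = class_weighted
        self.conf_thresh = conf_thresh
        self.iou_thresh = iou_thresh
        self.max_iters = max_iters
        self.seed = seed

    def _model_config(self) -> ModelConfig:
        sites = self.replacement_sites or ()
        return ModelConfig(num_classes=self.num_classes, replacement_set=tuple(sites))

    def fit(self, X, y):
        X = list(X)
        y = list(y)
        if len(X) != len(y):
            raise ValueError(f"X and y length mismatch: {len(X)} vs {len(y)}")
        if len(X) == 0:
            raise ValueError("cannot fit on an empty dataset")
        dataset = []
        counts = np.zeros(self.num_classes, dtype=int)
        for img, labels in zip(X, y):
            chw, lb = preprocess(img, self.imgsz)
            cls = np.array([l.class_id for l in labels], dtype=int)
            boxes = np.array([lb.forward_box(*l.to_xyxy(*lb.orig_hw[::-1]))
                              for l in labels], dtype=float).reshape(-1, 4)
            counts += np.bincount(cls, minlength=self.num_classes)
            dataset.append((chw, (cls, boxes)))
        tc = TrainConfig(lr0=self.lr0, lrf=self.lrf, batch_size=self.batch_size,
                         epochs=self.epochs, weight_decay=self.weight_decay,
                         momentum=self.momentum, seed=self.seed,
                         warmup_epochs=self.warmup_epochs, imgsz=self.imgsz,
                         max_iters=self.max_iters)
        self.model_ = assemble_model(self._model_config(), seed=self.seed)
        self.history_ = train_loop(
            self.model_, dataset, tc,
            class_counts=counts if self.class_weighted and counts.all() else None)
        self.classes_ = np.arange(self.num_classes)
        return self

    def predict(self, X):
        """Per-image lists of :class:`~fracdet.evaluation.DetectionRecord`."""
        self._check_fitted()
        X = list(X)
        recs = predict_images(self.model_, X, image_ids=[str(i) for i in range(len(X))],
                              imgsz=self.imgsz, conf_thresh=self.conf_thresh,
                              iou_thresh=self.iou_thresh)
        out = [[] for _ in X]
        for r in recs:
            out[int(r.image_id)].append(r)
        return out

    def score(self, X, y):
        """mAP50 of the detector on (X, y)."""
        self._check_fitted()
        X = list(X)
        recs = predict_images(self.model_, X, image_ids=[str(i) for i in range(len(X))],
                              imgsz=self.imgsz, conf_thresh=0.001,
                              iou_thresh=self.iou_thresh)
        gts = {}
        for i, (img, labels) in enumerate(zip(X, y)):
            h, w = np.asarray(img).shape[:2]
            gts[str(i)] = [(l.class_id, l.to_xyxy(w, h)) for l in labels]
        summary = evaluate(recs, gts, self.num_classes)
        return summary.map50

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted; call fit first")
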