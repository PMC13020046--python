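"""Batched inference: preprocess, forward, decode, map boxes back to the
original image frame."""

from __future__ import annotations

import numpy as np

from .arch import DetectionModel, model_forward, postprocess
from .data import preprocess
from .evaluation import DetectionRecord


def predict_images(model: DetectionModel, images, image_ids=None, imgsz: int = 640,
                   conf_thresh: float = 0.25, iou_thresh: float = 0.45,
                   batch_size: int = 8) -> list[DetectionRecord]:
    """Run the detector over raw grayscale/RGB images.

    Returns detections with boxes in each image's original pixel frame.
    """
    images = list(images)
    if image_ids is None:
        image_ids = [str(i) for i in range(len(images))]
    records: list[DetectionRecord] = []
    for start in range(0, len(images), batch_size):
        chunk = images[start : start + batch_size]
        pre = [preprocess(img, imgsz) for img in chunk]
        batch = np.stack([p[0] for p in pre])
        raw = model_forward(model, batch)
        dets = postprocess(raw, conf_thresh, iou_thresh, model.config.reg_max,
                           image_hw=(imgsz, imgsz))
        for k, (img_dets, (_, lb)) in enumerate(zip(dets, pre)):
            h0, w0 = lb.orig_hw
            for cls_id, box, conf in img_dets:
                x1, y1, x2, y2 = lb.backward_box(*box)
                x1, x2 = np.clip([x1, x2], 0, w0)
                y1, y2 = np.clip([y1, y2], 0, h0)
                if x2 - x1 < 1e-3 or y2 - y1 < 1e-3:
                    continue
                records.append(DetectionRecord(
                    image_id=image_ids[start + k], class_id=int(cls_id),
                    box=(float(x1), float(y1), float(x2), float(y2)),
                    confidence=float(conf)))
    return records
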