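"""Dataset I/O, preprocessing, splitting, augmentation and label analytics.

Labels use the YOLO text dialect: one ``class cx cy w h`` line per box,
coordinates normalized to the unit square, center format.  Internal pixel
boxes are xyxy, 0-based, half-open.  The dataset layout on disk is
``images/{train,val}/*.png`` + ``labels/{train,val}/*.txt`` + ``data.yaml``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from matplotlib.colors import hsv_to_rgb, rgb_to_hsv
from PIL import Image

CLASS_NAMES = ("A1", "A2", "A3")


class FormatError(ValueError):
    """Malformed label file content."""


@dataclass(frozen=True)
class BoxLabel:
    """Normalized center-format box with its fracture-grade class."""

    class_id: int
    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self):
        if not 0 <= self.cx <= 1 or not 0 <= self.cy <= 1:
            raise FormatError(f"center ({self.cx}, {self.cy}) outside [0, 1]")
        if not 0 < self.w <= 1 or not 0 < self.h <= 1:
            raise FormatError(f"size ({self.w}, {self.h}) outside (0, 1]")

    def to_xyxy(self, width: float = 1.0, height: float = 1.0):
        return ((self.cx - self.w / 2) * width, (self.cy - self.h / 2) * height,
                (self.cx + self.w / 2) * width, (self.cy + self.h / 2) * height)

    @classmethod
    def from_xyxy(cls, class_id, x1, y1, x2, y2, width=1.0, height=1.0):
        return cls(class_id, (x1 + x2) / 2 / width, (y1 + y2) / 2 / height,
                   (x2 - x1) / width, (y2 - y1) / height)


@dataclass
class DatasetManifest:
    root: Path
    images: dict          # split -> list of image paths
    labels: dict          # split -> list of label paths
    class_names: tuple = CLASS_NAMES
    seed: int | None = None

    @property
    def class_counts(self) -> dict:
        counts = {s: np.zeros(len(self.class_names), dtype=int) for s in self.labels}
        for split, paths in self.labels.items():
            for p in paths:
                for lab in read_yolo_labels(p, num_classes=len(self.class_names)):
                    counts[split][lab.class_id] += 1
        return {s: c.tolist() for s, c in counts.items()}

    def to_yaml(self, path=None):
        d = {
            "path": str(self.root),
            "train": "images/train",
            "val": "images/val",
            "nc": len(self.class_names),
            "names": list(self.class_names),
        }
        text = yaml.safe_dump(d, sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text


@dataclass
class AugmentConfig:
    hsv_h: float = 0.015
    hsv_s: float = 0.7
    hsv_v: float = 0.4
    translate: float = 0.1
    scale: float = 0.5
    fliplr: float = 0.5
    mosaic: float = 1.0
    mixup: float = 0.0   # mentioned upstream but disabled by default

    def __post_init__(self):
        for name in ("fliplr", "mosaic", "mixup"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be a probability in [0, 1]")
        for name in ("hsv_h", "hsv_s", "hsv_v", "translate", "scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


# ------------------------------------------------------------- label I/O


def read_yolo_labels(path, num_classes: int = 3) -> list[BoxLabel]:
    labels = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 5:
                raise FormatError(f"{path}:{ln}: expected 5 fields, got {len(parts)}")
            try:
                cls = int(parts[0])
                vals = [float(v) for v in parts[1:]]
            except ValueError as e:
                raise FormatError(f"{path}:{ln}: {e}") from None
            if not 0 <= cls < num_classes:
                raise FormatError(f"{path}:{ln}: class {cls} outside [0, {num_classes})")
            try:
                labels.append(BoxLabel(cls, *vals))
            except FormatError as e:
                raise FormatError(f"{path}:{ln}: {e}") from None
    return labels


def write_yolo_labels(labels, path):
    with open(path, "w") as fh:
        for lab in labels:
            fh.write(f"{lab.class_id} {lab.cx:.6f} {lab.cy:.6f} {lab.w:.6f} {lab.h:.6f}\n")


def convert_labelme(json_path, num_classes: int = 3,
                    class_names=CLASS_NAMES) -> list[BoxLabel]:
    """Convert a Labelme annotation JSON (rectangle shapes) to YOLO labels."""
    with open(json_path) as fh:
        d = json.load(fh)
    w, h = d["imageWidth"], d["imageHeight"]
    name_to_id = {n: i for i, n in enumerate(class_names)}
    labels = []
    for shape in d.get("shapes", []):
        if shape.get("shape_type") not in (None, "rectangle", "polygon"):
            continue
        pts = np.asarray(shape["points"], dtype=float)
        x1, y1 = pts.min(axis=0)
        x2, y2 = pts.max(axis=0)
        cls = name_to_id.get(shape["label"])
        if cls is None:
            raise FormatError(f"{json_path}: unknown label {shape['label']!r}")
        labels.append(BoxLabel.from_xyxy(cls, x1, y1, x2, y2, width=w, height=h))
    return labels


# ---------------------------------------------------------- preprocessing


@dataclass(frozen=True)
class LetterboxParams:
    scale: float
    pad_x: float
    pad_y: float
    orig_hw: tuple[int, int]

    def forward_box(self, x1, y1, x2, y2):
        s = self.scale
        return (x1 * s + self.pad_x, y1 * s + self.pad_y,
                x2 * s + self.pad_x, y2 * s + self.pad_y)

    def backward_box(self, x1, y1, x2, y2):
        s = self.scale
        return ((x1 - self.pad_x) / s, (y1 - self.pad_y) / s,
                (x2 - self.pad_x) / s, (y2 - self.pad_y) / s)


LUMA = np.array([0.299, 0.587, 0.114])


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Luminance grayscale, replicated to 3 channels (HWC uint8 or float)."""
    img = np.asarray(image)
    if img.ndim == 2:
        gray = img.astype(np.float32)
    elif img.ndim == 3 and img.shape[2] == 3:
        gray = img.astype(np.float32) @ LUMA.astype(np.float32)
    elif img.ndim == 3 and img.shape[2] == 1:
        gray = img[:, :, 0].astype(np.float32)
    else:
        raise ValueError(f"unsupported image shape {img.shape}")
    return np.repeat(gray[:, :, None], 3, axis=2)


def letterbox(image: np.ndarray, imgsz: int = 640, pad_value: float = 114.0):
    """Aspect-preserving resize + symmetric gray padding to imgsz×imgsz."""
    img = np.asarray(image, dtype=np.float32)
    h, w = img.shape[:2]
    if h == 0 or w == 0:
        raise ValueError("empty image")
    s = min(imgsz / h, imgsz / w)
    nh, nw = round(h * s), round(w * s)
    if (nh, nw) != (h, w):
        # PIL bilinear resize channel-wise
        chans = [np.asarray(Image.fromarray(img[:, :, c]).resize((nw, nh), Image.BILINEAR))
                 for c in range(img.shape[2])]
        img = np.stack(chans, axis=2)
    top = (imgsz - nh) // 2
    left = (imgsz - nw) // 2
    out = np.full((imgsz, imgsz, img.shape[2]), pad_value, dtype=np.float32)
    out[top : top + nh, left : left + nw] = img
    return out, LetterboxParams(scale=s, pad_x=left, pad_y=top, orig_hw=(h, w))


def preprocess(image: np.ndarray, imgsz: int = 640):
    """Grayscale → replicate 3ch → letterbox → scale to [0, 1], CHW.

    Returns (chw float32 array, :class:`LetterboxParams`).
    """
    gray = to_grayscale(image)
    boxed, params = letterbox(gray, imgsz)
    return boxed.transpose(2, 0, 1) / 255.0, params


def load_image(path) -> np.ndarray:
    with Image.open(path) as im:
        return np.asarray(im.convert("L"))


# -------------------------------------------------------------- splitting


def split_dataset(ids, train_fraction: float = 0.8, seed: int = 0,
                  stratify_classes=None):
    """Seeded shuffle split; train size is ⌊fraction·n⌋.

    With ``stratify_classes`` (a per-id class array) the floor split is
    applied within each class.
    """
    ids = list(ids)
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 ids to split")
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    if stratify_classes is None:
        perm = rng.permutation(n)
        k = int(np.floor(train_fraction * n))
        train = [ids[i] for i in perm[:k]]
        test = [ids[i] for i in perm[k:]]
        return train, test
    classes = np.asarray(stratify_classes)
    train, test = [], []
    for c in np.unique(classes):
        idx = np.flatnonzero(classes == c)
        perm = rng.permutation(len(idx))
        k = int(np.floor(train_fraction * len(idx)))
        train.extend(ids[idx[i]] for i in perm[:k])
        test.extend(ids[idx[i]] for i in perm[k:])
    return train, test


# ------------------------------------------------------------ augmentation


def hflip(image: np.ndarray, labels):
    """Mirror the image; each label's cx becomes 1−cx."""
    flipped = np.ascontiguousarray(np.asarray(image)[:, ::-1])
    new = [BoxLabel(l.class_id, 1.0 - l.cx, l.cy, l.w, l.h) for l in labels]
    return flipped, new


def hsv_jitter(image: np.ndarray, config: AugmentConfig, rng: np.random.Generator):
    """Random hue/saturation/value gains (YOLO-style).

    On replicated-grayscale input, hue and saturation are no-ops by
    construction; only the value (brightness) gain has an effect.
    """
    img = np.asarray(image, dtype=np.float32)
    if img.ndim == 2:
        img = np.repeat(img[:, :, None], 3, axis=2)
    gains = rng.uniform(-1, 1, 3) * [config.hsv_h, config.hsv_s, config.hsv_v] + 1
    hsv = rgb_to_hsv(np.clip(img, 0, 255) / 255.0)
    hsv[..., 0] = (hsv[..., 0] * gains[0]) % 1.0
    hsv[..., 1] = np.clip(hsv[..., 1] * gains[1], 0, 1)
    hsv[..., 2] = np.clip(hsv[..., 2] * gains[2], 0, 1)
    return hsv_to_rgb(hsv) * 255.0


def _affine_boxes(labels, canvas: int, shift_x: float, shift_y: float, scale: float,
                  min_px: float = 2.0):
    out = []
    for cls, x1, y1, x2, y2 in labels:
        cx, cy = canvas / 2, canvas / 2
        nx1 = (x1 - cx) * scale + cx + shift_x
        nx2 = (x2 - cx) * scale + cx + shift_x
        ny1 = (y1 - cy) * scale + cy + shift_y
        ny2 = (y2 - cy) * scale + cy + shift_y
        nx1, nx2 = np.clip([nx1, nx2], 0, canvas)
        ny1, ny2 = np.clip([ny1, ny2], 0, canvas)
        if nx2 - nx1 >= min_px and ny2 - ny1 >= min_px:
            out.append((cls, nx1, ny1, nx2, ny2))
    return out


def mosaic_and_affine(images, labels_per_image, config: AugmentConfig,
                      rng: np.random.Generator, imgsz: int = 640):
    """Four-image mosaic with jittered center, then random scale/translate.

    Input images must already be square (letterboxed) of side ``imgsz``;
    labels are normalized :class:`BoxLabel`.  Returns (image, labels) with
    the composite at side ``imgsz`` (canvas downscaled ×2), boxes clipped
    and degenerate (<2 px) boxes dropped.
    """
    if len(images) != 4 or len(labels_per_image) != 4:
        raise ValueError("mosaic needs exactly 4 source items")
    canvas_sz = 2 * imgsz
    canvas = np.full((canvas_sz, canvas_sz, 3), 114.0, dtype=np.float32)
    cx = int(rng.uniform(0.5 * imgsz, 1.5 * imgsz))
    cy = int(rng.uniform(0.5 * imgsz, 1.5 * imgsz))
    pix_labels = []
    corners = [(0, 0, cx, cy), (cx, 0, canvas_sz, cy), (0, cy, cx, canvas_sz), (cx, cy, canvas_sz, canvas_sz)]
    for (img, labs, (x1c, y1c, x2c, y2c)) in zip(images, labels_per_image, corners):
        img = np.asarray(img, dtype=np.float32)
        if img.ndim == 2:
            img = np.repeat(img[:, :, None], 3, axis=2)
        h, w = img.shape[:2]
        cw = min(x2c - x1c, w)
        chh = min(y2c - y1c, h)
        # paste anchored at the mosaic center: left/top quadrants keep their
        # right/bottom edge, right/bottom quadrants their left/top edge
        px1 = x2c - cw if x1c == 0 else x1c
        py1 = y2c - chh if y1c == 0 else y1c
        sx1 = w - cw if x1c == 0 else 0
        sy1 = h - chh if y1c == 0 else 0
        canvas[py1 : py1 + chh, px1 : px1 + cw] = img[sy1 : sy1 + chh, sx1 : sx1 + cw]
        for l in labs:
            bx1, by1, bx2, by2 = l.to_xyxy(w, h)
            nx1, ny1 = bx1 - sx1 + px1, by1 - sy1 + py1
            nx2, ny2 = bx2 - sx1 + px1, by2 - sy1 + py1
            nx1, nx2 = np.clip([nx1, nx2], px1, px1 + cw)
            ny1, ny2 = np.clip([ny1, ny2], py1, py1 + chh)
            if nx2 - nx1 >= 2 and ny2 - ny1 >= 2:
                pix_labels.append((l.class_id, nx1, ny1, nx2, ny2))
    scale = rng.uniform(1 - config.scale, 1 + config.scale)
    shift_x = rng.uniform(-config.translate, config.translate) * canvas_sz
    shift_y = rng.uniform(-config.translate, config.translate) * canvas_sz
    pix_labels = _affine_boxes(pix_labels, canvas_sz, shift_x, shift_y, scale)
    canvas = _affine_image(canvas, shift_x, shift_y, scale)
    canvas = hsv_jitter(canvas, config, rng)
    # downscale canvas 2x back to imgsz
    small = np.stack(
        [np.asarray(Image.fromarray(canvas[:, :, c]).resize((imgsz, imgsz), Image.BILINEAR))
         for c in range(3)], axis=2)
    out_labels = []
    for cls, x1, y1, x2, y2 in pix_labels:
        try:
            out_labels.append(BoxLabel.from_xyxy(cls, x1, y1, x2, y2, canvas_sz, canvas_sz))
        except FormatError:
            continue
    return small, out_labels


def _affine_image(img: np.ndarray, shift_x: float, shift_y: float, scale: float):
    """Center scale + translate via PIL affine (nearest output size)."""
    h, w = img.shape[:2]
    # inverse map coefficients for PIL.Image.transform
    a = 1.0 / scale
    cx, cy = w / 2, h / 2
    c0 = cx - a * (cx + shift_x)
    d0 = cy - a * (cy + shift_y)
    chans = [
        np.asarray(Image.fromarray(img[:, :, c]).transform(
            (w, h), Image.AFFINE, (a, 0, c0, 0, a, d0),
            resample=Image.BILINEAR, fillcolor=114.0))
        for c in range(img.shape[2])
    ]
    return np.stack(chans, axis=2)


# --------------------------------------------------------------- analytics


def label_stats(labels, num_classes: int = 3, bins: int = 20) -> dict:
    """Per-class counts, center/size histograms, aspect ratios, correlations."""
    labels = list(labels)
    if not labels:
        raise ValueError("no labels to analyze")
    arr = np.array([[l.cx, l.cy, l.w, l.h] for l in labels])
    cls = np.array([l.class_id for l in labels])
    counts = np.bincount(cls, minlength=num_classes)
    aspect = arr[:, 3] / arr[:, 2]
    degenerate = bool(np.allclose(arr.std(axis=0), 0))
    if degenerate:
        corr = np.zeros((4, 4))
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(arr.T)
        corr = np.nan_to_num(corr, nan=0.0)
    return {
        "per_class_counts": counts.tolist(),
        "center_hist": np.histogram2d(arr[:, 0], arr[:, 1], bins=bins, range=[[0, 1], [0, 1]])[0].tolist(),
        "size_hist": np.histogram2d(arr[:, 2], arr[:, 3], bins=bins, range=[[0, 1], [0, 1]])[0].tolist(),
        "aspect_hist": np.histogram(aspect, bins=bins)[0].tolist(),
        "aspect_bin_edges": np.histogram(aspect, bins=bins)[1].tolist(),
        "correlations": corr.tolist(),
        "correlations_degenerate": degenerate,
        "n_labels": len(labels),
    }


# ---------------------------------------------------------- dataset on disk


def load_manifest(root) -> DatasetManifest:
    root = Path(root)
    with open(root / "data.yaml") as fh:
        d = yaml.safe_load(fh)
    images, labels = {}, {}
    for split in ("train", "val"):
        img_dir = root / d.get(split, f"images/{split}")
        imgs = sorted(img_dir.glob("*.png")) + sorted(img_dir.glob("*.jpg"))
        images[split] = imgs
        labels[split] = [root / "labels" / split / (p.stem + ".txt") for p in imgs]
    return DatasetManifest(root=root, images=images, labels=labels,
                           class_names=tuple(d.get("names", CLASS_NAMES)))
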