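"""Seeded synthetic femur-radiograph generator with graded fracture patterns.

Emulates the statistical structure of a proximal-femur fracture X-ray
dataset — one small fracture target per grayscale image, three separable
AO/OTA-like classes with imbalanced counts — without attempting
radiological realism.  A phantom is a bright femur silhouette (shaft band,
neck, femoral-head disk, trochanteric bulge) on a darker background;
the fracture is carved as dark intensity discontinuities whose geometry
depends on the grade:

* A1-like: a single oblique line through the trochanteric region;
* A2-like: two or three intersecting lines with an offset intermediate
  fragment;
* A3-like: a single transverse / reverse-oblique line below the trochanter.

Labels are tight boxes around the carved region with a 5% margin.  Class
counts in generated datasets follow deterministic largest-remainder
apportionment of the configured mix, so the default mix over 976 images
yields exactly 261/579/136.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

from .data import (BoxLabel, CLASS_NAMES, DatasetManifest, split_dataset,
                   write_yolo_labels)

#: class mix of the emulated study population (A1, A2, A3)
DEFAULT_MIX = (261 / 976, 579 / 976, 136 / 976)


@dataclass
class PhantomConfig:
    image_size: int = 640
    class_mix: tuple[float, float, float] = DEFAULT_MIX
    bone_intensity: tuple[float, float] = (150.0, 200.0)
    background_intensity: float = 40.0
    blur_sigma: float = 1.5
    noise_sigma: float = 4.0
    poisson_noise: bool = False
    fracture_depth: float = 0.55         # fractional intensity drop on the line
    line_width_range: tuple[float, float] = (2.0, 5.0)   # pixels at size 640
    extent_range: tuple[float, float] = (0.10, 0.30)     # box side / image side
    seed: int = 0

    def __post_init__(self):
        if self.image_size % 32:
            raise ValueError("image_size must be divisible by 32")
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise ValueError("class_mix must sum to 1")
        if self.blur_sigma < 0 or self.noise_sigma < 0:
            raise ValueError("sigmas must be >= 0")


@dataclass
class FracturePattern:
    kind: str                      # "A1" | "A2" | "A3"
    lines: list = field(default_factory=list)   # ((x1,y1),(x2,y2), width)
    fragment_shift: float = 0.0

    @property
    def line_count(self) -> int:
        return len(self.lines)


def _capsule_mask(xx, yy, p0, p1, radius):
    """Boolean mask of points within ``radius`` of segment p0–p1."""
    px, py = p1[0] - p0[0], p1[1] - p0[1]
    norm = px * px + py * py
    t = np.clip(((xx - p0[0]) * px + (yy - p0[1]) * py) / max(norm, 1e-9), 0, 1)
    dx = xx - (p0[0] + t * px)
    dy = yy - (p0[1] + t * py)
    return dx * dx + dy * dy <= radius * radius


def _sample_pattern(kind: str, center, extent, config: PhantomConfig,
                    rng: np.random.Generator) -> FracturePattern:
    s = config.image_size
    wlo, whi = config.line_width_range
    width = rng.uniform(wlo, whi) * s / 640.0
    cx, cy = center

    def endpoints(theta, length, offset=(0.0, 0.0)):
        dx = math.cos(theta) * length / 2
        dy = math.sin(theta) * length / 2
        ox, oy = offset
        return ((cx + ox - dx, cy + oy - dy), (cx + ox + dx, cy + oy + dy))

    lines = []
    if kind == "A1":
        theta = math.radians(rng.uniform(35, 65))
        lines.append((*endpoints(theta, extent * rng.uniform(0.8, 1.0)), width))
        shift = 0.0
    elif kind == "A2":
        theta = math.radians(rng.uniform(35, 65))
        lines.append((*endpoints(theta, extent * rng.uniform(0.8, 1.0)), width))
        n_extra = rng.integers(1, 3)  # 1 or 2 secondary lines
        shift = rng.uniform(0.15, 0.35) * extent
        for i in range(n_extra):
            theta2 = theta - math.radians(rng.uniform(40, 80))
            off = (rng.uniform(-shift, shift), rng.uniform(-shift, shift))
            lines.append((*endpoints(theta2, extent * rng.uniform(0.5, 0.8), off), width))
    elif kind == "A3":
        # transverse or reverse-oblique (slope opposite the A1 band)
        if rng.random() < 0.5:
            theta = math.radians(rng.uniform(-12, 12))
        else:
            theta = math.radians(rng.uniform(-40, -20))
        lines.append((*endpoints(theta, extent * rng.uniform(0.8, 1.0)), width))
        shift = 0.0
    else:
        raise ValueError(f"unknown pattern kind {kind!r}")
    return FracturePattern(kind=kind, lines=lines, fragment_shift=shift)


def render_phantom(config: PhantomConfig, class_id: int, rng: np.random.Generator):
    """Render one phantom; returns (uint8 image, BoxLabel, FracturePattern)."""
    if class_id not in (0, 1, 2):
        raise ValueError(f"class_id must be 0, 1 or 2, got {class_id}")
    s = config.image_size
    ys, xs = np.mgrid[0:s, 0:s].astype(np.float32)
    bone = rng.uniform(*config.bone_intensity)
    img = np.full((s, s), config.background_intensity, dtype=np.float32)
    img += rng.normal(0, 2.0) + (ys / s) * rng.uniform(-10, 10)  # mild field drift

    jx = rng.uniform(-0.03, 0.03) * s
    jy = rng.uniform(-0.03, 0.03) * s
    shaft_top = (0.50 * s + jx, 0.32 * s + jy)
    shaft_bot = (0.55 * s + jx, 0.97 * s + jy)
    head_c = (0.32 * s + jx, 0.20 * s + jy)
    head_r = rng.uniform(0.075, 0.095) * s
    troch_c = (0.52 * s + jx, 0.30 * s + jy)

    img[_capsule_mask(xs, ys, shaft_top, shaft_bot, 0.075 * s)] = bone
    # broad proximal mass so fracture lines stay on bone
    img[_capsule_mask(xs, ys, head_c, (0.55 * s + jx, 0.45 * s + jy), 0.115 * s)] = bone * 0.98
    img[_capsule_mask(xs, ys, head_c, troch_c, 0.055 * s)] = bone * 0.96  # neck
    img[(xs - head_c[0]) ** 2 + (ys - head_c[1]) ** 2 <= head_r**2] = bone * 1.05
    img[_capsule_mask(xs, ys, (troch_c[0], troch_c[1] - 0.03 * s),
                      (troch_c[0] + 0.02 * s, troch_c[1] + 0.06 * s), 0.055 * s)] = bone * 1.02

    kind = CLASS_NAMES[class_id]
    extent = rng.uniform(*config.extent_range) * s
    if kind == "A3":
        center = (troch_c[0] + rng.uniform(-0.02, 0.02) * s,
                  troch_c[1] + rng.uniform(0.06, 0.10) * s)
    else:
        center = (troch_c[0] + rng.uniform(-0.02, 0.02) * s,
                  troch_c[1] + rng.uniform(-0.02, 0.02) * s)
    pattern = _sample_pattern(kind, center, extent, config, rng)

    carved = np.zeros((s, s), dtype=bool)
    for p0, p1, width in pattern.lines:
        m = _capsule_mask(xs, ys, p0, p1, width)
        carved |= m
    img[carved] *= 1.0 - config.fracture_depth

    if config.blur_sigma > 0:
        img = gaussian_filter(img, config.blur_sigma)
    if config.poisson_noise:
        img = rng.poisson(np.clip(img, 0, None)).astype(np.float32)
    if config.noise_sigma > 0:
        img = img + rng.normal(0, config.noise_sigma, img.shape)
    img = np.clip(img, 0, 255).astype(np.uint8)

    ys_c, xs_c = np.nonzero(carved)
    x1, x2 = xs_c.min(), xs_c.max() + 1
    y1, y2 = ys_c.min(), ys_c.max() + 1
    mx, my = 0.05 * (x2 - x1), 0.05 * (y2 - y1)
    x1, y1 = max(x1 - mx, 0.0), max(y1 - my, 0.0)
    x2, y2 = min(x2 + mx, s), min(y2 + my, s)
    label = BoxLabel.from_xyxy(class_id, x1, y1, x2, y2, width=s, height=s)
    return img, label, pattern


def generate_example(config: PhantomConfig, class_id: int, rng: np.random.Generator):
    """One (image, label) pair; deterministic given config, class and rng state."""
    img, label, _ = render_phantom(config, class_id, rng)
    return img, label


def apportion_counts(n: int, mix, tie_order=None) -> list[int]:
    """Largest-remainder apportionment; ties go to the earlier class."""
    mix = np.asarray(mix, dtype=float)
    quotas = n * mix
    counts = np.floor(quotas).astype(int)
    rem = quotas - counts
    order = sorted(range(len(mix)), key=lambda i: (-rem[i], i))
    for i in range(n - counts.sum()):
        counts[order[i % len(mix)]] += 1
    return counts.tolist()


def generate_dataset(n: int, config: PhantomConfig, out_dir,
                     train_fraction: float = 0.8) -> DatasetManifest:
    """Write a YOLO-layout dataset of ``n`` phantoms and its data.yaml.

    Class counts follow deterministic apportionment of ``config.class_mix``;
    the train/val partition is a seeded shuffle split at ``train_fraction``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    out = Path(out_dir)
    rng = np.random.default_rng(config.seed)
    counts = apportion_counts(n, config.class_mix)
    class_seq = np.repeat(np.arange(len(counts)), counts)
    rng.shuffle(class_seq)
    ids = [f"phantom_{i:05d}" for i in range(n)]
    if n >= 2:
        train_ids, val_ids = split_dataset(ids, train_fraction, seed=config.seed)
    else:
        train_ids, val_ids = ids, []
    split_of = {i: "train" for i in train_ids}
    split_of.update({i: "val" for i in val_ids})
    for sub in ("images/train", "images/val", "labels/train", "labels/val"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    images = {"train": [], "val": []}
    labels = {"train": [], "val": []}
    for i, (img_id, cls) in enumerate(zip(ids, class_seq)):
        img, label, _ = render_phantom(config, int(cls), rng)
        split = split_of[img_id]
        ipath = out / "images" / split / f"{img_id}.png"
        lpath = out / "labels" / split / f"{img_id}.txt"
        Image.fromarray(img).save(ipath)
        write_yolo_labels([label], lpath)
        images[split].append(ipath)
        labels[split].append(lpath)
    manifest = DatasetManifest(root=out, images=images, labels=labels,
                               class_names=CLASS_NAMES, seed=config.seed)
    manifest.to_yaml(out / "data.yaml")
    return manifest


def fracture_contrast(image: np.ndarray, label: BoxLabel) -> float:
    """Intensity gap between surrounding bone and the carved fracture line.

    Compares the mean of bone-like pixels (upper half of the intensity
    distribution) in a ring around the label box against the mean of the
    darkest 30% of pixels inside the box — the carved discontinuity.
    """
    img = np.asarray(image, dtype=float)
    h, w = img.shape[:2]
    x1, y1, x2, y2 = label.to_xyxy(w, h)
    x1i, y1i, x2i, y2i = int(x1), int(y1), int(math.ceil(x2)), int(math.ceil(y2))
    inner = img[y1i:y2i, x1i:x2i]
    gx = max(2, (x2i - x1i) // 2)
    gy = max(2, (y2i - y1i) // 2)
    ox1, oy1 = max(x1i - gx, 0), max(y1i - gy, 0)
    ox2, oy2 = min(x2i + gx, w), min(y2i + gy, h)
    ring = img[oy1:oy2, ox1:ox2].copy()
    ring[y1i - oy1 : y2i - oy1, x1i - ox1 : x2i - ox1] = np.nan
    ring_vals = ring[~np.isnan(ring)]
    bone = np.concatenate([ring_vals, inner.ravel()])
    bone = bone[bone >= np.percentile(bone, 60)].mean()
    carved = inner[inner <= np.percentile(inner, 25)].mean()
    return float(bone - carved)
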