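"""Detector architecture: YOLOv8n graph with optional ADown downsampling.

The network is the standard one-stage anchor-free design: a CSP-style
backbone (stem + four stages of downsample→C2f, then SPPF), an FPN
top-down / PAN bottom-up neck, and a decoupled head predicting, per grid
cell at strides 8/16/32, a discrete distribution over ``reg_max`` integer
bins for each of the four box-edge distances plus one logit per class.

The variant of interest replaces stride-2 3×3 downsampling convolutions at
selected sites with ADown blocks: a 2×2 stride-1 average pool, an even
channel split, then two half-width branches — a 3×3 stride-2 max pool
followed by a 1×1 convolution, and a 3×3 stride-2 convolution — whose
outputs are concatenated.  ADown needs ~2.5·c·c′ weights against the plain
convolution's 9·c·c′, which is where the parameter/FLOP savings come from.

Replaceable sites are named ``P2 P3 P4 P5`` (backbone downsamplers after
the stem) and ``N4 N5`` (the two PAN downsamplers).  The stem is never
replaceable: its input channel count (3) cannot be split evenly.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, asdict

import numpy as np
import yaml

from . import nn
from .nn import Tensor

VALID_SITES = ("P2", "P3", "P4", "P5", "N4", "N5")

#: downsampling sites replaced by ADown in the shipped variant, calibrated
#: against the printed parameter/FLOP budget of the reference model pair
#: (see accounting.calibrate_replacement_set)
DEFAULT_REPLACEMENT_SET = ("P2", "P3", "P4", "P5", "N5")


class ConfigurationError(ValueError):
    """Invalid architecture or run configuration."""


class ShapeError(ValueError):
    """Input tensor shape incompatible with the network."""


@dataclass(frozen=True)
class ConvBlockSpec:
    """Conv→BN→SiLU block description (closed-form params: k²·c1·c2 + 2·c2)."""

    in_channels: int
    out_channels: int
    kernel: int = 3
    stride: int = 1

    def __post_init__(self):
        if self.kernel not in (1, 3):
            raise ConfigurationError(f"kernel must be 1 or 3, got {self.kernel}")
        if self.in_channels <= 0 or self.out_channels <= 0:
            raise ConfigurationError("channel counts must be positive")

    @property
    def padding(self) -> int:
        return self.kernel // 2

    @property
    def param_count(self) -> int:
        return self.kernel**2 * self.in_channels * self.out_channels + 2 * self.out_channels


@dataclass(frozen=True)
class ADownSpec:
    """ADown block description.

    Closed-form parameter count (both convs carry BN scale+shift):
    ``9·(c1/2)·(c2/2) + (c1/2)·(c2/2) + 4·(c2/2)`` = 2.5·c1·c2 + 2·c2.
    """

    in_channels: int
    out_channels: int

    def __post_init__(self):
        if self.in_channels <= 0 or self.out_channels <= 0:
            raise ConfigurationError("channel counts must be positive")
        if self.in_channels % 2 or self.out_channels % 2:
            raise ConfigurationError(
                f"ADown needs even channel counts, got {self.in_channels}->{self.out_channels}"
            )

    @property
    def param_count(self) -> int:
        ci, co = self.in_channels // 2, self.out_channels // 2
        return (9 * ci * co + 2 * co) + (ci * co + 2 * co)


@dataclass
class ModelConfig:
    num_classes: int = 3
    width_multiple: float = 0.25
    depth_multiple: float = 0.33
    max_channels: int = 1024
    reg_max: int = 16
    input_channels: int = 3
    replacement_set: tuple[str, ...] = ()

    def __post_init__(self):
        if self.num_classes < 1:
            raise ConfigurationError("num_classes must be >= 1")
        self.replacement_set = tuple(self.replacement_set)
        for site in self.replacement_set:
            if site == "stem":
                raise ConfigurationError("the stem downsampler is never replaced by ADown")
            if site not in VALID_SITES:
                raise ConfigurationError(f"unknown downsample site {site!r}; valid: {VALID_SITES}")

    def channels(self, c: int) -> int:
        """Scale a nominal channel count by the width multiple (ceil to /8)."""
        c = min(c, self.max_channels)
        return int(math.ceil(c * self.width_multiple / 8) * 8)

    def depth(self, n: int) -> int:
        return max(round(n * self.depth_multiple), 1)

    def to_yaml(self, path=None) -> str:
        d = asdict(self)
        d["replacement_set"] = list(self.replacement_set)
        text = yaml.safe_dump(d, sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "ModelConfig":
        if hasattr(source, "read"):
            d = yaml.safe_load(source)
        else:
            text = str(source)
            if "\n" in text or ":" in text:
                d = yaml.safe_load(io.StringIO(text))
            else:
                with open(text) as fh:
                    d = yaml.safe_load(fh)
        return cls(**d)


@dataclass
class RawPrediction:
    """Per-level head outputs: box-distribution logits and class logits."""

    box_logits: list  # per level: (N, 4*reg_max, H, W)
    cls_logits: list  # per level: (N, num_classes, H, W)
    strides: tuple[int, ...] = (8, 16, 32)


# --------------------------------------------------------------- blocks


class ADown(nn.Module):
    """Average-pooling downsampling block.

    Dataflow: 2×2 stride-1 average pool → even channel split → first half
    through 3×3 stride-2 max pool + 1×1 conv, second half through 3×3
    stride-2 conv → concatenation.  (The branch-to-half assignment follows
    the published description; swapping halves is parameter-identical.)
    """

    def __init__(self, in_channels: int, out_channels: int, rng=None):
        super().__init__()
        self.spec = ADownSpec(in_channels, out_channels)
        half_in, half_out = in_channels // 2, out_channels // 2
        self.cv_pool = nn.ConvBlock(half_in, half_out, kernel=1, stride=1, rng=rng)
        self.cv_conv = nn.ConvBlock(half_in, half_out, kernel=3, stride=2, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        if c != self.spec.in_channels:
            raise ConfigurationError(f"expected {self.spec.in_channels} channels, got {c}")
        if h < 4 or w < 4 or h % 2 or w % 2:
            raise ShapeError(f"ADown needs even spatial dims >= 4, got {h}x{w}")
        x = x.avg_pool2d(2, 1)
        half = c // 2
        x1 = x[:, :half]
        x2 = x[:, half:]
        y1 = self.cv_pool(x1.max_pool2d(3, 2, 1))
        y2 = self.cv_conv(x2)
        return nn.concat([y1, y2], axis=1)


class Bottleneck(nn.Module):
    def __init__(self, channels: int, shortcut: bool = True, rng=None):
        super().__init__()
        self.cv1 = nn.ConvBlock(channels, channels, 3, rng=rng)
        self.cv2 = nn.ConvBlock(channels, channels, 3, rng=rng)
        self.shortcut = shortcut

    def forward(self, x: Tensor) -> Tensor:
        y = self.cv2(self.cv1(x))
        return x + y if self.shortcut else y


class C2f(nn.Module):
    """Cross-stage-partial block: split, chain bottlenecks, fuse."""

    def __init__(self, in_channels: int, out_channels: int, n: int = 1,
                 shortcut: bool = False, rng=None):
        super().__init__()
        self.hidden = out_channels // 2
        self.n = n
        self.cv1 = nn.ConvBlock(in_channels, 2 * self.hidden, 1, rng=rng)
        for i in range(n):
            setattr(self, f"m{i}", Bottleneck(self.hidden, shortcut, rng=rng))
        self.cv2 = nn.ConvBlock((2 + n) * self.hidden, out_channels, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        y = self.cv1(x)
        parts = [y[:, : self.hidden], y[:, self.hidden :]]
        for i in range(self.n):
            parts.append(getattr(self, f"m{i}")(parts[-1]))
        return self.cv2(nn.concat(parts, axis=1))


class SPPF(nn.Module):
    """Spatial pyramid pooling (fast): three chained 5×5 stride-1 max pools."""

    def __init__(self, in_channels: int, out_channels: int, rng=None):
        super().__init__()
        hidden = in_channels // 2
        self.cv1 = nn.ConvBlock(in_channels, hidden, 1, rng=rng)
        self.cv2 = nn.ConvBlock(4 * hidden, out_channels, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        y = self.cv1(x)
        p1 = y.max_pool2d(5, 1, 2)
        p2 = p1.max_pool2d(5, 1, 2)
        p3 = p2.max_pool2d(5, 1, 2)
        return self.cv2(nn.concat([y, p1, p2, p3], axis=1))


class DetectHead(nn.Module):
    """Decoupled anchor-free head: box-distribution and class branches."""

    def __init__(self, num_classes: int, reg_max: int, level_channels, rng=None):
        super().__init__()
        self.num_classes = num_classes
        self.reg_max = reg_max
        self.strides = (8, 16, 32)
        c2 = max(16, level_channels[0] // 4, 4 * reg_max)
        c3 = max(level_channels[0], min(num_classes, 100))
        for i, ch in enumerate(level_channels):
            setattr(self, f"box{i}a", nn.ConvBlock(ch, c2, 3, rng=rng))
            setattr(self, f"box{i}b", nn.ConvBlock(c2, c2, 3, rng=rng))
            setattr(self, f"box{i}c", nn.Conv2d(c2, 4 * reg_max, 1, bias=True, rng=rng))
            setattr(self, f"cls{i}a", nn.ConvBlock(ch, c3, 3, rng=rng))
            setattr(self, f"cls{i}b", nn.ConvBlock(c3, c3, 3, rng=rng))
            setattr(self, f"cls{i}c", nn.Conv2d(c3, num_classes, 1, bias=True, rng=rng))
        # prior-aware bias init: box bias 1, class bias at a low objectness
        # prior so untrained predictions are not wall-to-wall positives
        for i, s in enumerate(self.strides):
            getattr(self, f"box{i}c").bias.data[...] = 1.0
            prior = math.log(5.0 / num_classes / (640 / s) ** 2)
            getattr(self, f"cls{i}c").bias.data[...] = prior

    def forward(self, feats) -> RawPrediction:
        box_logits, cls_logits = [], []
        for i, f in enumerate(feats):
            b = getattr(self, f"box{i}c")(getattr(self, f"box{i}b")(getattr(self, f"box{i}a")(f)))
            c = getattr(self, f"cls{i}c")(getattr(self, f"cls{i}b")(getattr(self, f"cls{i}a")(f)))
            box_logits.append(b)
            cls_logits.append(c)
        return RawPrediction(box_logits, cls_logits, self.strides)


# ---------------------------------------------------------------- model


class DetectionModel(nn.Module):
    """Full detector graph (backbone + neck + head) per a :class:`ModelConfig`."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        ch = config.channels
        dep = config.depth
        c1, c2_, c3_, c4, c5 = ch(64), ch(128), ch(256), ch(512), ch(1024)

        def downsample(site: str, cin: int, cout: int):
            if site in config.replacement_set:
                return ADown(cin, cout, rng=rng)
            return nn.ConvBlock(cin, cout, 3, 2, rng=rng)

        self.stem = nn.ConvBlock(config.input_channels, c1, 3, 2, rng=rng)
        self.down_p2 = downsample("P2", c1, c2_)
        self.c2f_p2 = C2f(c2_, c2_, dep(3), shortcut=True, rng=rng)
        self.down_p3 = downsample("P3", c2_, c3_)
        self.c2f_p3 = C2f(c3_, c3_, dep(6), shortcut=True, rng=rng)
        self.down_p4 = downsample("P4", c3_, c4)
        self.c2f_p4 = C2f(c4, c4, dep(6), shortcut=True, rng=rng)
        self.down_p5 = downsample("P5", c4, c5)
        self.c2f_p5 = C2f(c5, c5, dep(3), shortcut=True, rng=rng)
        self.sppf = SPPF(c5, c5, rng=rng)

        self.c2f_up4 = C2f(c5 + c4, c4, dep(3), rng=rng)
        self.c2f_up3 = C2f(c4 + c3_, c3_, dep(3), rng=rng)
        self.down_n4 = downsample("N4", c3_, c3_)
        self.c2f_n4 = C2f(c3_ + c4, c4, dep(3), rng=rng)
        self.down_n5 = downsample("N5", c4, c4)
        self.c2f_n5 = C2f(c4 + c5, c5, dep(3), rng=rng)
        self.head = DetectHead(config.num_classes, config.reg_max, (c3_, c4, c5), rng=rng)

    def forward(self, x: Tensor) -> RawPrediction:
        n, c, h, w = x.shape
        if h % 32 or w % 32:
            raise ShapeError(f"input spatial dims must be divisible by 32, got {h}x{w}")
        x = self.stem(x)
        x = self.c2f_p2(self.down_p2(x))
        f8 = self.c2f_p3(self.down_p3(x))
        f16 = self.c2f_p4(self.down_p4(f8))
        f32 = self.sppf(self.c2f_p5(self.down_p5(f16)))

        t16 = self.c2f_up4(nn.concat([f32.upsample_nearest2(), f16], axis=1))
        t8 = self.c2f_up3(nn.concat([t16.upsample_nearest2(), f8], axis=1))
        o16 = self.c2f_n4(nn.concat([self.down_n4(t8), t16], axis=1))
        o32 = self.c2f_n5(nn.concat([self.down_n5(o16), f32], axis=1))
        return self.head([t8, o16, o32])


def build_conv_block(spec: ConvBlockSpec, rng=None) -> nn.ConvBlock:
    return nn.ConvBlock(spec.in_channels, spec.out_channels, spec.kernel, spec.stride, rng=rng)


def build_adown(spec: ADownSpec, rng=None) -> ADown:
    return ADown(spec.in_channels, spec.out_channels, rng=rng)


def adown_forward(block: ADown, x: Tensor) -> Tensor:
    return block(x)


def assemble_model(config: ModelConfig, seed: int = 0) -> DetectionModel:
    return DetectionModel(config, seed=seed)


def model_forward(model: DetectionModel, images: np.ndarray) -> RawPrediction:
    """Run inference on an (N, C, H, W) float batch in [0, 1]."""
    with nn.no_grad():
        model.eval()
        return model(Tensor(np.asarray(images, dtype=np.float32)))


# ------------------------------------------------------------- decoding


def anchor_grid(hw_per_level, strides=(8, 16, 32)):
    """Cell-center coordinates (pixels) and per-anchor strides, concatenated."""
    centers, strs = [], []
    for (h, w), s in zip(hw_per_level, strides):
        ys, xs = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        pts = np.stack([(xs + 0.5) * s, (ys + 0.5) * s], axis=-1).reshape(-1, 2)
        centers.append(pts)
        strs.append(np.full(h * w, s, dtype=np.float64))
    return np.concatenate(centers), np.concatenate(strs)


def decode_distributions(box_logits: np.ndarray, reg_max: int) -> np.ndarray:
    """Expectation of the per-edge softmax distribution over integer bins.

    box_logits: (..., 4*reg_max) → distances (..., 4) in stride units.
    """
    shp = box_logits.shape[:-1]
    z = box_logits.reshape(*shp, 4, reg_max)
    z = z - z.max(axis=-1, keepdims=True)
    p = np.exp(z)
    p /= p.sum(axis=-1, keepdims=True)
    return (p * np.arange(reg_max)).sum(axis=-1)


def flatten_prediction(raw: RawPrediction, reg_max: int):
    """Concatenate levels: (N, A, 4*reg_max) box logits, (N, A, nc) class logits,
    anchor centers (A, 2) in pixels and per-anchor strides (A,)."""
    box, cls, hw = [], [], []
    for b, c in zip(raw.box_logits, raw.cls_logits):
        bd = b.data if isinstance(b, Tensor) else b
        cd = c.data if isinstance(c, Tensor) else c
        n, k, h, w = bd.shape
        hw.append((h, w))
        box.append(bd.reshape(n, k, h * w).transpose(0, 2, 1))
        cls.append(cd.reshape(n, cd.shape[1], h * w).transpose(0, 2, 1))
    centers, strides = anchor_grid(hw, raw.strides)
    return np.concatenate(box, axis=1), np.concatenate(cls, axis=1), centers, strides


def nms_xyxy(boxes: np.ndarray, scores: np.ndarray, iou_thresh: float) -> np.ndarray:
    """Greedy non-maximum suppression; returns kept indices (descending score)."""
    order = np.argsort(-scores, kind="stable")
    keep = []
    while order.size:
        i = order[0]
        keep.append(i)
        if order.size == 1:
            break
        rest = order[1:]
        xx1 = np.maximum(boxes[i, 0], boxes[rest, 0])
        yy1 = np.maximum(boxes[i, 1], boxes[rest, 1])
        xx2 = np.minimum(boxes[i, 2], boxes[rest, 2])
        yy2 = np.minimum(boxes[i, 3], boxes[rest, 3])
        inter = np.maximum(xx2 - xx1, 0) * np.maximum(yy2 - yy1, 0)
        area_i = (boxes[i, 2] - boxes[i, 0]) * (boxes[i, 3] - boxes[i, 1])
        area_r = (boxes[rest, 2] - boxes[rest, 0]) * (boxes[rest, 3] - boxes[rest, 1])
        iou = inter / np.maximum(area_i + area_r - inter, 1e-12)
        order = rest[iou <= iou_thresh]
    return np.asarray(keep, dtype=int)


def postprocess(raw: RawPrediction, conf_thresh: float = 0.25, iou_thresh: float = 0.45,
                reg_max: int = 16, image_hw=None, max_det: int = 300):
    """Decode raw head outputs into scored pixel-space detections.

    Returns, per image, a list of ``(class_id, (x1, y1, x2, y2), confidence)``
    triples after class-aware greedy NMS.
    """
    if not (0 <= conf_thresh <= 1 and 0 <= iou_thresh <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    box_l, cls_l, centers, strides = flatten_prediction(raw, reg_max)
    n = box_l.shape[0]
    results = []
    for i in range(n):
        scores = 1.0 / (1.0 + np.exp(-cls_l[i]))  # (A, nc)
        best = scores.max(axis=1)
        mask = best >= conf_thresh
        if not mask.any():
            results.append([])
            continue
        d = decode_distributions(box_l[i, mask], reg_max) * strides[mask, None]
        ctr = centers[mask]
        boxes = np.stack([
            ctr[:, 0] - d[:, 0], ctr[:, 1] - d[:, 1],
            ctr[:, 0] + d[:, 2], ctr[:, 1] + d[:, 3],
        ], axis=1)
        if image_hw is not None:
            h, w = image_hw
            boxes[:, 0::2] = boxes[:, 0::2].clip(0, w)
            boxes[:, 1::2] = boxes[:, 1::2].clip(0, h)
        sc = scores[mask]
        dets = []
        for cls_id in range(sc.shape[1]):
            cmask = sc[:, cls_id] >= conf_thresh
            if not cmask.any():
                continue
            keep = nms_xyxy(boxes[cmask], sc[cmask, cls_id], iou_thresh)
            for k in keep:
                idx = np.flatnonzero(cmask)[k]
                dets.append((cls_id, tuple(boxes[idx]), float(sc[idx, cls_id])))
        dets.sort(key=lambda t: -t[2])
        results.append(dets[:max_det])
    return results


# ------------------------------------------------------------ checkpoint


def save_checkpoint(model: DetectionModel, path):
    """Flat map of named parameter/buffer arrays plus a config snapshot."""
    state = model.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps(asdict(model.config)).encode(), dtype=np.uint8
    )
    np.savez(path, **state)


def load_checkpoint(path) -> DetectionModel:
    with np.load(path) as z:
        cfg = json.loads(bytes(z["__config__"]).decode())
        cfg["replacement_set"] = tuple(cfg["replacement_set"])
        model = DetectionModel(ModelConfig(**cfg))
        model.load_state_dict({k: z[k] for k in z.files if k != "__config__"})
    return model
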