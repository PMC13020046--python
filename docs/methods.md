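# Methods

## Architecture

The detector is the YOLOv8n graph at width multiple 0.25, depth multiple
0.33, max channels 1024: a stem (3×3 stride-2 conv), four backbone stages
(downsample + C2f cross-stage-partial block, depths 1/2/2/1), SPPF with
three chained 5×5 stride-1 max pools, an FPN top-down / PAN bottom-up neck
with two downsampling sites, and a decoupled anchor-free head at strides
8/16/32.  Each head level predicts `4·reg_max` box-distribution logits
(`reg_max` = 16 integer bins per edge distance) and one logit per class.
Every convolution is followed by batch normalization (no conv bias) and
SiLU, except the two final 1×1 prediction convolutions, which carry biases
and no normalization.  Inputs are 3-channel; grayscale radiographs are
replicated across channels (a single-channel stem would change the
parameter total by only 288 but break the budget bookkeeping below).

Baseline learnable-scalar count with 3 classes: **3,011,417** (3.01 M).

### ADown block

Dataflow: 2×2 stride-1 average pool (padding 0, output (h−1)×(w−1)) →
even channel split → first half through a 3×3 stride-2 max pool (padding
1) and a 1×1 convolution, second half through a 3×3 stride-2 convolution
(padding 1) → concatenation.  With padding 1 on the stride-2 ops, even
inputs halve exactly, so ADown is shape-compatible with the plain
downsampling convolution at every site.  Both convolutions keep the
conv→BN→SiLU convention (the alternative — a bare 1×1 fusion conv —
changes the count by only `2·c′/2` per site).  The branch-to-half
assignment (max-pool branch first) follows the published block
description; swapping the halves is parameter-identical.

Closed forms per downsampling site (`c` in, `c′` out):

| block | parameters | MACs per output element |
|---|---|---|
| plain conv | `9·c·c′ + 2c′` | `9·c` |
| ADown | `2.5·c·c′ + 2c′` | `2.5·c` |

### Replacement-set calibration

The six replaceable sites are the backbone downsamplers after the stem
(P2: 16→32, P3: 32→64, P4: 64→128, P5: 128→256) and the two PAN-neck
downsamplers (N4: 64→64, N5: 128→128).  The stem is excluded: its
3-channel input cannot be split evenly.  The reference budget pair for the
ADown variant (2.64 M parameters, 7.3 GFLOPs) is **not jointly reachable**
by any of the 64 site subsets under exact accounting — the subsets closest
on parameters ({P4, P5, N5} → 2.64 M) land at 7.66 GFLOPs, and the
subsets closest on FLOPs land at 2.60–2.62 M.  The shipped default is
therefore calibrated jointly: `calibrate_replacement_set` enumerates all
subsets and minimizes the summed squared relative error against the
budget pair, selecting **{P2, P3, P4, P5, N5}** → 2,622,041 parameters
(2.62 M) and 7.317 GFLOPs (7.3), i.e. exact on FLOPs and within 0.7% on
parameters, with reductions of 12.9% / 9.5% versus the nominal
12.3% / 9.8%.  This set also matches the verbal description of the
variant (downsampling convolutions replaced in backbone *and* neck).  The
set is exposed in `ModelConfig.replacement_set` and the YAML config, so
any other subset can be built and accounted.

## Accounting conventions

* Parameters: every learnable scalar (conv weights, BN scale/shift, head
  biases).  Reported in millions to 2 decimals.
* MACs: convolution/linear layers only, `kernel²·in_channels` per output
  element; pooling, activations and BN excluded.  FLOPs = 2×MACs at a
  3×640×640 input, reported to 1 decimal.  This is the only convention
  consistent with the 8.1 GFLOPs baseline figure for this architecture
  family.
* Reduction percentages are computed from unrounded totals and rounded to
  1 decimal at the end.
* Output shapes are traced by running a real forward pass on zeros, so
  the MAC table cannot drift from the implementation.

## Training objective

* **Assignment** — task-aligned: candidates are cells whose centers fall
  inside a ground-truth box; each box takes its top-10 candidates by
  `score^0.5 · IoU^6`; a cell claimed twice goes to the box with higher
  IoU.  Soft classification targets are the alignment metric rescaled per
  box to its best candidate IoU.
* **Classification** — binary cross-entropy on logits against the soft
  targets, multiplied by per-class inverse-frequency weights (normalized
  to mean 1), summed and divided by the total target score.  Weights enter
  the loss, not the sampler.
* **Box** — `1 − CIoU` over assigned cells, weighted by target score.
  CIoU's aspect coefficient `α = v/(v − IoU + 1)` is treated as a
  constant during backpropagation (the standard practice).
* **DFL** — cross-entropy of each edge-distance softmax against the two
  integer bins bracketing the target distance (in stride units, clipped
  to `[0, reg_max − 1 − 0.01]`), linearly weighted.
* **Combination** — `7.5·box + 0.5·cls + 1.5·dfl`; the component weights
  are the upstream defaults of this detector family.
* **Schedule** — SGD, momentum 0.937, weight decay 5·10⁻⁴ (BN parameters
  and biases excluded from decay), lr0 = 0.01 cosine-annealed to
  lr0·lrf = 10⁻⁴ at the final epoch, linear warmup over the first 3
  epochs (configurable).  Nominal settings: batch 16, 200 epochs.
* Head biases are initialized to a low-objectness prior
  (`log(5/nc/(640/s)²)` per level) so the initial classification loss is
  not dominated by the ~10³ background cells.

All randomness (weight init, shuffling, phantom geometry, splits) derives
from explicit `numpy` generators; two runs with the same seed produce
bit-identical datasets, loss sequences and partitions.

## Evaluation conventions

* Matching for PR/AP is class-strict, greedy by descending confidence,
  one-to-one; confidence ties break by input order, IoU ties by first
  ground-truth index.
* AP: 101-point interpolation of the precision envelope; the interpolated
  precision at recall `g` is the envelope value at the first point with
  recall ≥ `g` and 0 beyond the maximum achieved recall (so a perfect
  detector scores exactly 1 and a detector with no true positives scores
  exactly 0).  Classes without ground truth have undefined AP and are
  excluded from means.
* Reported per-class P and R are taken at the confidence maximizing the
  class F1 (the convention of the common training toolchain); mAP uses
  all detections above confidence 0.001, the confusion matrix uses
  confidence 0.25 and IoU 0.45 with class-agnostic matching, columns
  (per ground-truth class, plus background) normalized to 1.

## Synthetic phantoms

The generator emulates the statistical structure of the emulated study
population, not radiological appearance: grayscale 640×640 (configurable)
images with a bright femur silhouette on a dark background, exactly one
fracture per image, three classes with imbalanced counts (defaults
261/579/136 over 976 images via largest-remainder apportionment — counts
are apportioned, not sampled, so the manifest is exact), small targets
(boxes 10–30% of the image side — the reference data's box statistics are
not published, so this range is an assumption exposed in
`PhantomConfig.extent_range`).  Class geometry: A1 one oblique line
(35–65°), A2 two–three intersecting lines with an offset fragment, A3 one
transverse (±12°) or reverse-oblique (−40…−20°) line below the
trochanter.  Gaussian blur (σ 1.5) and Gaussian noise (σ 4) are applied;
Poisson noise is available but off by default.  The carved line is ≥ 20
gray levels darker than surrounding bone by construction, which is what
makes the tiny-overfit training check meaningful.

What passing tests on phantoms does **not** show: performance on clinical
radiographs.  Phantoms have no soft tissue, no positioning variability, no
exposure differences and perfectly consistent labels; results on them
validate the pipeline's mechanics (shapes, losses, convergence, metric
arithmetic), not clinical accuracy.

## Problem sizes in the test suite

The repository's training checks run at deliberately small scale, chosen
as the smallest sizes that still exercise every code path: the smoke run
generates 64 phantoms at 160×160, trains the ADown variant with batch 8
and a 400-iteration cap, and requires the composite loss to fall by at
least 50% (it typically does so within ~40 iterations and stops early);
the determinism checks use 2–8 images and 2–4 iterations.  Nominal
full-scale settings (640×640, batch 16, 200 epochs) remain the defaults
in `TrainConfig`.

## HSV augmentation on grayscale input

The pipeline implements the standard YOLO augmentations (mosaic with
affine scale ∈ [0.5, 1.5] and translate ≤ 0.1, horizontal flip with
`cx → 1 − cx`, HSV gains 0.015/0.7/0.4).  On replicated-grayscale images
hue and saturation jitter are no-ops by construction — saturation is zero
— so only the value (brightness) gain has an effect; this is documented
rather than "fixed", since it is exactly what happens when the upstream
toolchain is applied to grayscale radiographs.  Mosaic uses a jittered
canvas center, clips boxes to their quadrant and drops boxes below 2 px.
Horizontal-flip dataset doubling exactly doubles per-class instance
counts.

## Known limitations

* The autograd engine is correctness-first: convolution is im2col +
  BLAS matmul, activations are retained for backward, and training at
  640×640 is impractical on a laptop CPU — the package's training-scale
  claims are the small-scale ones above.
* Batch normalization uses true batch statistics with full backward;
  very small batches (< 4) make the statistics noisy, as usual.
* The replacement-set calibration resolves an inconsistency in the
  reference budget pair (see above); if the intended set differs, any
  subset can be selected explicitly in the model YAML.
* `N = 1` in the reference description of mAP is read as a typo for the
  number of classes (3), and the recall equation's left-hand symbol as R.
* One box per image is assumed by the phantom generator (matching the
  emulated study, where image and instance counts coincide); the
  detection pipeline itself handles any number of boxes.
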