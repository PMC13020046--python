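"""Deterministic parameter and FLOP accounting for the detector.

Conventions
-----------
* Parameters: every learnable scalar — convolution weights, normalization
  scale/shift, head biases.  Reported in millions to 2 decimals.
* MACs: multiply-accumulates of convolution/linear layers only
  (``kernel² · in_channels`` per output element); pooling, activation and
  normalization are excluded.  FLOPs = 2 × MACs, reported in GFLOPs to
  1 decimal at a stated input size (default 640×640).
* Reduction percentages are computed from unrounded totals and reported to
  1 decimal.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from . import nn
from .arch import (ADownSpec, ConvBlockSpec, DetectionModel, ModelConfig,
                   ShapeError, VALID_SITES, assemble_model)


@dataclass
class AccountingReport:
    per_layer: list  # (name, kind, param_count, mac_count)
    total_params: int
    total_gflops: float
    input_hw: tuple[int, int]

    @property
    def params_millions(self) -> float:
        return round(self.total_params / 1e6, 2)

    @property
    def gflops(self) -> float:
        return round(self.total_gflops, 1)

    @property
    def total_macs(self) -> int:
        return int(sum(m for _, _, _, m in self.per_layer))


def count_parameters(model: nn.Module) -> int:
    """Closed-form learnable-scalar count from layer hyperparameters.

    (Tests cross-check this against a brute-force traversal that sums the
    element counts of every parameter array.)
    """
    total = 0
    for m in model.modules():
        if isinstance(m, nn.Conv2d):
            total += m.kernel**2 * m.in_channels * m.out_channels
            if m.has_bias:
                total += m.out_channels
        elif isinstance(m, nn.BatchNorm2d):
            total += 2 * m.num_features
    return total


def account(model: DetectionModel, input_hw=(640, 640)) -> AccountingReport:
    """Per-layer parameter and MAC table at the given input size."""
    h, w = input_hw
    if h % 32 or w % 32:
        raise ShapeError(f"input dims must be divisible by 32, got {h}x{w}")
    with nn.no_grad():
        model.eval()
        model(nn.Tensor(np.zeros((1, model.config.input_channels, h, w), dtype=np.float32)))
    rows = []
    for name, m in _named_conv_and_norm(model):
        if isinstance(m, nn.Conv2d):
            p = m.kernel**2 * m.in_channels * m.out_channels + (m.out_channels if m.has_bias else 0)
            ho, wo = m.last_output_hw
            macs = m.kernel**2 * m.in_channels * m.out_channels * ho * wo
            rows.append((name, "conv", p, macs))
        else:
            rows.append((name, "batchnorm", 2 * m.num_features, 0))
    total_p = sum(r[2] for r in rows)
    total_m = sum(r[3] for r in rows)
    return AccountingReport(rows, total_p, 2.0 * total_m / 1e9, (h, w))


def _named_conv_and_norm(module: nn.Module, prefix: str = ""):
    for name, child in module._modules.items():
        full = f"{prefix}{name}"
        if isinstance(child, (nn.Conv2d, nn.BatchNorm2d)):
            yield full, child
        else:
            yield from _named_conv_and_norm(child, prefix=f"{full}.")


def estimate_gflops(model: DetectionModel, input_hw=(640, 640)) -> float:
    return account(model, input_hw).total_gflops


def compare_models(report_a: AccountingReport, report_b: AccountingReport):
    """Percentage reductions (params, FLOPs) of b relative to a, 1 decimal."""
    if report_a.input_hw != report_b.input_hw:
        raise ValueError("reports were computed at different input sizes")
    if report_a.total_params == 0 or report_a.total_gflops == 0:
        raise ZeroDivisionError("baseline totals must be non-zero")
    dp = 100.0 * (report_a.total_params - report_b.total_params) / report_a.total_params
    df = 100.0 * (report_a.total_gflops - report_b.total_gflops) / report_a.total_gflops
    return round(dp, 1), round(df, 1)


# ----------------------------------------------------------- closed forms


def conv_block_params(c_in: int, c_out: int, kernel: int = 3) -> int:
    return ConvBlockSpec(c_in, c_out, kernel).param_count


def adown_params(c_in: int, c_out: int) -> int:
    return ADownSpec(c_in, c_out).param_count


def calibrate_replacement_set(printed_params_m: float = 2.64,
                              printed_gflops: float = 7.3,
                              config: ModelConfig | None = None,
                              input_hw=(640, 640)) -> tuple[str, ...]:
    """Choose the ADown replacement set best matching a printed budget pair.

    Enumerates all subsets of the replaceable downsample sites, computes
    exact parameter and FLOP totals for each variant from the baseline
    report and per-site closed-form deltas, and returns the subset with the
    smallest summed squared relative error against the printed
    (params-in-millions, GFLOPs) pair.
    """
    config = config or ModelConfig()
    base = account(assemble_model(config), input_hw)

    # per-site deltas from closed forms (exact: MAC depends only on the
    # output grid of the site, which ADown preserves)
    site_dims = _site_dims(config)
    deltas = {}
    for site, (c1, c2, stride) in site_dims.items():
        ho, wo = input_hw[0] // stride, input_hw[1] // stride
        dp = conv_block_params(c1, c2) - adown_params(c1, c2)
        conv_macs = 9 * c1 * c2 * ho * wo
        adown_macs = (9 * (c1 // 2) * (c2 // 2) + (c1 // 2) * (c2 // 2)) * ho * wo
        deltas[site] = (dp, conv_macs - adown_macs)

    best, best_err = (), float("inf")
    for r in range(len(VALID_SITES) + 1):
        for subset in itertools.combinations(VALID_SITES, r):
            p = base.total_params - sum(deltas[s][0] for s in subset)
            g = 2.0 * (base.total_macs - sum(deltas[s][1] for s in subset)) / 1e9
            err = ((p / 1e6 - printed_params_m) / printed_params_m) ** 2 \
                + ((g - printed_gflops) / printed_gflops) ** 2
            if err < best_err:
                best, best_err = subset, err
    return best


def _site_dims(config: ModelConfig) -> dict[str, tuple[int, int, int]]:
    ch = config.channels
    return {
        "P2": (ch(64), ch(128), 4),
        "P3": (ch(128), ch(256), 8),
        "P4": (ch(256), ch(512), 16),
        "P5": (ch(512), ch(1024), 32),
        "N4": (ch(256), ch(256), 16),
        "N5": (ch(512), ch(512), 32),
    }
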