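"""Neural-network modules over the autograd core: Conv2d, BatchNorm2d and
the Conv→BN→SiLU block convention used everywhere in the detector."""

from __future__ import annotations

import math

import numpy as np

from .tensor import Tensor


class Module:
    """Minimal module container: named parameters, buffers, train/eval mode."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._modules: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def register_parameter(self, name: str, value: np.ndarray) -> Tensor:
        t = Tensor(np.asarray(value, dtype=np.float32), requires_grad=True)
        self._params[name] = t
        object.__setattr__(self, name, t)
        return t

    def register_buffer(self, name: str, value: np.ndarray):
        self._buffers[name] = np.asarray(value, dtype=np.float32)
        object.__setattr__(self, name, self._buffers[name])

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield f"{prefix}{name}", p
        for mname, mod in self._modules.items():
            yield from mod.named_parameters(prefix=f"{prefix}{mname}.")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def modules(self):
        yield self
        for mod in self._modules.values():
            yield from mod.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def num_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    # ----------------------------------------------------------- state IO
    def state_dict(self) -> dict[str, np.ndarray]:
        out = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, b in self._named_buffers():
            out[name] = b.copy()
        return out

    def _named_buffers(self, prefix: str = ""):
        for name, b in self._buffers.items():
            yield f"{prefix}{name}", b
        for mname, mod in self._modules.items():
            yield from mod._named_buffers(prefix=f"{prefix}{mname}.")

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = dict(self.named_parameters())
        buffers = dict(self._named_buffers())
        missing = (set(params) | set(buffers)) - set(state)
        if missing:
            raise KeyError(f"missing keys in state dict: {sorted(missing)[:5]} ...")
        for name, p in params.items():
            arr = np.asarray(state[name], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data[...] = arr
        for name, b in buffers.items():
            b[...] = np.asarray(state[name], dtype=b.dtype)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    """Plain 2-D convolution (no normalization, optional bias)."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int = 1, padding: int = 0, bias: bool = False,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if in_channels <= 0 or out_channels <= 0:
            raise ValueError("channel counts must be positive")
        rng = rng or np.random.default_rng(0)
        self.in_channels, self.out_channels = in_channels, out_channels
        self.kernel, self.stride, self.padding = kernel, stride, padding
        fan_in = in_channels * kernel * kernel
        bound = 1.0 / math.sqrt(fan_in)
        self.register_parameter(
            "weight", rng.uniform(-bound, bound, size=(out_channels, in_channels, kernel, kernel))
        )
        self.has_bias = bias
        if bias:
            self.register_parameter("bias", rng.uniform(-bound, bound, size=(out_channels,)))

    def forward(self, x: Tensor) -> Tensor:
        h, w = x.shape[2], x.shape[3]
        k, s, p = self.kernel, self.stride, self.padding
        self.last_output_hw = ((h + 2 * p - k) // s + 1, (w + 2 * p - k) // s + 1)
        return x.conv2d(self.weight, self.bias if self.has_bias else None,
                        stride=self.stride, padding=self.padding)


class BatchNorm2d(Module):
    def __init__(self, num_features: int, eps: float = 1e-3, momentum: float = 0.03):
        super().__init__()
        self.num_features = num_features
        self.eps, self.momentum = eps, momentum
        self.register_parameter("gamma", np.ones(num_features))
        self.register_parameter("beta", np.zeros(num_features))
        self.register_buffer("running_mean", np.zeros(num_features))
        self.register_buffer("running_var", np.ones(num_features))

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            self.running_mean *= 1 - self.momentum
            self.running_mean += self.momentum * mu
            self.running_var *= 1 - self.momentum
            self.running_var += self.momentum * var
        else:
            mu, var = self.running_mean, self.running_var
        if self.training:
            return self._train_bn(x, mu.astype(x.dtype), var.astype(x.dtype))
        inv = (1.0 / np.sqrt(var + self.eps)).astype(x.dtype)
        scale = (self.gamma.data * inv).reshape(1, -1, 1, 1)
        shift = (self.beta.data - self.gamma.data * mu * inv).reshape(1, -1, 1, 1)
        out = x * Tensor(scale) + Tensor(shift)
        return out

    def _train_bn(self, x: Tensor, mu: np.ndarray, var: np.ndarray) -> Tensor:
        """Full batch-norm backward (through the batch statistics)."""
        eps = self.eps
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (x.data - mu.reshape(1, -1, 1, 1)) * inv.reshape(1, -1, 1, 1)
        gamma, beta = self.gamma, self.beta
        out_data = gamma.data.reshape(1, -1, 1, 1) * xhat + beta.data.reshape(1, -1, 1, 1)
        m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]

        def backward(g):
            if gamma.requires_grad:
                gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
            if beta.requires_grad:
                beta._accum(g.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                gmean = g.mean(axis=(0, 2, 3)).reshape(1, -1, 1, 1)
                gxhat_mean = (g * xhat).mean(axis=(0, 2, 3)).reshape(1, -1, 1, 1)
                gx = (gamma.data * inv).reshape(1, -1, 1, 1) * (g - gmean - xhat * gxhat_mean)
                x._accum(gx.astype(x.dtype))

        return x._make(out_data.astype(x.dtype), (x, gamma, beta), backward)


class ConvBlock(Module):
    """Conv → BatchNorm → SiLU, the detector's uniform block.

    Kernel must be 1 or 3; padding is kernel//2 so stride-1 blocks preserve
    spatial size and stride-2 blocks halve even inputs exactly.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int = 1,
                 stride: int = 1, act: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if kernel not in (1, 3):
            raise ValueError(f"unsupported kernel size {kernel}; expected 1 or 3")
        if in_channels <= 0 or out_channels <= 0:
            raise ValueError("channel counts must be positive")
        self.conv = Conv2d(in_channels, out_channels, kernel, stride, kernel // 2, bias=False, rng=rng)
        self.bn = BatchNorm2d(out_channels)
        self.act = act

    def forward(self, x: Tensor) -> Tensor:
        y = self.bn(self.conv(x))
        return y.silu() if self.act else y


class SGD:
    """SGD with momentum, decoupled parameter groups and weight decay."""

    def __init__(self, groups, lr: float, momentum: float = 0.937):
        # groups: list of dicts {params: [Tensor], weight_decay: float}
        self.groups = groups
        self.lr = lr
        self.momentum = momentum
        self._v = [[np.zeros_like(p.data) for p in g["params"]] for g in groups]

    def step(self):
        for g, vs in zip(self.groups, self._v):
            wd = g.get("weight_decay", 0.0)
            lr = g.get("lr", self.lr)
            for p, v in zip(g["params"], vs):
                if p.grad is None:
                    continue
                d = p.grad + wd * p.data
                v *= self.momentum
                v += d
                p.data -= lr * v

    def zero_grad(self):
        for g in self.groups:
            for p in g["params"]:
                p.zero_grad()
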