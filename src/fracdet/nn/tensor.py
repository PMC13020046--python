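"""Reverse-mode automatic differentiation over numpy arrays.

A compact define-by-run autograd core: each operation returns a new
:class:`Tensor` holding the forward value and a closure that maps the
output gradient to parent gradients.  The op set is exactly what a
single-stage convolutional detector needs — convolution, pooling,
normalization, elementwise math (including ``atan`` for complete-IoU),
reductions, indexing and fused losses.  float32 is the working dtype;
gradient-check tests run the same ops in float64.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "concat", "stack", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (inference / assignment)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    # make numpy defer to the reflected operators instead of elementwise
    # coercion (e.g. ndarray - Tensor must hit Tensor.__rsub__)
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self._parents = _parents if self.requires_grad else ()
        self._backward = _backward if self.requires_grad else None

    # ------------------------------------------------------------- basics
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    @property
    def dtype(self):
        return self.data.dtype

    def __len__(self):
        return len(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    # ------------------------------------------------------------ backward
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative topological sort (deep graphs)
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                node._backward = None  # free graph
                node._parents = ()

    def _accum(self, grad: np.ndarray):
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    def zero_grad(self):
        self.grad = None

    # ------------------------------------------------------- construction
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other))

    def _make(self, data, parents, backward) -> "Tensor":
        req = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        return Tensor(data, requires_grad=req, _parents=tuple(p for p in parents if p.requires_grad), _backward=backward if req else None)

    # -------------------------------------------------------- elementwise
    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data**2, other.shape))

        return self._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, p: float):
        out_data = self.data**p

        def backward(g):
            self._accum(g * p * self.data ** (p - 1))

        return self._make(out_data, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accum(g * out_data)

        return self._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            self._accum(g * 0.5 / out_data)

        return self._make(out_data, (self,), backward)

    def atan(self):
        def backward(g):
            self._accum(g / (1.0 + self.data**2))

        return self._make(np.arctan(self.data), (self,), backward)

    def clip(self, lo=None, hi=None):
        """Clamp values; gradient passes only where unclamped."""
        out_data = np.clip(self.data, lo, hi)
        mask = np.ones_like(self.data, dtype=bool)
        if lo is not None:
            mask &= self.data >= lo
        if hi is not None:
            mask &= self.data <= hi

        def backward(g):
            self._accum(g * mask)

        return self._make(out_data, (self,), backward)

    def maximum(self, other):
        other = self._lift(other)
        out_data = np.maximum(self.data, other.data)
        pick = self.data >= other.data  # ties route to self

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * pick, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * ~pick, other.shape))

        return self._make(out_data, (self, other), backward)

    def minimum(self, other):
        other = self._lift(other)
        out_data = np.minimum(self.data, other.data)
        pick = self.data <= other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * pick, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * ~pick, other.shape))

        return self._make(out_data, (self, other), backward)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            self._accum(g * s * (1.0 - s))

        return self._make(s, (self,), backward)

    def silu(self):
        s = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            self._accum(g * s * (1.0 + self.data * (1.0 - s)))

        return self._make(self.data * s, (self,), backward)

    # --------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                axes = tuple(a % self.data.ndim for a in axes)
                gg = np.expand_dims(gg, axes)
            self._accum(np.broadcast_to(gg, self.shape).astype(self.data.dtype))

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    # ------------------------------------------------------------- shape
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)

        def backward(g):
            self._accum(g.reshape(self.shape))

        return self._make(out_data, (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            self._accum(g.transpose(inv))

        return self._make(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        return self._make(out_data, (self,), backward)

    # ------------------------------------------------------------ linalg
    def matmul(self, other):
        other = self._lift(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.shape))

        return self._make(out_data, (self, other), backward)

    __matmul__ = matmul

    # ------------------------------------------------------ fused softmax
    def softmax(self, axis=-1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * p).sum(axis=axis, keepdims=True)
            self._accum(p * (g - dot))

        return self._make(p, (self,), backward)

    def log_softmax(self, axis=-1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        out_data = z - lse
        p = np.exp(out_data)

        def backward(g):
            self._accum(g - p * g.sum(axis=axis, keepdims=True))

        return self._make(out_data, (self,), backward)

    # ----------------------------------------------------- spatial ops
    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None, stride: int = 1, padding: int = 0):
        """2-D cross-correlation, NCHW × OIkk, via im2col + matmul."""
        x, w = self.data, weight.data
        n, c, h, wd = x.shape
        o, ci, kh, kw = w.shape
        if ci != c:
            raise ValueError(f"channel mismatch: input {c}, weight expects {ci}")
        s, p = stride, padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        ho = (h + 2 * p - kh) // s + 1
        wo = (wd + 2 * p - kw) // s + 1
        win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::s, ::s]
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(n, ho * wo, c * kh * kw)
        wmat = w.reshape(o, -1)
        out = cols @ wmat.T  # (n, ho*wo, o)
        if bias is not None:
            out = out + bias.data
        out_data = out.transpose(0, 2, 1).reshape(n, o, ho, wo)

        def backward(g):
            gflat = g.reshape(n, o, ho * wo).transpose(0, 2, 1)  # (n, L, o)
            if weight.requires_grad:
                gw = np.einsum("nlo,nlk->ok", gflat, cols, optimize=True)
                weight._accum(gw.reshape(w.shape))
            if bias is not None and bias.requires_grad:
                bias._accum(gflat.sum(axis=(0, 1)))
            if self.requires_grad:
                gcols = gflat @ wmat  # (n, L, c*kh*kw)
                gcols = gcols.reshape(n, ho, wo, c, kh, kw).transpose(0, 3, 4, 5, 1, 2)
                gxp = np.zeros_like(xp)
                for i in range(kh):
                    for j in range(kw):
                        gxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += gcols[:, :, i, j]
                self._accum(gxp[:, :, p : p + h, p : p + wd] if p else gxp)

        parents = (self, weight) if bias is None else (self, weight, bias)
        return self._make(out_data, parents, backward)

    def _pool2d(self, kernel: int, stride: int, padding: int, mode: str):
        x = self.data
        n, c, h, w = x.shape
        k, s, p = kernel, stride, padding
        if p:
            fill = -np.inf if mode == "max" else 0.0
            xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=fill)
        else:
            xp = x
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        win = win.reshape(n, c, ho, wo, k * k)
        if mode == "max":
            arg = win.argmax(axis=-1)
            out_data = np.take_along_axis(win, arg[..., None], axis=-1)[..., 0]
        else:
            out_data = win.mean(axis=-1)

        def backward(g):
            gxp = np.zeros_like(xp)
            if mode == "max":
                for q in range(k * k):
                    mask = arg == q
                    if not mask.any():
                        continue
                    i, j = q // k, q % k
                    gxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += g * mask
            else:
                ga = g / (k * k)
                for q in range(k * k):
                    i, j = q // k, q % k
                    gxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += ga
            self._accum(gxp[:, :, p : p + h, p : p + w] if p else gxp)

        return self._make(out_data, (self,), backward)

    def max_pool2d(self, kernel: int, stride: int, padding: int = 0):
        return self._pool2d(kernel, stride, padding, "max")

    def avg_pool2d(self, kernel: int, stride: int, padding: int = 0):
        return self._pool2d(kernel, stride, padding, "avg")

    def upsample_nearest2(self):
        """Nearest-neighbour ×2 upsampling."""
        n, c, h, w = self.data.shape
        out_data = self.data.repeat(2, axis=2).repeat(2, axis=3)

        def backward(g):
            self._accum(g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

        return self._make(out_data, (self,), backward)

    # ---------------------------------------------------------- losses
    def bce_with_logits(self, target: np.ndarray):
        """Elementwise binary cross-entropy on logits (numerically stable)."""
        z = self.data
        t = np.asarray(target)
        out_data = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))

        def backward(g):
            self._accum(g * (1.0 / (1.0 + np.exp(-z)) - t))

        return self._make(out_data, (self,), backward)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(a, b)
                t._accum(g[tuple(idx)])

    req = _GRAD_ENABLED and any(t.requires_grad for t in tensors)
    return Tensor(out_data, requires_grad=req,
                  _parents=tuple(t for t in tensors if t.requires_grad),
                  _backward=backward if req else None)


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(g, i, axis=axis))

    req = _GRAD_ENABLED and any(t.requires_grad for t in tensors)
    return Tensor(out_data, requires_grad=req,
                  _parents=tuple(t for t in tensors if t.requires_grad),
                  _backward=backward if req else None)
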