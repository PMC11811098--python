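"""Minimal reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine: each :class:`Tensor` wraps an ndarray and, when
produced by an operation, remembers its parents and a closure that maps the
output gradient to parent gradients.  ``backward()`` runs the tape in
reverse topological order.  The op set is exactly what the segmentation
U-Net and the windowed-attention classifier need: broadcast arithmetic,
matmul, reshape/transpose/slice/concat/roll, reductions, softmax and
log-softmax, layer norm, GELU/ReLU/sigmoid, 3×3 convolution (im2col),
2×2 max-pool and nearest-neighbour upsampling.
"""

from __future__ import annotations

import math
from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "no_grad"]

_grad_enabled = True


class no_grad:
    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(self, data, requires_grad: bool = False, name: str = ""):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad and _grad_enabled
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None
        self.name = name

    # -- plumbing ----------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad needs a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- helpers -----------------------------------------------------------

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other))

    def _make(self, data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(data)
        if _grad_enabled and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.shape)
                )

        return self._make(out_data, (self, other), backward)

    def __pow__(self, exponent: float):
        out_data = self.data**exponent

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1))

        return self._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.shape))

        return self._make(out_data, (self, other), backward)

    # -- shape ops ---------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.shape
        out_data = self.data.reshape(shape)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.reshape(orig))

        return self._make(out_data, (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out_data = self.data.transpose(axes)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inv))

        return self._make(out_data, (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accumulate(full)

        return self._make(out_data, (self,), backward)

    def roll(self, shift, axis):
        out_data = np.roll(self.data, shift, axis=axis)

        def backward(g):
            if self.requires_grad:
                neg = tuple(-s for s in shift) if isinstance(shift, tuple) else -shift
                self._accumulate(np.roll(g, neg, axis=axis))

        return self._make(out_data, (self,), backward)

    @staticmethod
    def concat(tensors: Sequence["Tensor"], axis: int = 0) -> "Tensor":
        tensors = [Tensor._wrap(t) for t in tensors]
        out_data = np.concatenate([t.data for t in tensors], axis=axis)
        sizes = [t.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)

        def backward(g):
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(lo, hi)
                    t._accumulate(g[tuple(sl)])

        out = Tensor(out_data)
        if _grad_enabled and any(t.requires_grad for t in tensors):
            out.requires_grad = True
            out._parents = tuple(tensors)
            out._backward = backward
        return out

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if self.requires_grad:
                gg = g
                if axis is not None and not keepdims:
                    gg = np.expand_dims(gg, axis)
                self._accumulate(np.broadcast_to(gg, self.shape).copy())

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            denom = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            denom = math.prod(self.shape[a] for a in axes)
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / denom)

    # -- nonlinearities ----------------------------------------------------

    def relu(self):
        mask = self.data > 0
        out_data = self.data * mask

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return self._make(out_data, (self,), backward)

    def sigmoid(self):
        from scipy.special import expit

        out_data = expit(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), backward)

    def gelu(self):
        # tanh approximation (matches common transformer implementations)
        x = self.data
        c = math.sqrt(2.0 / math.pi)
        inner = c * (x + 0.044715 * x**3)
        t = np.tanh(inner)
        out_data = 0.5 * x * (1.0 + t)

        def backward(g):
            if self.requires_grad:
                dt = (1.0 - t**2) * c * (1.0 + 3 * 0.044715 * x**2)
                self._accumulate(g * (0.5 * (1.0 + t) + 0.5 * x * dt))

        return self._make(out_data, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * out_data)

        return self._make(out_data, (self,), backward)

    def log(self):
        out_data = np.log(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        return self._make(out_data, (self,), backward)

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            if self.requires_grad:
                dot = (g * out_data).sum(axis=axis, keepdims=True)
                self._accumulate(out_data * (g - dot))

        return self._make(out_data, (self,), backward)

    def log_softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        out_data = z - lse
        soft = np.exp(out_data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g - soft * g.sum(axis=axis, keepdims=True))

        return self._make(out_data, (self,), backward)

    def batch_norm(self, weight: "Tensor", bias: "Tensor",
                   running_mean: np.ndarray, running_var: np.ndarray,
                   training: bool, momentum: float = 0.1, eps: float = 1e-5):
        """Per-channel batch norm of NCHW maps; updates running stats in place."""
        x = self.data
        if training:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = x.shape[0] * x.shape[2] * x.shape[3]
            running_mean *= 1.0 - momentum
            running_mean += momentum * mu
            running_var *= 1.0 - momentum
            running_var += momentum * var * (m / max(m - 1, 1))
        else:
            mu, var = running_mean, running_var
        inv = (1.0 / np.sqrt(var + eps)).astype(x.dtype)
        xhat = (x - mu[None, :, None, None]) * inv[None, :, None, None]
        out_data = (
            xhat * weight.data[None, :, None, None]
            + bias.data[None, :, None, None]
        )

        def backward(g):
            gx_hat = g * weight.data[None, :, None, None]
            if self.requires_grad:
                if training:
                    mean_g = gx_hat.mean(axis=(0, 2, 3), keepdims=True)
                    mean_gx = (gx_hat * xhat).mean(axis=(0, 2, 3), keepdims=True)
                    dx = (gx_hat - mean_g - xhat * mean_gx) * inv[None, :, None, None]
                else:
                    dx = gx_hat * inv[None, :, None, None]
                self._accumulate(dx)
            if weight.requires_grad:
                weight._accumulate((g * xhat).sum(axis=(0, 2, 3)))
            if bias.requires_grad:
                bias._accumulate(g.sum(axis=(0, 2, 3)))

        return self._make(out_data, (self, weight, bias), backward)

    def layer_norm(self, weight: "Tensor", bias: "Tensor", eps: float = 1e-5):
        """Layer norm over the last axis with affine parameters."""
        x = self.data
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (x - mu) * inv
        out_data = xhat * weight.data + bias.data
        n = x.shape[-1]

        def backward(g):
            gx_hat = g * weight.data
            if self.requires_grad:
                term = (
                    gx_hat
                    - gx_hat.mean(axis=-1, keepdims=True)
                    - xhat * (gx_hat * xhat).mean(axis=-1, keepdims=True)
                )
                self._accumulate(term * inv)
            if weight.requires_grad:
                weight._accumulate(
                    (g * xhat).reshape(-1, n).sum(axis=0)
                )
            if bias.requires_grad:
                bias._accumulate(g.reshape(-1, n).sum(axis=0))

        return self._make(out_data, (self, weight, bias), backward)

    # -- image ops (NCHW) --------------------------------------------------

    def conv2d(self, weight: "Tensor", bias: "Tensor" | None = None,
               padding: int = 1):
        """2-D convolution, stride 1, square kernel, NCHW layout."""
        x = self.data
        w = weight.data
        out_data, cols = _conv2d_forward(x, w, padding)
        if bias is not None:
            out_data = out_data + bias.data[None, :, None, None]

        def backward(g):
            if weight.requires_grad:
                weight._accumulate(_conv2d_dw(cols, g, w.shape))
            if bias is not None and bias.requires_grad:
                bias._accumulate(g.sum(axis=(0, 2, 3)))
            if self.requires_grad:
                self._accumulate(_conv2d_dx(g, w, padding, x.shape))

        parents = (self, weight) if bias is None else (self, weight, bias)
        return self._make(out_data, parents, backward)

    def max_pool2d(self):
        """2×2 max pooling, stride 2; spatial dims must be even."""
        n, c, h, w = self.data.shape
        xr = self.data.reshape(n, c, h // 2, 2, w // 2, 2)
        xr = xr.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        idx = xr.argmax(axis=-1)
        out_data = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

        def backward(g):
            if self.requires_grad:
                gw = np.zeros((n, c, h // 2, w // 2, 4), dtype=g.dtype)
                np.put_along_axis(gw, idx[..., None], g[..., None], axis=-1)
                gw = gw.reshape(n, c, h // 2, w // 2, 2, 2)
                gw = gw.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)
                self._accumulate(gw)

        return self._make(out_data, (self,), backward)

    def upsample2x(self):
        """Nearest-neighbour ×2 upsampling of NCHW maps."""
        out_data = self.data.repeat(2, axis=2).repeat(2, axis=3)

        def backward(g):
            if self.requires_grad:
                n, c, h2, w2 = g.shape
                gg = g.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))
                self._accumulate(gg)

        return self._make(out_data, (self,), backward)


# ---------------------------------------------------------------------------
# convolution internals (im2col; stride 1 only)


def _im2col(x: np.ndarray, k: int, padding: int) -> np.ndarray:
    """(N, C, H, W) -> (N*H_out*W_out, C*k*k) patch matrix."""
    n, c, h, w = x.shape
    if padding:
        x = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    view = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    # view: (N, C, H_out, W_out, k, k) -> (N, H_out, W_out, C, k, k)
    view = view.transpose(0, 2, 3, 1, 4, 5)
    n_, ho, wo = view.shape[:3]
    return np.ascontiguousarray(view).reshape(n_ * ho * wo, c * k * k)


def _conv2d_forward(x: np.ndarray, w: np.ndarray, padding: int):
    n, c, h, ww = x.shape
    co, ci, k, _ = w.shape
    ho = h + 2 * padding - k + 1
    wo = ww + 2 * padding - k + 1
    cols = _im2col(x, k, padding)
    out = cols @ w.reshape(co, ci * k * k).T
    out = out.reshape(n, ho, wo, co).transpose(0, 3, 1, 2)
    return np.ascontiguousarray(out), cols


def _conv2d_dw(cols: np.ndarray, g: np.ndarray, w_shape) -> np.ndarray:
    co, ci, k, _ = w_shape
    gmat = g.transpose(0, 2, 3, 1).reshape(-1, co)  # (N*Ho*Wo, Co)
    return (gmat.T @ cols).reshape(w_shape)


def _conv2d_dx(g: np.ndarray, w: np.ndarray, padding: int, x_shape) -> np.ndarray:
    # full correlation of g with the 180°-rotated kernels
    co, ci, k, _ = w.shape
    w_rot = w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (Ci, Co, k, k)
    dx, _ = _conv2d_forward(g, np.ascontiguousarray(w_rot), k - 1 - padding)
    assert dx.shape == x_shape
    return dx
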