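"""Reverse-mode automatic differentiation on NumPy arrays.

A small tape-based engine: every operation records its parents and a
closure that propagates the output gradient to them.  ``Tensor.backward``
walks the tape in reverse topological order.  Only the primitives that
cannot be expressed compositionally (convolution, pooling, indexing,
nearest-neighbour upsampling, a few nonlinearities with known closed-form
derivatives) carry hand-written gradients; everything else in the library
is built from these and differentiated automatically.

Multiply–accumulate (MAC) accounting for the profiler is hooked into the
two dense primitives (``matmul`` and ``conv2d``) via :class:`MacCounter`.
"""

from __future__ import annotations

import contextlib
import math
from typing import Callable, Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import special as _special

__all__ = [
    "Tensor",
    "Parameter",
    "as_tensor",
    "no_grad",
    "MacCounter",
    "concatenate",
    "stack",
    "matmul",
    "conv2d",
    "max_pool2d",
    "upsample_nearest2x",
    "sigmoid",
    "elu",
    "gelu",
    "relu",
    "erf",
    "layernorm",
    "softmax",
]

_GRAD_ENABLED = True
_MAC_COUNTER: "MacCounter | None" = None


class MacCounter:
    """Context manager accumulating multiply–accumulate counts of dense ops."""

    def __init__(self) -> None:
        self.macs = 0

    def add(self, n: int) -> None:
        self.macs += int(n)

    def __enter__(self) -> "MacCounter":
        global _MAC_COUNTER
        self._prev = _MAC_COUNTER
        _MAC_COUNTER = self
        return self

    def __exit__(self, *exc) -> None:
        global _MAC_COUNTER
        _MAC_COUNTER = self._prev


@contextlib.contextmanager
def no_grad():
    """Disable graph recording (inference / data paths)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
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
    """An ndarray with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # make ndarray <op> Tensor defer to the Tensor reflected operators
    __array_priority__ = 1000

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: tuple["Tensor", ...] = (),
        _backward: Callable[[np.ndarray], None] | None = None,
    ) -> None:
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = _parents if _GRAD_ENABLED else ()
        self._backward = _backward if _GRAD_ENABLED else None

    # ---- basic introspection -------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    @property
    def dtype(self):
        return self.data.dtype

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, dtype={self.dtype})"

    # ---- autograd ------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
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
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            if grad.dtype != self.data.dtype:
                grad = grad.astype(self.data.dtype)
            self.grad = grad
        else:
            self.grad = self.grad + grad

    def zero_grad(self) -> None:
        self.grad = None

    # ---- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def _bw(g):
            self._accumulate(_unbroadcast(g, self.shape))
            other._accumulate(_unbroadcast(g, other.shape))

        out._backward = _bw if _GRAD_ENABLED else None
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))
        out._backward = (lambda g: self._accumulate(-g)) if _GRAD_ENABLED else None
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def _bw(g):
            self._accumulate(_unbroadcast(g * other.data, self.shape))
            other._accumulate(_unbroadcast(g * self.data, other.shape))

        out._backward = _bw if _GRAD_ENABLED else None
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data, _parents=(self, other))

        def _bw(g):
            self._accumulate(_unbroadcast(g / other.data, self.shape))
            other._accumulate(
                _unbroadcast(-g * self.data / (other.data**2), other.shape)
            )

        out._backward = _bw if _GRAD_ENABLED else None
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        out = Tensor(self.data**exponent, _parents=(self,))

        def _bw(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1))

        out._backward = _bw if _GRAD_ENABLED else None
        return out

    def __matmul__(self, other):
        return matmul(self, other)

    # ---- shape ops -----------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), _parents=(self,))
        src_shape = self.shape
        out._backward = (
            (lambda g: self._accumulate(g.reshape(src_shape)))
            if _GRAD_ENABLED
            else None
        )
        return out

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        out = Tensor(self.data.transpose(axes), _parents=(self,))
        inv = tuple(np.argsort(axes))
        out._backward = (
            (lambda g: self._accumulate(g.transpose(inv))) if _GRAD_ENABLED else None
        )
        return out

    def swapaxes(self, a: int, b: int) -> "Tensor":
        out = Tensor(self.data.swapaxes(a, b), _parents=(self,))
        out._backward = (
            (lambda g: self._accumulate(g.swapaxes(a, b))) if _GRAD_ENABLED else None
        )
        return out

    def __getitem__(self, idx) -> "Tensor":
        out = Tensor(self.data[idx], _parents=(self,))

        def _bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accumulate(full)

        out._backward = _bw if _GRAD_ENABLED else None
        return out

    # ---- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def _bw(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        out._backward = _bw if _GRAD_ENABLED else None
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int | None = None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.max(axis=axis, keepdims=keepdims)
        out = Tensor(out_data, _parents=(self,))

        def _bw(g):
            if axis is None:
                mask = self.data == out_data
                self._accumulate(g * mask / mask.sum())
                return
            expanded = out_data if keepdims else np.expand_dims(out_data, axis)
            ge = g if keepdims else np.expand_dims(g, axis)
            mask = self.data == expanded
            counts = mask.sum(axis=axis, keepdims=True)
            self._accumulate(ge * mask / counts)

        out._backward = _bw if _GRAD_ENABLED else None
        return out

    # ---- elementwise nonlinearities with closed-form grads -------------
    def exp(self) -> "Tensor":
        y = np.exp(self.data)
        out = Tensor(y, _parents=(self,))
        out._backward = (lambda g: self._accumulate(g * y)) if _GRAD_ENABLED else None
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), _parents=(self,))
        out._backward = (
            (lambda g: self._accumulate(g / self.data)) if _GRAD_ENABLED else None
        )
        return out

    def sqrt(self) -> "Tensor":
        y = np.sqrt(self.data)
        out = Tensor(y, _parents=(self,))
        out._backward = (
            (lambda g: self._accumulate(g * 0.5 / y)) if _GRAD_ENABLED else None
        )
        return out


class Parameter(Tensor):
    """A trainable tensor (leaf of the graph)."""

    def __init__(self, data) -> None:
        super().__init__(np.asarray(data), requires_grad=True)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


# ---------------------------------------------------------------------------
# free functions
# ---------------------------------------------------------------------------


def concatenate(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(
        np.concatenate([t.data for t in tensors], axis=axis), _parents=tuple(tensors)
    )
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def _bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accumulate(piece)

    out._backward = _bw if _GRAD_ENABLED else None
    return out


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors], axis=axis), _parents=tuple(tensors))

    def _bw(g):
        for i, t in enumerate(tensors):
            t._accumulate(np.take(g, i, axis=axis))

    out._backward = _bw if _GRAD_ENABLED else None
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    y = a.data @ b.data
    if _MAC_COUNTER is not None:
        k = a.data.shape[-1]
        _MAC_COUNTER.add(y.size * k)
    out = Tensor(y, _parents=(a, b))

    def _bw(g):
        ga = g @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ g
        a._accumulate(_unbroadcast(ga, a.shape))
        b._accumulate(_unbroadcast(gb, b.shape))

    out._backward = _bw if _GRAD_ENABLED else None
    return out


def sigmoid(x: Tensor) -> Tensor:
    x = as_tensor(x)
    y = _special.expit(x.data)
    out = Tensor(y, _parents=(x,))
    out._backward = (
        (lambda g: x._accumulate(g * y * (1.0 - y))) if _GRAD_ENABLED else None
    )
    return out


def relu(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = Tensor(np.maximum(x.data, 0.0), _parents=(x,))
    out._backward = (
        (lambda g: x._accumulate(g * (x.data > 0))) if _GRAD_ENABLED else None
    )
    return out


def elu(x: Tensor, alpha: float = 1.0) -> Tensor:
    x = as_tensor(x)
    neg = alpha * np.expm1(np.minimum(x.data, 0.0))
    y = np.where(x.data > 0, x.data, neg)
    out = Tensor(y, _parents=(x,))

    def _bw(g):
        x._accumulate(g * np.where(x.data > 0, 1.0, neg + alpha))

    out._backward = _bw if _GRAD_ENABLED else None
    return out


def erf(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = Tensor(_special.erf(x.data), _parents=(x,))

    def _bw(g):
        x._accumulate(g * (2.0 / math.sqrt(math.pi)) * np.exp(-x.data**2))

    out._backward = _bw if _GRAD_ENABLED else None
    return out


def gelu(x: Tensor) -> Tensor:
    """Exact (erf-based) Gaussian error linear unit."""
    x = as_tensor(x)
    cdf = 0.5 * (1.0 + _special.erf(x.data / math.sqrt(2.0)))
    y = x.data * cdf
    out = Tensor(y, _parents=(x,))

    def _bw(g):
        pdf = np.exp(-0.5 * x.data**2) / math.sqrt(2.0 * math.pi)
        x._accumulate(g * (cdf + x.data * pdf))

    out._backward = _bw if _GRAD_ENABLED else None
    return out


# ---------------------------------------------------------------------------
# spatial primitives
# ---------------------------------------------------------------------------


def layernorm(x: Tensor, weight: Tensor, bias: Tensor, axis: int, eps: float) -> Tensor:
    """Fused layer normalization over one axis with affine parameters.

    ``weight``/``bias`` must broadcast against ``x`` (e.g. ``(1, C, 1, 1)``
    for channel normalization of NCHW maps).
    """
    x, weight, bias = as_tensor(x), as_tensor(weight), as_tensor(bias)
    mu = x.data.mean(axis=axis, keepdims=True)
    xc = x.data - mu
    var = np.mean(xc * xc, axis=axis, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    y = xc * inv
    out = Tensor(y * weight.data + bias.data, _parents=(x, weight, bias))

    def _bw(g):
        weight._accumulate(_unbroadcast(g * y, weight.shape))
        bias._accumulate(_unbroadcast(g, bias.shape))
        gy = g * weight.data
        gx = (
            gy
            - gy.mean(axis=axis, keepdims=True)
            - y * np.mean(gy * y, axis=axis, keepdims=True)
        ) * inv
        x._accumulate(gx)

    out._backward = _bw if _GRAD_ENABLED else None
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Fused numerically-stable softmax along ``axis``."""
    x = as_tensor(x)
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    y = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(y, _parents=(x,))

    def _bw(g):
        x._accumulate((g - (g * y).sum(axis=axis, keepdims=True)) * y)

    out._backward = _bw if _GRAD_ENABLED else None
    return out


def _pad2d(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))


def conv2d(
    x: Tensor,
    weight: Tensor,
    bias: Tensor | None = None,
    stride: int = 1,
    padding: int = 0,
    groups: int = 1,
) -> Tensor:
    """2D cross-correlation on NCHW input via im2col.

    ``weight`` has shape (C_out, C_in // groups, kh, kw).  Depthwise
    convolution is ``groups == C_in`` with C_out == C_in.
    """
    x, weight = as_tensor(x), as_tensor(weight)
    B, Cin, H, W = x.shape
    Cout, Cin_g, kh, kw = weight.shape
    if Cin % groups or Cout % groups or Cin_g != Cin // groups:
        raise ValueError(
            f"channel/group mismatch: input {Cin} channels, weight expects "
            f"{Cin_g}×{groups} (groups={groups})"
        )
    xp = _pad2d(x.data, padding)
    Hp, Wp = xp.shape[2:]
    OH = (Hp - kh) // stride + 1
    OW = (Wp - kw) // stride + 1
    if OH <= 0 or OW <= 0:
        raise ValueError(f"kernel {kh}x{kw} does not fit input {H}x{W} (pad {padding})")
    # (B, Cin, OH, OW, kh, kw) strided view — no copy yet
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    if _MAC_COUNTER is not None:
        _MAC_COUNTER.add(B * OH * OW * Cout * Cin_g * kh * kw)

    depthwise = groups == Cin and Cout == Cin
    if depthwise:
        winv = win.reshape(B, Cin, OH, OW, kh * kw)  # view (last axes contiguous)
        wflat = weight.data.reshape(Cin, kh * kw)
        y = np.einsum("bcxyk,ck->bcxy", winv, wflat)
        cols = None
    else:
        if groups == 1:
            cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(
                B * OH * OW, Cin * kh * kw
            )
            y = (
                (cols @ weight.data.reshape(Cout, -1).T)
                .reshape(B, OH, OW, Cout)
                .transpose(0, 3, 1, 2)
            )
        else:
            cols = (
                win.reshape(B, groups, Cin_g, OH, OW, kh, kw)
                .transpose(1, 0, 3, 4, 2, 5, 6)
                .reshape(groups, B * OH * OW, Cin_g * kh * kw)
            )
            wmat = weight.data.reshape(groups, Cout // groups, Cin_g * kh * kw)
            y = (
                np.matmul(cols, wmat.swapaxes(-1, -2))
                .reshape(groups, B, OH, OW, Cout // groups)
                .transpose(1, 0, 4, 2, 3)
                .reshape(B, Cout, OH, OW)
            )
    if bias is not None:
        y = y + bias.data.reshape(1, Cout, 1, 1)
    parents = (x, weight) if bias is None else (x, weight, bias)
    out = Tensor(y, _parents=parents)

    def _col2im(gcols_flat) -> np.ndarray:
        """Scatter (B, Cin, OH, OW, kh, kw) patch grads back to the input."""
        gxp = np.zeros((B, Cin, Hp, Wp), dtype=gcols_flat.dtype)
        for i in range(kh):
            for j in range(kw):
                gxp[
                    :, :, i : i + OH * stride : stride, j : j + OW * stride : stride
                ] += gcols_flat[:, :, :, :, i, j]
        if padding:
            gxp = gxp[:, :, padding:-padding, padding:-padding]
        return gxp

    def _bw(g):
        if depthwise:
            winv = win.reshape(B, Cin, OH, OW, kh * kw)
            gw = np.einsum("bcxy,bcxyk->ck", g, winv)
            weight._accumulate(gw.reshape(weight.shape))
            gcols = g[..., None, None] * weight.data.reshape(1, Cin, 1, 1, kh, kw)
            x._accumulate(_col2im(gcols))
        elif groups == 1:
            gf = g.transpose(0, 2, 3, 1).reshape(B * OH * OW, Cout)
            weight._accumulate((gf.T @ cols).reshape(weight.shape))
            gcols = (gf @ weight.data.reshape(Cout, -1)).reshape(
                B, OH, OW, Cin, kh, kw
            ).transpose(0, 3, 1, 2, 4, 5)
            x._accumulate(_col2im(gcols))
        else:
            wmat = weight.data.reshape(groups, Cout // groups, Cin_g * kh * kw)
            gf = (
                g.reshape(B, groups, Cout // groups, OH, OW)
                .transpose(1, 0, 3, 4, 2)
                .reshape(groups, B * OH * OW, Cout // groups)
            )
            weight._accumulate(
                np.matmul(gf.swapaxes(-1, -2), cols).reshape(weight.shape)
            )
            gcols = (
                np.matmul(gf, wmat)
                .reshape(groups, B, OH, OW, Cin_g, kh, kw)
                .transpose(1, 0, 4, 2, 3, 5, 6)
                .reshape(B, Cin, OH, OW, kh, kw)
            )
            x._accumulate(_col2im(gcols))
        if bias is not None:
            bias._accumulate(g.sum(axis=(0, 2, 3)))

    out._backward = _bw if _GRAD_ENABLED else None
    return out


def max_pool2d(x: Tensor, kernel: int = 3, stride: int = 2, padding: int = 1) -> Tensor:
    x = as_tensor(x)
    B, C, H, W = x.shape
    xp = np.pad(
        x.data,
        ((0, 0), (0, 0), (padding, padding), (padding, padding)),
        constant_values=-np.inf,
    )
    Hp, Wp = xp.shape[2:]
    OH = (Hp - kernel) // stride + 1
    OW = (Wp - kernel) // stride + 1
    win = sliding_window_view(xp, (kernel, kernel), axis=(2, 3))[:, :, ::stride, ::stride]
    flat = win.reshape(B, C, OH, OW, kernel * kernel)
    idx = flat.argmax(axis=-1)
    y = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
    out = Tensor(y, _parents=(x,))

    def _bw(g):
        gxp = np.zeros((B, C, Hp, Wp), dtype=g.dtype)
        oh, ow = np.meshgrid(np.arange(OH), np.arange(OW), indexing="ij")
        rows = oh[None, None] * stride + idx // kernel
        cols_ = ow[None, None] * stride + idx % kernel
        bb, cc = np.meshgrid(np.arange(B), np.arange(C), indexing="ij")
        np.add.at(
            gxp,
            (bb[..., None, None], cc[..., None, None], rows, cols_),
            g,
        )
        if padding:
            gxp = gxp[:, :, padding:-padding, padding:-padding]
        x._accumulate(gxp)

    out._backward = _bw if _GRAD_ENABLED else None
    return out


def upsample_nearest2x(x: Tensor) -> Tensor:
    x = as_tensor(x)
    B, C, H, W = x.shape
    y = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)
    out = Tensor(y, _parents=(x,))

    def _bw(g):
        x._accumulate(g.reshape(B, C, H, 2, W, 2).sum(axis=(3, 5)))

    out._backward = _bw if _GRAD_ENABLED else None
    return out
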