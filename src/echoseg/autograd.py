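"""Minimal reverse-mode automatic differentiation over numpy arrays.

This is the numerical substrate for the segmentation network: a ``Tensor``
records the operations applied to it and ``Tensor.backward`` accumulates
gradients by walking the tape in reverse topological order.  Only the
primitives the network needs are provided -- elementwise arithmetic,
reductions, 2-D convolution (stride 1, configurable asymmetric padding),
2x2 max pooling, 2x bilinear upsampling and channel concatenation.  All
primitives are validated against central finite differences in the test
suite.

Arrays are float64 throughout; spatial tensors follow the (N, C, H, W)
layout convention.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "Parameter", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus the backward closure that produced it."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # make `ndarray <op> Tensor` dispatch to our reflected operators instead
    # of numpy broadcasting the Tensor as an object scalar
    __array_ufunc__ = None
    __array_priority__ = 1000

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- graph construction -------------------------------------------------

    @staticmethod
    def _make(data, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- elementwise arithmetic ---------------------------------------------

    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out_data = self.data / other.data

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        return self._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, exponent: float):
        exponent = float(exponent)
        out_data = self.data**exponent

        def backward(g):
            return (g * exponent * self.data ** (exponent - 1.0),)

        return self._make(out_data, (self,), backward)

    # -- elementwise nonlinearities ------------------------------------------

    def relu(self) -> "Tensor":
        mask = self.data > 0.0
        return self._make(self.data * mask, (self,), lambda g: (g * mask,))

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))
        return self._make(s, (self,), lambda g: (g * s * (1.0 - s),))

    def log(self) -> "Tensor":
        return self._make(np.log(self.data), (self,), lambda g: (g / self.data,))

    def clip(self, lo: float, hi: float) -> "Tensor":
        """Clamp values; the gradient is passed through only inside [lo, hi]."""
        inside = (self.data >= lo) & (self.data <= hi)
        out_data = np.clip(self.data, lo, hi)
        return self._make(out_data, (self,), lambda g: (g * inside,))

    # -- reductions ----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.shape

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, shape).copy(),)
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            return (np.broadcast_to(gg, shape).copy(),)

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis, keepdims: bool = True) -> "Tensor":
        """Max over axes; gradient is split evenly among tied maxima."""
        axes = (axis,) if isinstance(axis, int) else tuple(axis)
        out_data = self.data.max(axis=axes, keepdims=True)
        mask = (self.data == out_data).astype(np.float64)
        mask /= mask.sum(axis=axes, keepdims=True)
        res = out_data if keepdims else out_data.squeeze(axes)

        def backward(g):
            gg = g if keepdims else np.expand_dims(g, axes)
            return (mask * gg,)

        return self._make(res, (self,), backward)

    # -- spatial primitives ---------------------------------------------------

    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None,
               padding: tuple[int, int, int, int] | None = None) -> "Tensor":
        """Stride-1 2-D cross-correlation on (N, C, H, W) input.

        ``padding`` is (top, bottom, left, right); defaults to "same" output
        size with the extra pixel of an even kernel placed top/left.
        """
        x = self.data
        w = weight.data
        if x.ndim != 4 or w.ndim != 4:
            raise ValueError("conv2d expects 4-D input and weight")
        n, c, h, wd = x.shape
        oc, ic, kh, kw = w.shape
        if ic != c:
            raise ValueError(
                f"conv2d channel mismatch: input has {c} channels, "
                f"weight expects {ic}"
            )
        if padding is None:
            padding = (kh // 2, (kh - 1) // 2, kw // 2, (kw - 1) // 2)
        pt, pb, pl, pr = padding
        xp = np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
        ho = h + pt + pb - kh + 1
        wo = wd + pl + pr - kw + 1

        cols = np.empty((n, c, kh, kw, ho, wo), dtype=np.float64)
        for i in range(kh):
            for j in range(kw):
                cols[:, :, i, j] = xp[:, :, i:i + ho, j:j + wo]
        cols_m = cols.reshape(n, c * kh * kw, ho * wo)
        w_m = w.reshape(oc, c * kh * kw)
        out = np.matmul(w_m, cols_m).reshape(n, oc, ho, wo)
        if bias is not None:
            out = out + bias.data.reshape(1, oc, 1, 1)

        parents = (self, weight) if bias is None else (self, weight, bias)

        def backward(g):
            gm = g.reshape(n, oc, ho * wo)
            grad_w = np.matmul(gm, cols_m.transpose(0, 2, 1)).sum(axis=0)
            grad_w = grad_w.reshape(oc, c, kh, kw)
            grad_cols = np.matmul(w_m.T, gm).reshape(n, c, kh, kw, ho, wo)
            grad_xp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    grad_xp[:, :, i:i + ho, j:j + wo] += grad_cols[:, :, i, j]
            grad_x = grad_xp[:, :, pt:pt + h, pl:pl + wd]
            if bias is None:
                return (grad_x, grad_w)
            return (grad_x, grad_w, g.sum(axis=(0, 2, 3)))

        return self._make(out, parents, backward)

    def maxpool2x2(self) -> "Tensor":
        x = self.data
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("maxpool2x2 requires even spatial dimensions")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

        def backward(g):
            grad_r = np.zeros_like(xr)
            np.put_along_axis(grad_r, idx[..., None], g[..., None], axis=-1)
            grad = grad_r.reshape(n, c, h // 2, w // 2, 2, 2)
            grad = grad.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)
            return (grad,)

        return self._make(out, (self,), backward)

    def upsample2x(self) -> "Tensor":
        """2x bilinear upsampling (half-pixel-centre convention)."""
        out = _up_axis(_up_axis(self.data, axis=-1), axis=-2)

        def backward(g):
            return (_up_axis_adjoint(_up_axis_adjoint(g, axis=-2), axis=-1),)

        return self._make(out, (self,), backward)

    # -- backward pass --------------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that requires no grad")
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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))

        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if g is None or not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = g.copy() if g.base is not None else g
                else:
                    parent.grad = parent.grad + g
            # free the tape as we go: intermediate grads and closures are not
            # needed once consumed, keeping peak memory proportional to one
            # forward pass (leaf tensors keep their accumulated grad)
            node.grad = None
            node._backward = None
            node._parents = ()


class Parameter(Tensor):
    """A trainable tensor (always tracks gradients)."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def concat(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    """Concatenate tensors along ``axis`` (channel axis by default)."""
    tensors = list(tensors)
    sizes = [t.shape[axis] for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(out_data, tensors, backward)


# -- bilinear upsampling helpers ---------------------------------------------


def _up_axis(x: np.ndarray, axis: int) -> np.ndarray:
    """Double the length of ``axis`` by bilinear interpolation.

    Output sample centres sit at input coordinates (i + 0.5) / 2 - 0.5, the
    standard half-pixel convention, so out[2m] = 0.75 x[m] + 0.25 x[m-1] and
    out[2m+1] = 0.75 x[m] + 0.25 x[m+1] with edge clamping.
    """
    x = np.moveaxis(x, axis, -1)
    left = np.concatenate([x[..., :1], x[..., :-1]], axis=-1)
    right = np.concatenate([x[..., 1:], x[..., -1:]], axis=-1)
    out = np.empty(x.shape[:-1] + (2 * x.shape[-1],), dtype=x.dtype)
    out[..., 0::2] = 0.75 * x + 0.25 * left
    out[..., 1::2] = 0.75 * x + 0.25 * right
    return np.moveaxis(out, -1, axis)


def _up_axis_adjoint(g: np.ndarray, axis: int) -> np.ndarray:
    """Exact adjoint of :func:`_up_axis` along ``axis``."""
    g = np.moveaxis(g, axis, -1)
    ge = g[..., 0::2]
    go = g[..., 1::2]
    gx = 0.75 * (ge + go)
    gx[..., :-1] += 0.25 * ge[..., 1:]
    gx[..., 0] += 0.25 * ge[..., 0]
    gx[..., 1:] += 0.25 * go[..., :-1]
    gx[..., -1] += 0.25 * go[..., -1]
    return np.moveaxis(gx, -1, axis)
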