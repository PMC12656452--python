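"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The network and all loss terms in this package are differentiated through
this module.  It implements a single :class:`Tensor` type carrying a value,
an accumulated gradient and a backward closure, plus the small set of
primitives the model needs (broadcasting arithmetic, matmul, reductions,
slicing, concatenation, a strided im2col convolution).  Gradients follow the
usual conventions: broadcasting sums the gradient back over expanded axes,
``max`` distributes the gradient over tied maxima, and ``detach`` cuts the
graph (used e.g. for the numerically stabilising shift inside softmax).
"""

from __future__ import annotations

from contextlib import contextmanager
from typing import Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "as_tensor", "concatenate", "conv2d", "no_grad"]

_GRAD_ENABLED = [True]


@contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum axes that were expanded from size 1
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An n-d array node in a dynamically built computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        if arr.dtype.kind != "f":
            arr = arr.astype(np.float64)
        self.data: np.ndarray = arr
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # ------------------------------------------------------------------ basics
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def __float__(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype)
        else:
            self.grad += g

    @staticmethod
    def _make(data, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED[-1] and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(parents)
            out._backward = backward
        return out

    # ---------------------------------------------------------------- backward
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this node; ``grad`` defaults to ones."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs can exceed the recursion limit
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -------------------------------------------------------------- arithmetic
    # Python/NumPy scalars take a fast path that preserves the array dtype
    # (wrapping them in a 0-d float64 Tensor would upcast float32 graphs).
    def __add__(self, other):
        if _is_scalar(other):
            c = other

            def backward(g):
                self._accumulate(g)

            return Tensor._make(self.data + c, (self,), backward)
        other = as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accumulate(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        if _is_scalar(other):
            return self + (-other)
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        if _is_scalar(other):
            return (-self) + other
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        if _is_scalar(other):
            c = other

            def backward(g):
                self._accumulate(g * c)

            return Tensor._make(self.data * c, (self,), backward)
        other = as_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if _is_scalar(other):
            return self * (1.0 / other)
        other = as_tensor(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.shape)
                )

        return Tensor._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        if not np.isscalar(p):
            raise TypeError("only scalar exponents are supported")
        out_data = self.data**p

        def backward(g):
            self._accumulate(g * p * self.data ** (p - 1))

        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = as_tensor(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                if other.data.ndim == 1:
                    self._accumulate(_unbroadcast(np.outer(g, other.data)
                                                  if self.data.ndim == 2 else g * other.data,
                                                  self.shape))
                else:
                    self._accumulate(
                        _unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.shape)
                    )
            if other.requires_grad:
                if self.data.ndim == 1:
                    other._accumulate(_unbroadcast(np.outer(self.data, g), other.shape))
                else:
                    other._accumulate(
                        _unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.shape)
                    )

        return Tensor._make(out_data, (self, other), backward)

    # ------------------------------------------------------------ element-wise
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accumulate(g * out_data)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            self._accumulate(g / self.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            self._accumulate(g / (2.0 * out_data))

        return Tensor._make(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            self._accumulate(g * mask)

        return Tensor._make(self.data * mask, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            self._accumulate(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), backward)

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy()
                                 if np.ndim(g) == 0 else np.full(self.shape, g))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(gg, self.shape).copy())

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def max(self, axis=None, keepdims: bool = False):
        out_data = self.data.max(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                mask = self.data == out_data
                self._accumulate(mask * (g / mask.sum()))
            else:
                expanded = self.data.max(axis=axis, keepdims=True)
                mask = self.data == expanded
                counts = mask.sum(axis=axis, keepdims=True)
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(mask * (gg / counts))

        return Tensor._make(out_data, (self,), backward)

    # ------------------------------------------------------------------ shapes
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old_shape = self.shape

        def backward(g):
            self._accumulate(g.reshape(old_shape))

        return Tensor._make(self.data.reshape(shape), (self,), backward)

    def flatten(self):
        return self.reshape(-1)

    def transpose(self, *axes):
        if not axes:
            axes = tuple(range(self.ndim))[::-1]
        elif len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            self._accumulate(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), backward)

    @property
    def T(self):
        return self.transpose()

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accumulate(full)

        return Tensor._make(out_data, (self,), backward)


def _is_scalar(x) -> bool:
    return isinstance(x, (int, float, np.integer, np.floating))


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concatenate(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor._make(out_data, tensors, backward)


def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int):
    """(B,C,Hp,Wp) -> (B, C*kh*kw, OH*OW) patches, C-contiguous."""
    sw = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    sw = sw[:, :, ::stride, ::stride]  # (B, C, OH, OW, kh, kw)
    b, c, oh, ow = sw.shape[:4]
    cols = sw.transpose(0, 1, 4, 5, 2, 3).reshape(b, c * kh * kw, oh * ow)
    return np.ascontiguousarray(cols), oh, ow


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """Batched 2-d cross-correlation: x (B,C,H,W), w (Cout,Cin,kh,kw)."""
    x, w = as_tensor(x), as_tensor(w)
    bsz, cin, _, _ = x.shape
    cout, cin_w, kh, kw = w.shape
    if cin != cin_w:
        raise ValueError(f"conv2d channel mismatch: input {cin}, weight {cin_w}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))) \
        if padding else x.data
    cols, oh, ow = _im2col(xp, kh, kw, stride)
    w2 = w.data.reshape(cout, -1)
    out_data = np.matmul(w2, cols).reshape(bsz, cout, oh, ow)
    parents = [x, w]
    if b is not None:
        b = as_tensor(b)
        out_data = out_data + b.data.reshape(1, cout, 1, 1)
        parents.append(b)

    def backward(g):
        g2 = g.reshape(bsz, cout, oh * ow)
        if b is not None and b.requires_grad:
            b._accumulate(g2.sum(axis=(0, 2)))
        if w.requires_grad:
            dw = np.einsum("bol,bkl->ok", g2, cols, optimize=True)
            w._accumulate(dw.reshape(w.shape))
        if x.requires_grad:
            dcols = np.matmul(w2.T, g2)  # (B, C*kh*kw, OH*OW)
            dcols = dcols.reshape(bsz, cin, kh, kw, oh, ow)
            dxp = np.zeros_like(xp)
            for u in range(kh):
                for v in range(kw):
                    dxp[:, :, u:u + stride * oh:stride,
                        v:v + stride * ow:stride] += dcols[:, :, u, v]
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x._accumulate(dxp)

    return Tensor._make(out_data, parents, backward)
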