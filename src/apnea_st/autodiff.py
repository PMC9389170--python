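"""A small reverse-mode automatic-differentiation engine on NumPy arrays.

Supports exactly the operations the CNN-BiGRU network needs: broadcasting
arithmetic, (batched) matrix multiplication, the sigmoid/tanh/ReLU
nonlinearities, softmax, same-padding 1-D convolution, non-overlapping max
pooling, slicing, stacking and reshaping.  Gradients are accumulated by a
topological-order sweep from a scalar loss.

All data is float64.  The engine is deliberately minimal — no graphs across
calls, no in-place ops, no higher-order derivatives.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

from .errors import ShapeError

__all__ = [
    "Tensor",
    "sigmoid",
    "tanh",
    "relu",
    "log",
    "exp",
    "clip",
    "softmax",
    "conv1d_same",
    "max_pool1d",
    "stack",
    "concat",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward_fn")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward_fn: Callable[[np.ndarray], tuple] | None = None,
    ):
        self.data = np.asarray(data, dtype=float)
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self.grad: np.ndarray | None = None
        self._parents = parents
        self._backward_fn = backward_fn

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph traversal ----------------------------------------------------

    def backward(self) -> None:
        """Accumulate gradients of this scalar into every reachable parent."""
        if self.data.size != 1:
            raise ShapeError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack_ = [self]
        while stack_:
            node = stack_[-1]
            if id(node) in seen:
                stack_.pop()
                continue
            pending = [p for p in node._parents if id(p) not in seen and p.requires_grad]
            if pending:
                stack_.extend(pending)
            else:
                seen.add(id(node))
                stack_.pop()
                if node.requires_grad:
                    topo.append(node)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward_fn is None or node.grad is None:
                continue
            for parent, g in zip(node._parents, node._backward_fn(node.grad)):
                if g is None or not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = np.zeros_like(parent.data)
                parent.grad += _unbroadcast(np.asarray(g), parent.data.shape)

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ---------------------------------------------------------

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._wrap(other)
        return Tensor(
            self.data + other.data,
            parents=(self, other),
            backward_fn=lambda g: (g, g),
        )

    __radd__ = __add__

    def __mul__(self, other):
        other = self._wrap(other)
        return Tensor(
            self.data * other.data,
            parents=(self, other),
            backward_fn=lambda g: (g * other.data, g * self.data),
        )

    __rmul__ = __mul__

    def __neg__(self):
        return Tensor(-self.data, parents=(self,), backward_fn=lambda g: (-g,))

    def __sub__(self, other):
        other = self._wrap(other)
        return Tensor(
            self.data - other.data,
            parents=(self, other),
            backward_fn=lambda g: (g, -g),
        )

    def __rsub__(self, other):
        return self._wrap(other) - self

    def __truediv__(self, other):
        other = self._wrap(other)
        return Tensor(
            self.data / other.data,
            parents=(self, other),
            backward_fn=lambda g: (g / other.data, -g * self.data / other.data**2),
        )

    def __matmul__(self, other):
        other = self._wrap(other)
        a, b = self.data, other.data
        try:
            out = a @ b
        except ValueError as exc:
            raise ShapeError(f"matmul shapes {a.shape} @ {b.shape}: {exc}") from exc

        def bwd(g):
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            return ga, gb

        return Tensor(out, parents=(self, other), backward_fn=bwd)

    def __getitem__(self, key):
        def bwd(g):
            gx = np.zeros_like(self.data)
            np.add.at(gx, key, g)
            return (gx,)

        return Tensor(self.data[key], parents=(self,), backward_fn=bwd)

    # -- reductions / shape -------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        def bwd(g):
            if axis is None:
                return (np.broadcast_to(g, self.data.shape).copy(),)
            gg = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(gg, self.data.shape).copy(),)

        return Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,), backward_fn=bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return Tensor(
            self.data.reshape(shape),
            parents=(self,),
            backward_fn=lambda g: (g.reshape(self.data.shape),),
        )

    def swapaxes(self, a: int, b: int):
        return Tensor(
            np.swapaxes(self.data, a, b),
            parents=(self,),
            backward_fn=lambda g: (np.swapaxes(g, a, b),),
        )


# ---------------------------------------------------------------------------
# elementwise nonlinearities
# ---------------------------------------------------------------------------


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    return Tensor(s, parents=(x,), backward_fn=lambda g: (g * s * (1 - s),))


def tanh(x: Tensor) -> Tensor:
    t = np.tanh(x.data)
    return Tensor(t, parents=(x,), backward_fn=lambda g: (g * (1 - t * t),))


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    return Tensor(x.data * mask, parents=(x,), backward_fn=lambda g: (g * mask,))


def log(x: Tensor) -> Tensor:
    return Tensor(np.log(x.data), parents=(x,), backward_fn=lambda g: (g / x.data,))


def exp(x: Tensor) -> Tensor:
    e = np.exp(x.data)
    return Tensor(e, parents=(x,), backward_fn=lambda g: (g * e,))


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    mask = (x.data > lo) & (x.data < hi)
    return Tensor(np.clip(x.data, lo, hi), parents=(x,), backward_fn=lambda g: (g * mask,))


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)

    def bwd(g):
        return (s * (g - (g * s).sum(axis=axis, keepdims=True)),)

    return Tensor(s, parents=(x,), backward_fn=bwd)


# ---------------------------------------------------------------------------
# structural ops
# ---------------------------------------------------------------------------


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = list(tensors)
    out = np.stack([t.data for t in tensors], axis=axis)

    def bwd(g):
        return tuple(np.take(g, i, axis=axis) for i in range(len(tensors)))

    return Tensor(out, parents=tuple(tensors), backward_fn=bwd)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = list(tensors)
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(out, parents=tuple(tensors), backward_fn=bwd)


# ---------------------------------------------------------------------------
# 1-D convolution and pooling (batch, time, channels)
# ---------------------------------------------------------------------------


def conv1d_same(x: Tensor, w: Tensor) -> Tensor:
    """Same-padding cross-correlation: x (B,T,Cin), w (L,Cin,Cout) -> (B,T,Cout)."""
    B, T, cin = x.data.shape
    L, cin_w, cout = w.data.shape
    if cin != cin_w:
        raise ShapeError(f"conv input has {cin} channels but filter expects {cin_w}")
    pad_l = (L - 1) // 2
    pad_r = L - 1 - pad_l
    xp = np.pad(x.data, ((0, 0), (pad_l, pad_r), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xp, L, axis=1)  # (B,T,Cin,L)
    out = np.einsum("btcl,lco->bto", win, w.data, optimize=True)

    def bwd(g):
        gw = np.einsum("btcl,bto->lco", win, g, optimize=True)
        gxp = np.zeros_like(xp)
        for l in range(L):
            gxp[:, l : l + T, :] += g @ w.data[l].T
        return gxp[:, pad_l : pad_l + T, :], gw

    return Tensor(out, parents=(x, w), backward_fn=bwd)


def max_pool1d(x: Tensor, k: int = 3) -> Tensor:
    """Non-overlapping max pooling along time; trailing remainder dropped."""
    if k < 1:
        raise ShapeError(f"pool size must be >= 1, got {k}")
    B, T, C = x.data.shape
    Tp = T // k
    if Tp < 1:
        raise ShapeError(f"sequence length {T} shorter than pool size {k}")
    xr = x.data[:, : Tp * k, :].reshape(B, Tp, k, C)
    idx = xr.argmax(axis=2)
    out = np.take_along_axis(xr, idx[:, :, None, :], axis=2)[:, :, 0, :]

    def bwd(g):
        gxr = np.zeros_like(xr)
        np.put_along_axis(gxr, idx[:, :, None, :], g[:, :, None, :], axis=2)
        gx = np.zeros_like(x.data)
        gx[:, : Tp * k, :] = gxr.reshape(B, Tp * k, C)
        return (gx,)

    return Tensor(out, parents=(x,), backward_fn=bwd)
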