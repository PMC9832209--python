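"""Minimal reverse-mode automatic differentiation over numpy arrays.

The model in this package is small (a few thousand parameters, full-batch
training on tens of subjects), so a compact tape-based engine over float64
numpy arrays is sufficient and keeps the whole computation deterministic on
one CPU. Only the operations the model needs are implemented: elementwise
arithmetic with broadcasting, (batched) matrix products, the activations
used by the network, reductions, stacking/slicing, and an integer-indexed
table lookup for the learned spatial-encoding vector.

Gradient correctness of every op is verified against central finite
differences in the test suite.
"""

from __future__ import annotations

from contextlib import contextmanager
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "default_dtype",
    "use_dtype",
    "Tensor",
    "as_tensor",
    "exp",
    "log",
    "tanh",
    "sigmoid",
    "elu",
    "clip",
    "tsum",
    "tmean",
    "matmul",
    "reshape",
    "stack",
    "unsqueeze",
    "squeeze",
    "take",
    "softmax",
    "Adam",
]


_DEFAULT_DTYPE = np.float64


def default_dtype() -> np.dtype:
    return _DEFAULT_DTYPE


@contextmanager
def use_dtype(dtype):
    """Temporarily set the dtype new tensors are created with.

    float64 is the default (op-level numerics); float32 halves memory
    traffic for full training runs, matching common deep-learning practice.
    """
    global _DEFAULT_DTYPE
    prev = _DEFAULT_DTYPE
    _DEFAULT_DTYPE = np.dtype(dtype)
    try:
        yield
    finally:
        _DEFAULT_DTYPE = prev


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
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus the tape metadata needed for backpropagation."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # make numpy defer `ndarray <op> Tensor` to the reflected Tensor ops
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=_DEFAULT_DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- introspection -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autodiff core -------------------------------------------------
    def _accumulate(self, grad: np.ndarray, fresh: bool = False) -> None:
        # ``fresh`` marks a newly allocated array the tensor may own
        # outright; otherwise copy on first write, since incoming grads
        # may alias upstream buffers
        if self.grad is None:
            self.grad = grad if fresh else np.array(grad)
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (default seed: ones)."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack_: list[tuple[Tensor, bool]] = [(self, False)]
        while stack_:
            node, expanded = stack_.pop()
            if id(node) in seen:
                continue
            if expanded:
                seen.add(id(node))
                topo.append(node)
                continue
            stack_.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack_.append((p, False))
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operators -----------------------------------------------------
    def __add__(self, other):
        return _binary(self, other, lambda a, b: a + b, _add_bw)

    __radd__ = __add__

    def __mul__(self, other):
        return _binary(self, other, lambda a, b: a * b, _mul_bw)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __truediv__(self, other):
        return _binary(self, other, lambda a, b: a / b, _div_bw)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return _getitem(self, idx)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _result(data: np.ndarray, parents: Sequence[Tensor], backward) -> Tensor:
    out = Tensor(data)
    grad_parents = tuple(p for p in parents if p.requires_grad)
    if grad_parents:
        out.requires_grad = True
        out._parents = grad_parents
        out._backward = backward
    return out


# ---------------------------------------------------------------------
# binary elementwise ops

def _binary(a, b, fwd, make_bw) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = fwd(a.data, b.data)
    return _result(data, (a, b), make_bw(a, b))


def _add_bw(a: Tensor, b: Tensor):
    def bw(g):
        if a.requires_grad:
            ga = _unbroadcast(g, a.data.shape)
            a._accumulate(ga, fresh=ga is not g)
        if b.requires_grad:
            gb = _unbroadcast(g, b.data.shape)
            b._accumulate(gb, fresh=gb is not g)

    return bw


def _mul_bw(a: Tensor, b: Tensor):
    def bw(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape), fresh=True)
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape), fresh=True)

    return bw


def _div_bw(a: Tensor, b: Tensor):
    def bw(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g / b.data, a.data.shape), fresh=True)
        if b.requires_grad:
            b._accumulate(
                _unbroadcast(-g * a.data / (b.data**2), b.data.shape), fresh=True
            )

    return bw


# ---------------------------------------------------------------------
# unary elementwise ops

def _unary(a, data: np.ndarray, dfun) -> Tensor:
    a = as_tensor(a)

    def bw(g):
        a._accumulate(g * dfun(), fresh=True)

    return _result(data, (a,), bw)


def exp(a) -> Tensor:
    a = as_tensor(a)
    out = np.exp(a.data)
    return _unary(a, out, lambda: out)


def log(a) -> Tensor:
    a = as_tensor(a)
    return _unary(a, np.log(a.data), lambda: 1.0 / a.data)


def tanh(a) -> Tensor:
    a = as_tensor(a)
    out = np.tanh(a.data)
    return _unary(a, out, lambda: 1.0 - out**2)


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    out = 1.0 / (1.0 + np.exp(-a.data))
    return _unary(a, out, lambda: out * (1.0 - out))


def elu(a, alpha: float = 1.0) -> Tensor:
    a = as_tensor(a)
    neg = alpha * (np.exp(np.minimum(a.data, 0.0)) - 1.0)
    out = np.where(a.data > 0, a.data, neg)
    return _unary(a, out, lambda: np.where(a.data > 0, 1.0, neg + alpha))


def clip(a, lo: float, hi: float) -> Tensor:
    """Clamp values; gradient passes through only inside the interval."""
    a = as_tensor(a)
    out = np.clip(a.data, lo, hi)
    inside = (a.data > lo) & (a.data < hi)
    return _unary(a, out, lambda: inside.astype(np.float64))


# ---------------------------------------------------------------------
# reductions

def tsum(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def bw(g):
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        a._accumulate(np.broadcast_to(g, a.data.shape).copy(), fresh=True)

    return _result(data, (a,), bw)


def tmean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    n = a.data.size if axis is None else a.data.shape[axis]
    return tsum(a, axis=axis, keepdims=keepdims) * (1.0 / n)


# ---------------------------------------------------------------------
# linear algebra / shape ops

def matmul(a, b) -> Tensor:
    """Matrix product with numpy batch broadcasting; operands must be >= 2-D."""
    a, b = as_tensor(a), as_tensor(b)
    if a.ndim < 2 or b.ndim < 2:
        raise ValueError("matmul requires operands with ndim >= 2")
    if b.ndim == 2 and a.ndim > 2:
        # batched-by-static product: one flat GEMM beats a matmul loop
        lead = a.data.shape[:-1]
        a2 = a.data.reshape(-1, a.data.shape[-1])
        data = (a2 @ b.data).reshape(lead + (b.data.shape[-1],))

        def bw(g):
            g2 = g.reshape(-1, g.shape[-1])
            if a.requires_grad:
                a._accumulate((g2 @ b.data.T).reshape(a.data.shape), fresh=True)
            if b.requires_grad:
                b._accumulate(a2.T @ g2, fresh=True)

        return _result(data, (a, b), bw)
    data = a.data @ b.data

    def bw(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a._accumulate(_unbroadcast(ga, a.data.shape), fresh=True)
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b._accumulate(_unbroadcast(gb, b.data.shape), fresh=True)

    return _result(data, (a, b), bw)


def _is_basic_index(idx) -> bool:
    items = idx if isinstance(idx, tuple) else (idx,)
    return all(isinstance(i, (int, slice, type(None), type(Ellipsis))) for i in items)


def _getitem(a: Tensor, idx) -> Tensor:
    data = a.data[idx]
    basic = _is_basic_index(idx)  # basic slices never repeat elements

    def bw(g):
        buf = np.zeros_like(a.data)
        if basic:
            buf[idx] += g
        else:
            np.add.at(buf, idx, g)
        a._accumulate(buf, fresh=True)

    return _result(data, (a,), bw)


def take(table, idx: np.ndarray) -> Tensor:
    """Integer-array lookup ``table[idx]`` for a 1-D table, with
    scatter-add backward (bincount: indices repeat heavily)."""
    table = as_tensor(table)
    idx = np.asarray(idx)
    data = table.data[idx]
    size = table.data.shape[0]

    def bw(g):
        buf = np.bincount(idx.ravel(), weights=g.ravel(), minlength=size)
        table._accumulate(buf.astype(table.data.dtype), fresh=True)

    return _result(data, (table,), bw)


def reshape(a, shape: tuple[int, ...]) -> Tensor:
    a = as_tensor(a)
    data = a.data.reshape(shape)

    def bw(g):
        a._accumulate(g.reshape(a.data.shape))

    return _result(data, (a,), bw)


def unsqueeze(a, axis: int) -> Tensor:
    a = as_tensor(a)
    data = np.expand_dims(a.data, axis)

    def bw(g):
        a._accumulate(g.reshape(a.data.shape))

    return _result(data, (a,), bw)


def squeeze(a, axis: int) -> Tensor:
    a = as_tensor(a)
    data = np.squeeze(a.data, axis)

    def bw(g):
        a._accumulate(g.reshape(a.data.shape))

    return _result(data, (a,), bw)


def stack(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    data = np.stack([t.data for t in ts], axis=axis)

    def bw(g):
        parts = np.split(g, len(ts), axis=axis)
        for t, piece in zip(ts, parts):
            if t.requires_grad:
                t._accumulate(piece.reshape(t.data.shape))

    return _result(data, ts, bw)


def softmax(x: Tensor, axis: int = -1, mask: np.ndarray | None = None) -> Tensor:
    """Numerically stable softmax; optional 0/1 support mask.

    Masked-out entries get exactly zero weight; rows must keep at least one
    unmasked entry (guaranteed upstream by the mandatory self-loop).
    """
    x = as_tensor(x)
    shift = np.max(x.data, axis=axis, keepdims=True)  # constant: no gradient
    e = exp(x - Tensor(shift))
    if mask is not None:
        e = e * Tensor(np.asarray(mask, dtype=_DEFAULT_DTYPE))
    return e / tsum(e, axis=axis, keepdims=True)


# ---------------------------------------------------------------------
# optimizer

class Adam:
    """Adam with L2 weight decay folded into the gradient (torch-style)."""

    def __init__(
        self,
        params: Sequence[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
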