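"""Compact reverse-mode automatic differentiation on numpy arrays.

The engine is a tape of :class:`Tensor` nodes.  Each non-leaf node stores its
parents and a vector-Jacobian-product (VJP) closure written *in terms of
Tensor operations*, so a backward pass run with ``create_graph=True`` builds a
new differentiable graph.  That is what the Wasserstein gradient penalty
needs: the gradient of the critic with respect to its input is itself part of
a loss that is differentiated again with respect to the critic parameters.

Only the operations required by the models in this package are implemented:
elementwise arithmetic, 2-D matrix product, reductions, reshaping, a handful
of activations, and gather/scatter along the last axis (the basis of the
im2col convolution).  Gradients of every operation are checked against
central finite differences in the test suite.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "no_grad",
    "grad_of",
    "tensor",
    "concat_last",
]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the block (fast constant math)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class Tensor:
    """A numpy array with an optional place in the autodiff tape."""

    __slots__ = ("data", "parents", "vjp", "requires_grad", "grad")

    def __init__(
        self,
        data,
        parents: Sequence["Tensor"] = (),
        vjp: Optional[Callable] = None,
        requires_grad: bool = False,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.parents = tuple(parents)
        self.vjp = vjp
        self.requires_grad = requires_grad
        self.grad: Optional[np.ndarray] = None

    # -- basic protocol ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- operators ---------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __radd__(self, other):
        return add(other, self)

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __mul__(self, other):
        return mul(self, other)

    def __rmul__(self, other):
        return mul(other, self)

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(other, self)

    def __neg__(self):
        return neg(self)

    def __pow__(self, exponent):
        return power(self, exponent)

    def __matmul__(self, other):
        return matmul(self, other)

    # -- convenience methods ------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean_(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def swapaxes(self, a, b):
        return swapaxes(self, a, b)

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        """Accumulate gradients into ``.grad`` of every reachable leaf."""
        grads = _backward(self, seed=grad, create_graph=False)
        for node, g in grads.items():
            if node.vjp is None and node.requires_grad:
                if node.grad is None:
                    node.grad = g.data.copy()
                else:
                    node.grad = node.grad + g.data


def tensor(data, requires_grad: bool = False) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float64), requires_grad=requires_grad)


def _coerce(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def _make(data: np.ndarray, parents: Sequence[Tensor], vjp: Callable) -> Tensor:
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        return Tensor(data, parents=parents, vjp=vjp, requires_grad=True)
    return Tensor(data)


# ---------------------------------------------------------------------------
# backward machinery
# ---------------------------------------------------------------------------


def _topo_order(root: Tensor) -> list:
    """Iterative post-order over the tape (graphs can be ~1e5 nodes deep)."""
    order: list = []
    seen = set()
    stack = [(root, False)]
    while stack:
        node, expanded = stack.pop()
        if expanded:
            order.append(node)
            continue
        if id(node) in seen or not node.requires_grad:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node.parents:
            if p.requires_grad and id(p) not in seen:
                stack.append((p, False))
    return order


def _backward(root: Tensor, seed=None, create_graph: bool = False) -> dict:
    if seed is None:
        seed_t = Tensor(np.ones_like(root.data))
    else:
        seed_t = _coerce(seed)
    grads: dict = {id(root): seed_t}
    by_id = {id(root): root}
    order = _topo_order(root)
    ctx = contextlib.nullcontext() if create_graph else no_grad()
    with ctx:
        for node in reversed(order):
            g = grads.pop(id(node), None)
            by_id.pop(id(node), None)
            if g is None:
                continue
            if node.vjp is None:
                grads[id(node)] = g
                by_id[id(node)] = node
                continue
            parent_grads = node.vjp(g)
            for p, pg in zip(node.parents, parent_grads):
                if pg is None or not p.requires_grad:
                    continue
                cur = grads.get(id(p))
                grads[id(p)] = pg if cur is None else cur + pg
                by_id[id(p)] = p
    return {by_id[k]: v for k, v in grads.items()}


def grad_of(
    output: Tensor,
    inputs: Sequence[Tensor],
    seed=None,
    create_graph: bool = False,
) -> list:
    """Gradients of ``output`` w.r.t. ``inputs`` as Tensors.

    With ``create_graph=True`` the returned tensors stay connected to the
    tape, so expressions built from them support a further backward pass.
    """
    grads = _backward(output, seed=seed, create_graph=create_graph)
    out = []
    for t in inputs:
        g = grads.get(t)
        if g is None:
            g = Tensor(np.zeros_like(t.data))
        out.append(g)
    return out


# ---------------------------------------------------------------------------
# broadcasting helper
# ---------------------------------------------------------------------------


def _unbroadcast(g: Tensor, shape: tuple) -> Tensor:
    if g.data.shape == shape:
        return g
    extra = g.data.ndim - len(shape)
    axes = list(range(extra))
    for i, s in enumerate(shape):
        if s == 1 and g.data.shape[i + extra] != 1:
            axes.append(i + extra)
    if axes:
        g = sum_(g, axis=tuple(axes), keepdims=False)
    if g.data.shape != shape:
        g = reshape(g, shape)
    return g


# ---------------------------------------------------------------------------
# elementwise arithmetic
# ---------------------------------------------------------------------------


def add(a, b) -> Tensor:
    a, b = _coerce(a), _coerce(b)

    def vjp(g):
        return _unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape)

    return _make(a.data + b.data, (a, b), vjp)


def sub(a, b) -> Tensor:
    a, b = _coerce(a), _coerce(b)

    def vjp(g):
        return _unbroadcast(g, a.data.shape), _unbroadcast(neg(g), b.data.shape)

    return _make(a.data - b.data, (a, b), vjp)


def mul(a, b) -> Tensor:
    a, b = _coerce(a), _coerce(b)

    def vjp(g):
        return _unbroadcast(g * b, a.data.shape), _unbroadcast(g * a, b.data.shape)

    return _make(a.data * b.data, (a, b), vjp)


def div(a, b) -> Tensor:
    a, b = _coerce(a), _coerce(b)

    def vjp(g):
        ga = _unbroadcast(g / b, a.data.shape)
        gb = _unbroadcast(neg(g * a / (b * b)), b.data.shape)
        return ga, gb

    return _make(a.data / b.data, (a, b), vjp)


def neg(a) -> Tensor:
    a = _coerce(a)

    def vjp(g):
        return (neg(g),)

    return _make(-a.data, (a,), vjp)


def power(a, exponent: float) -> Tensor:
    a = _coerce(a)
    exponent = float(exponent)

    def vjp(g):
        return (g * (exponent * power(a, exponent - 1.0)),)

    return _make(a.data ** exponent, (a,), vjp)


# ---------------------------------------------------------------------------
# linear algebra / shape
# ---------------------------------------------------------------------------


def matmul(a, b) -> Tensor:
    a, b = _coerce(a), _coerce(b)
    if a.data.ndim != 2 or b.data.ndim != 2:
        raise ValueError("matmul supports 2-D operands only")

    def vjp(g):
        return matmul(g, transpose2d(b)), matmul(transpose2d(a), g)

    return _make(a.data @ b.data, (a, b), vjp)


def transpose2d(a) -> Tensor:
    a = _coerce(a)

    def vjp(g):
        return (transpose2d(g),)

    return _make(a.data.T, (a,), vjp)


def reshape(a, shape) -> Tensor:
    a = _coerce(a)
    old = a.data.shape

    def vjp(g):
        return (reshape(g, old),)

    return _make(a.data.reshape(shape), (a,), vjp)


def swapaxes(a, ax1: int, ax2: int) -> Tensor:
    a = _coerce(a)

    def vjp(g):
        return (swapaxes(g, ax1, ax2),)

    return _make(np.swapaxes(a.data, ax1, ax2), (a,), vjp)


def broadcast_to(a, shape) -> Tensor:
    a = _coerce(a)
    old = a.data.shape

    def vjp(g):
        return (_unbroadcast(g, old),)

    return _make(np.broadcast_to(a.data, shape).copy(), (a,), vjp)


def sum_(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _coerce(a)
    old = a.data.shape

    def vjp(g):
        gd = g
        if not keepdims and axis is not None:
            ax = axis if isinstance(axis, tuple) else (axis,)
            shp = list(g.data.shape)
            for i in sorted(a2 % len(old) for a2 in ax):
                shp.insert(i, 1)
            gd = reshape(g, tuple(shp))
        elif not keepdims and axis is None:
            gd = reshape(g, (1,) * len(old))
        return (broadcast_to(gd, old),)

    return _make(a.data.sum(axis=axis, keepdims=keepdims), (a,), vjp)


def mean_(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _coerce(a)
    if axis is None:
        n = a.data.size
    else:
        ax = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.data.shape[i] for i in ax]))
    return sum_(a, axis=axis, keepdims=keepdims) * (1.0 / n)


# ---------------------------------------------------------------------------
# activations and pointwise nonlinearities
# ---------------------------------------------------------------------------


# NOTE: activation vjps recompute the forward value from the parent instead of
# closing over the result tensor: a closure capturing its own output would form
# a reference cycle per op, which accumulates faster than the cyclic collector
# reclaims it during long training loops.  Recomputation keeps the closures
# acyclic and the vjps differentiable (needed for the gradient penalty).


def tanh(a) -> Tensor:
    a = _coerce(a)

    def vjp(g):
        t = tanh(a)
        return (g * (1.0 - t * t),)

    return _make(np.tanh(a.data), (a,), vjp)


def sigmoid(a) -> Tensor:
    a = _coerce(a)

    def vjp(g):
        s = sigmoid(a)
        return (g * (s * (1.0 - s)),)

    return _make(1.0 / (1.0 + np.exp(-a.data)), (a,), vjp)


def exp(a) -> Tensor:
    a = _coerce(a)

    def vjp(g):
        return (g * exp(a),)

    return _make(np.exp(a.data), (a,), vjp)


def log(a) -> Tensor:
    a = _coerce(a)

    def vjp(g):
        return (g / a,)

    return _make(np.log(a.data), (a,), vjp)


def sqrt(a) -> Tensor:
    a = _coerce(a)

    def vjp(g):
        return (g * (0.5 / sqrt(a)),)

    return _make(np.sqrt(a.data), (a,), vjp)


def abs_(a) -> Tensor:
    a = _coerce(a)
    sign = np.sign(a.data)  # subgradient 0 at 0

    def vjp(g):
        return (g * sign,)

    return _make(np.abs(a.data), (a,), vjp)


def leaky_relu(a, slope: float = 0.2) -> Tensor:
    a = _coerce(a)
    mask = np.where(a.data > 0, 1.0, slope)

    def vjp(g):
        return (g * mask,)

    return _make(a.data * mask, (a,), vjp)


# ---------------------------------------------------------------------------
# gather / scatter along the last axis (conv building blocks)
# ---------------------------------------------------------------------------


def take_last(a, idx: np.ndarray) -> Tensor:
    """``a[..., idx]`` with integer index array ``idx``; linear in ``a``."""
    a = _coerce(a)
    idx = np.asarray(idx, dtype=np.intp)
    last = a.data.shape[-1]

    def vjp(g):
        return (put_last(g, idx, last),)

    return _make(a.data[..., idx], (a,), vjp)


def put_last(g, idx: np.ndarray, last: int) -> Tensor:
    """Adjoint of :func:`take_last`: scatter-add into a last axis of size ``last``."""
    g = _coerce(g)
    idx = np.asarray(idx, dtype=np.intp)

    def vjp(gg):
        return (take_last(gg, idx),)

    out = np.zeros(g.data.shape[: g.data.ndim - idx.ndim] + (last,), dtype=np.float64)
    np.add.at(out, (Ellipsis, idx), g.data)
    return _make(out, (g,), vjp)


def pad_last(a, left: int, right: int) -> Tensor:
    a = _coerce(a)
    last = a.data.shape[-1]

    def vjp(g):
        return (slice_last(g, left, left + last),)

    pads = [(0, 0)] * (a.data.ndim - 1) + [(left, right)]
    return _make(np.pad(a.data, pads), (a,), vjp)


def slice_last(a, start: int, stop: int) -> Tensor:
    a = _coerce(a)
    last = a.data.shape[-1]

    def vjp(g):
        return (pad_last(g, start, last - stop),)

    return _make(a.data[..., start:stop].copy(), (a,), vjp)


def concat_last(tensors: Sequence[Tensor]) -> Tensor:
    """Concatenate along the last axis (used rarely; built from pads)."""
    tensors = [_coerce(t) for t in tensors]
    sizes = [t.data.shape[-1] for t in tensors]
    total = int(np.sum(sizes))
    out = None
    offset = 0
    for t, s in zip(tensors, sizes):
        piece = pad_last(t, offset, total - offset - s)
        out = piece if out is None else out + piece
        offset += s
    return out
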