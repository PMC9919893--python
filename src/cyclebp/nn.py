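"""Neural-network layers and the Adam optimizer on top of :mod:`cyclebp.autodiff`.

Layers follow the common convention of mini-batch-first layouts:
``(batch, channels, time)`` for convolutional/normalization layers and
``(batch, time, features)`` inside the recurrent stack.

The GRU layer uses a hand-derived backward-through-time pass registered as a
single tape node.  This keeps generator training fast (one node per layer
instead of thousands of per-timestep nodes) at the cost of not supporting
second-order gradients through the GRU — which nothing in this package needs:
the gradient penalty differentiates only the convolutional critics, whose
layers are built from fully composable tape operations.
"""

from __future__ import annotations

from typing import Iterable, List, Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

try:  # JIT the recurrent loops when numba is present; numpy otherwise
    from numba import njit as _njit

    def _jit(fn):
        return _njit(cache=True, fastmath=True)(fn)

except ImportError:  # pragma: no cover - numba is an optional accelerator

    def _jit(fn):
        return fn


class Module:
    """Minimal parameter container with recursive traversal."""

    def parameters(self) -> List[Tensor]:
        params: List[Tensor] = []
        seen = set()

        def walk(obj):
            if isinstance(obj, Tensor):
                if obj.requires_grad and id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    walk(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    walk(v)

        walk(self)
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_arrays(self) -> List[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: Sequence[np.ndarray]) -> None:
        own = self.parameters()
        if len(own) != len(arrays):
            raise ValueError(f"expected {len(own)} arrays, got {len(arrays)}")
        for p, a in zip(own, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, dtype=np.float64).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _param(data: np.ndarray) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float64), requires_grad=True)


def _orthogonal(rng: np.random.Generator, rows: int, cols: int) -> np.ndarray:
    a = rng.standard_normal((max(rows, cols), min(rows, cols)))
    q, r = np.linalg.qr(a)
    q = q * np.sign(np.diag(r))
    q = q[:rows, :cols] if q.shape[0] >= rows else q.T[:rows, :cols]
    return q


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        self.in_features = in_features
        self.out_features = out_features
        self.weight = _param(rng.normal(0.0, 0.02, size=(in_features, out_features)))
        self.bias = _param(np.zeros(out_features))

    def forward(self, x: Tensor) -> Tensor:
        shape = x.shape
        flat = x.reshape((-1, self.in_features)) if x.ndim != 2 else x
        out = flat @ self.weight + self.bias
        if x.ndim != 2:
            out = out.reshape(shape[:-1] + (self.out_features,))
        return out


class Conv1d(Module):
    """1-D convolution via im2col; kernel/stride/padding fixed per layer."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int,
        stride: int,
        padding: int,
        rng: np.random.Generator,
    ):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.stride = stride
        self.padding = padding
        self.weight = _param(
            rng.normal(0.0, 0.02, size=(in_channels * kernel, out_channels))
        )
        self.bias = _param(np.zeros(out_channels))

    def out_length(self, length: int) -> int:
        eff = length + 2 * self.padding - self.kernel
        if eff < 0:
            raise ValueError(f"input of length {length} too short for kernel {self.kernel}")
        return eff // self.stride + 1

    def forward(self, x: Tensor) -> Tensor:
        b, c, length = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {c}")
        l_out = self.out_length(length)
        padded = ad.pad_last(x, self.padding, self.padding)
        starts = np.arange(l_out) * self.stride
        idx = starts[:, None] + np.arange(self.kernel)[None, :]  # (l_out, k)
        cols = ad.take_last(padded, idx)  # (b, c, l_out, k)
        cols = cols.swapaxes(1, 2)  # (b, l_out, c, k)
        cols = cols.reshape((b * l_out, c * self.kernel))
        out = cols @ self.weight + self.bias  # (b*l_out, c_out)
        out = out.reshape((b, l_out, self.out_channels)).swapaxes(1, 2)
        return out


class BatchNorm1d(Module):
    """Normalizes each channel over (batch, time) using batch statistics."""

    def __init__(self, channels: int, eps: float = 1e-5):
        self.channels = channels
        self.eps = eps
        self.gamma = _param(np.ones((1, channels, 1)))
        self.beta = _param(np.zeros((1, channels, 1)))

    def forward(self, x: Tensor) -> Tensor:
        m = x.mean(axis=(0, 2), keepdims=True)
        centered = x - m
        v = (centered * centered).mean(axis=(0, 2), keepdims=True)
        xhat = centered / ad.sqrt(v + self.eps)
        return self.gamma * xhat + self.beta


class InstanceNorm1d(Module):
    """Normalizes each (batch, channel) series over time."""

    def __init__(self, channels: int, eps: float = 1e-5):
        self.channels = channels
        self.eps = eps
        self.gamma = _param(np.ones((1, channels, 1)))
        self.beta = _param(np.zeros((1, channels, 1)))

    def forward(self, x: Tensor) -> Tensor:
        m = x.mean(axis=2, keepdims=True)
        centered = x - m
        v = (centered * centered).mean(axis=2, keepdims=True)
        xhat = centered / ad.sqrt(v + self.eps)
        return self.gamma * xhat + self.beta


@_jit
def _gru_forward_loop(gi, w_hh, b_hh):
    """Sequential gate recursion; returns caches needed for backward."""
    b, t, h3 = gi.shape
    h = h3 // 3
    hs = np.zeros((b, t, h))
    rs = np.zeros((b, t, h))
    zs = np.zeros((b, t, h))
    ns = np.zeros((b, t, h))
    ghn = np.zeros((b, t, h))
    h_prevs = np.zeros((b, t, h))
    h_prev = np.zeros((b, h))
    for j in range(t):
        h_prevs[:, j] = h_prev
        gh = h_prev @ w_hh + b_hh
        r = 1.0 / (1.0 + np.exp(-(gi[:, j, :h] + gh[:, :h])))
        z = 1.0 / (1.0 + np.exp(-(gi[:, j, h : 2 * h] + gh[:, h : 2 * h])))
        ghn_j = gh[:, 2 * h :]
        n = np.tanh(gi[:, j, 2 * h :] + r * ghn_j)
        h_prev = (1.0 - z) * n + z * h_prev
        hs[:, j] = h_prev
        rs[:, j] = r
        zs[:, j] = z
        ns[:, j] = n
        ghn[:, j] = ghn_j
    return hs, rs, zs, ns, ghn, h_prevs


@_jit
def _gru_backward_loop(gd, rs, zs, ns, ghn, h_prevs, w_hh_t):
    """Backward through time: upstream grads -> pre-activation gate grads."""
    b, t, h = gd.shape
    d_gi = np.zeros((b, t, 3 * h))
    d_gh = np.zeros((b, t, 3 * h))
    dh = np.zeros((b, h))
    for j in range(t - 1, -1, -1):
        dh = dh + gd[:, j]
        r = rs[:, j]
        z = zs[:, j]
        n = ns[:, j]
        hp = h_prevs[:, j]
        dn = dh * (1.0 - z)
        dz = dh * (hp - n)
        dan = dn * (1.0 - n * n)
        daz = dz * z * (1.0 - z)
        dr = dan * ghn[:, j]
        dar = dr * r * (1.0 - r)
        d_gi[:, j, :h] = dar
        d_gi[:, j, h : 2 * h] = daz
        d_gi[:, j, 2 * h :] = dan
        d_gh[:, j, :h] = dar
        d_gh[:, j, h : 2 * h] = daz
        d_gh[:, j, 2 * h :] = dan * r
        dh = dh * z + np.ascontiguousarray(d_gh[:, j]) @ w_hh_t
    return d_gi, d_gh


class GRULayer(Module):
    """Single GRU layer, batch-first ``(B, T, in) -> (B, T, hidden)``.

    Gate order (r, z, n) and the separate hidden bias on the candidate gate
    follow the widespread convention:

        r_t = sigmoid(x_t Wir + h Whr + bir + bhr)
        z_t = sigmoid(x_t Wiz + h Whz + biz + bhz)
        n_t = tanh(x_t Win + bin + r_t * (h Whn + bhn))
        h_t = (1 - z_t) * n_t + z_t * h_{t-1}

    The initial hidden state is zero and is reset for every window.
    """

    def __init__(self, in_features: int, hidden: int, rng: np.random.Generator):
        self.in_features = in_features
        self.hidden = hidden
        h = hidden
        # input weights at the standard recurrent scale 1/sqrt(H): the tiny
        # GAN-conv initialization leaves the state input-blind (the recurrence
        # contracts to a fixed point and the output flattens)
        bound = 1.0 / np.sqrt(h)
        self.w_ih = _param(rng.uniform(-bound, bound, size=(in_features, 3 * h)))
        w_hh = np.concatenate([_orthogonal(rng, h, h) for _ in range(3)], axis=1)
        self.w_hh = _param(w_hh)
        self.b_ih = _param(np.zeros(3 * h))
        self.b_hh = _param(np.zeros(3 * h))

    def forward(self, x: Tensor) -> Tensor:
        if x.ndim != 3 or x.shape[2] != self.in_features:
            raise ValueError(
                f"GRU expects (B, T, {self.in_features}), got {x.shape}"
            )
        b, t, _ = x.shape
        h = self.hidden
        xd = x.data
        w_ih, w_hh = self.w_ih.data, self.w_hh.data
        b_ih, b_hh = self.b_ih.data, self.b_hh.data

        gi = xd.reshape(b * t, -1) @ w_ih + b_ih
        gi = np.ascontiguousarray(gi.reshape(b, t, 3 * h))

        hs, rs, zs, ns, ghn, h_prevs = _gru_forward_loop(gi, w_hh, b_hh)

        def vjp(g):
            gd = np.ascontiguousarray(g.data)
            w_hh_t = np.ascontiguousarray(w_hh.T)
            d_gi, d_gh = _gru_backward_loop(gd, rs, zs, ns, ghn, h_prevs, w_hh_t)
            d_gi2 = d_gi.reshape(b * t, 3 * h)
            d_gh2 = d_gh.reshape(b * t, 3 * h)
            dx = (d_gi2 @ w_ih.T).reshape(b, t, -1)
            dw_ih = xd.reshape(b * t, -1).T @ d_gi2
            dw_hh = h_prevs.reshape(b * t, h).T @ d_gh2
            db_ih = d_gi2.sum(axis=0)
            db_hh = d_gh2.sum(axis=0)
            return (
                Tensor(dx),
                Tensor(dw_ih),
                Tensor(dw_hh),
                Tensor(db_ih),
                Tensor(db_hh),
            )

        parents = (x, self.w_ih, self.w_hh, self.b_ih, self.b_hh)
        if any(p.requires_grad for p in parents):
            return Tensor(hs, parents=parents, vjp=vjp, requires_grad=True)
        return Tensor(hs)


class Adam:
    """Adam optimizer over a fixed parameter list."""

    def __init__(
        self,
        params: Iterable[Tensor],
        lr: float = 1e-4,
        betas: tuple = (0.5, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1.0 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1.0 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
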