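"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Only the operations the network architectures in this package need are
implemented: dense matmul, broadcasting add/mul, gather/segment reductions
for message passing on graphs, the usual pointwise nonlinearities, layer /
batch normalization, 1-D convolution, and a fused softmax cross-entropy.
Everything runs in float64; graphs here are small enough that CPU BLAS is
the only kernel required.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "take_rows",
    "segment_sum",
    "segment_mean",
    "segment_softmax",
    "leaky_relu",
    "relu",
    "elu",
    "layer_norm",
    "batch_norm",
    "conv1d",
    "dropout",
    "softmax_cross_entropy",
    "softmax",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple = ()
        self._backward = None

    # -- graph bookkeeping -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    def zero_grad(self):
        self.grad = None

    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.asarray(grad, dtype=np.float64)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    def _accum(self, grad: np.ndarray):
        if not self.requires_grad:
            return
        grad = _unbroadcast(grad, self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data + other.data

        def bwd(g):
            self._accum(g)
            other._accum(g)

        return Tensor._make(out_data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            self._accum(-g)

        return Tensor._make(-self.data, (self,), bwd)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data * other.data

        def bwd(g):
            self._accum(g * other.data)
            other._accum(g * self.data)

        return Tensor._make(out_data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, scalar: float):
        return self * (1.0 / float(scalar))

    def __matmul__(self, other: "Tensor"):
        out_data = self.data @ other.data

        def bwd(g):
            self._accum(g @ other.data.T)
            other._accum(self.data.T @ g)

        return Tensor._make(out_data, (self, other), bwd)

    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))

        return Tensor._make(out_data, (self,), bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    def reshape(self, *shape):
        orig = self.data.shape
        out_data = self.data.reshape(*shape)

        def bwd(g):
            self._accum(g.reshape(orig))

        return Tensor._make(out_data, (self,), bwd)

    @property
    def T(self):
        def bwd(g):
            self._accum(g.T)

        return Tensor._make(self.data.T, (self,), bwd)

    def narrow(self, start: int, stop: int):
        """Contiguous slice along axis 0."""
        out_data = self.data[start:stop]

        def bwd(g):
            full = np.zeros_like(self.data)
            full[start:stop] = g
            self._accum(full)

        return Tensor._make(out_data, (self,), bwd)


# -- structural ops ---------------------------------------------------------

def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    return Tensor._make(out_data, tensors, bwd)


def take_rows(t: Tensor, idx: np.ndarray) -> Tensor:
    """Gather rows (axis 0); the adjoint scatter-adds back."""
    idx = np.asarray(idx)
    out_data = t.data[idx]

    def bwd(g):
        full = np.zeros_like(t.data)
        np.add.at(full, idx, g)
        t._accum(full)

    return Tensor._make(out_data, (t,), bwd)


def segment_sum(t: Tensor, seg_ids: np.ndarray, n_segments: int) -> Tensor:
    """Sum rows of `t` grouped by `seg_ids` into `n_segments` output rows."""
    seg_ids = np.asarray(seg_ids)
    out_data = np.zeros((n_segments,) + t.data.shape[1:])
    np.add.at(out_data, seg_ids, t.data)

    def bwd(g):
        t._accum(g[seg_ids])

    return Tensor._make(out_data, (t,), bwd)


def segment_mean(t: Tensor, seg_ids: np.ndarray, n_segments: int) -> Tensor:
    seg_ids = np.asarray(seg_ids)
    counts = np.bincount(seg_ids, minlength=n_segments).astype(np.float64)
    counts = np.maximum(counts, 1.0)
    s = segment_sum(t, seg_ids, n_segments)
    return s * Tensor(1.0 / counts[:, None] if t.data.ndim > 1 else 1.0 / counts)


def segment_softmax(scores: Tensor, seg_ids: np.ndarray, n_segments: int) -> Tensor:
    """Softmax over groups of entries sharing a segment id.

    Used for attention-coefficient normalization over each node's incoming
    edges.  `scores` may be (E,) or (E, K) for K heads; segments are rows.
    Computed with per-segment max subtraction for overflow safety.
    """
    seg_ids = np.asarray(seg_ids)
    s = scores.data
    shape_tail = s.shape[1:]
    seg_max = np.full((n_segments,) + shape_tail, -np.inf)
    np.maximum.at(seg_max, seg_ids, s)
    ex = np.exp(s - seg_max[seg_ids])
    denom = np.zeros((n_segments,) + shape_tail)
    np.add.at(denom, seg_ids, ex)
    alpha = ex / denom[seg_ids]

    def bwd(g):
        # d e_i = alpha_i * (g_i - sum_j alpha_j g_j) within each segment
        dot = np.zeros((n_segments,) + shape_tail)
        np.add.at(dot, seg_ids, alpha * g)
        scores._accum(alpha * (g - dot[seg_ids]))

    return Tensor._make(alpha, (scores,), bwd)


# -- nonlinearities -----------------------------------------------------------

def leaky_relu(t: Tensor, negative_slope: float = 0.2) -> Tensor:
    pos = t.data > 0
    out_data = np.where(pos, t.data, negative_slope * t.data)

    def bwd(g):
        t._accum(np.where(pos, g, negative_slope * g))

    return Tensor._make(out_data, (t,), bwd)


def relu(t: Tensor) -> Tensor:
    pos = t.data > 0
    out_data = np.where(pos, t.data, 0.0)

    def bwd(g):
        t._accum(np.where(pos, g, 0.0))

    return Tensor._make(out_data, (t,), bwd)


def elu(t: Tensor, alpha: float = 1.0) -> Tensor:
    pos = t.data > 0
    expm1 = alpha * np.expm1(np.minimum(t.data, 0.0))
    out_data = np.where(pos, t.data, expm1)

    def bwd(g):
        t._accum(np.where(pos, g, g * (expm1 + alpha)))

    return Tensor._make(out_data, (t,), bwd)


# -- normalization -----------------------------------------------------------

def layer_norm(t: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize each row over its feature (last) axis, then scale and shift."""
    mu = t.data.mean(axis=-1, keepdims=True)
    var = t.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (t.data - mu) * inv
    out_data = gain.data * xhat + bias.data

    def bwd(g):
        gain._accum((g * xhat).sum(axis=tuple(range(g.ndim - 1))))
        bias._accum(g.sum(axis=tuple(range(g.ndim - 1))))
        gy = g * gain.data
        m1 = gy.mean(axis=-1, keepdims=True)
        m2 = (gy * xhat).mean(axis=-1, keepdims=True)
        t._accum((gy - m1 - xhat * m2) * inv)

    return Tensor._make(out_data, (t, gain, bias), bwd)


def batch_norm(t: Tensor, gain: Tensor, bias: Tensor, running: dict,
               training: bool, momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Batch normalization over (batch, channel, length): per-channel stats.

    `running` holds 'mean' and 'var' arrays of shape (C,), updated in place
    during training and used verbatim at inference.
    """
    axes = (0, 2)
    if training:
        mu = t.data.mean(axis=axes)
        var = t.data.var(axis=axes)
        running["mean"] = (1 - momentum) * running["mean"] + momentum * mu
        running["var"] = (1 - momentum) * running["var"] + momentum * var
    else:
        mu, var = running["mean"], running["var"]
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (t.data - mu[None, :, None]) * inv[None, :, None]
    out_data = gain.data[None, :, None] * xhat + bias.data[None, :, None]

    def bwd(g):
        gain._accum((g * xhat).sum(axis=axes))
        bias._accum(g.sum(axis=axes))
        gy = g * gain.data[None, :, None]
        if training:
            n = t.data.shape[0] * t.data.shape[2]
            m1 = gy.sum(axis=axes) / n
            m2 = (gy * xhat).sum(axis=axes) / n
            t._accum((gy - m1[None, :, None] - xhat * m2[None, :, None])
                     * inv[None, :, None])
        else:
            t._accum(gy * inv[None, :, None])

    return Tensor._make(out_data, (t, gain, bias), bwd)


# -- convolution --------------------------------------------------------------

def conv1d(t: Tensor, weight: Tensor, bias: Tensor, stride: int = 1) -> Tensor:
    """Valid 1-D convolution: (B, C_in, L) * (C_out, C_in, k) -> (B, C_out, L_out)."""
    B, C, L = t.data.shape
    O, _, k = weight.data.shape
    L_out = (L - k) // stride + 1
    idx = stride * np.arange(L_out)[:, None] + np.arange(k)[None, :]  # (L_out, k)
    patches = t.data[:, :, idx]                       # (B, C, L_out, k)
    cols = patches.transpose(0, 2, 1, 3).reshape(B * L_out, C * k)
    wmat = weight.data.reshape(O, C * k)
    out = (cols @ wmat.T).reshape(B, L_out, O).transpose(0, 2, 1) + bias.data[None, :, None]

    def bwd(g):
        gflat = g.transpose(0, 2, 1).reshape(B * L_out, O)
        weight._accum((gflat.T @ cols).reshape(O, C, k))
        bias._accum(g.sum(axis=(0, 2)))
        dcols = (gflat @ wmat).reshape(B, L_out, C, k).transpose(0, 2, 1, 3)
        dx = np.zeros_like(t.data)
        np.add.at(dx, (slice(None), slice(None), idx), dcols)
        t._accum(dx)

    return Tensor._make(out, (t, weight, bias), bwd)


# -- regularization / output ---------------------------------------------------

def dropout(t: Tensor, rate: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or rate <= 0.0:
        return t
    mask = (rng.random(t.data.shape) >= rate) / (1.0 - rate)
    return t * Tensor(mask)


def softmax(logits: np.ndarray) -> np.ndarray:
    """Numerically safe softmax over the last axis (plain ndarray helper)."""
    z = logits - logits.max(axis=-1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer `labels` under softmax(logits); fused
    log-sum-exp formulation so probabilities never underflow to zero."""
    labels = np.asarray(labels)
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=-1, keepdims=True))
    logp = z - lse
    n = len(labels)
    loss = -logp[np.arange(n), labels].mean()
    probs = np.exp(logp)

    def bwd(g):
        d = probs.copy()
        d[np.arange(n), labels] -= 1.0
        logits._accum(g * d / n)

    return Tensor._make(loss, (logits,), bwd)


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
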