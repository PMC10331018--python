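"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operations the bag classifier needs: 3x3 convolution,
batch normalization, 2x2 max pooling, linear maps, ReLU/sigmoid, softmax,
axis reductions and a numerically stable binary cross-entropy on logits,
plus an Adam optimizer.  Everything runs in float64; gradients of every
nontrivial op are verified against central finite differences in the test
suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "Parameter",
    "conv2d",
    "maxpool2x2",
    "batchnorm2d",
    "linear",
    "relu",
    "sigmoid",
    "softmax",
    "matmul",
    "dot",
    "getrow",
    "max_with_index",
    "bce_with_logits",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with a gradient and a backward closure."""

    __slots__ = ("value", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, value, requires_grad: bool = False):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple = ()
        self._backward = None

    # -- graph bookkeeping -------------------------------------------------
    @staticmethod
    def _make(value, parents, backward):
        out = Tensor(value)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.value)
        self.grad += g

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.value)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accum(np.asarray(grad, dtype=np.float64))
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    # -- shape ops ---------------------------------------------------------
    @property
    def shape(self):
        return self.value.shape

    def reshape(self, *shape):
        old = self.value.shape

        def bw(g):
            self._accum(g.reshape(old))

        return Tensor._make(self.value.reshape(*shape), (self,), bw)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.value.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.value.shape))

        return Tensor._make(self.value + other.value, (self, other), bw)

    __radd__ = __add__

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.value, self.value.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.value, other.value.shape))

        return Tensor._make(self.value * other.value, (self, other), bw)

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def sum(self, axis=None, keepdims=False):
        def bw(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.value.shape).copy()
                            if np.ndim(g) else np.full_like(self.value, g))
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.value.shape))

        return Tensor._make(self.value.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.value.size if axis is None else np.prod(
            [self.value.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, value):
        super().__init__(value, requires_grad=True)


# ---------------------------------------------------------------------------
# elementwise nonlinearities
# ---------------------------------------------------------------------------

def relu(x: Tensor) -> Tensor:
    mask = x.value > 0

    def bw(g):
        x._accum(g * mask)

    return Tensor._make(x.value * mask, (x,), bw)


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    e = np.exp(z[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def sigmoid(x: Tensor) -> Tensor:
    y = _sigmoid(x.value)

    def bw(g):
        x._accum(g * y * (1.0 - y))

    return Tensor._make(y, (x,), bw)


def softmax(x: Tensor) -> Tensor:
    """Softmax of a 1-D tensor, stabilized by max subtraction."""
    z = x.value - x.value.max()
    e = np.exp(z)
    y = e / e.sum()

    def bw(g):
        x._accum(y * (g - float(np.dot(g, y))))

    return Tensor._make(y, (x,), bw)


# ---------------------------------------------------------------------------
# linear algebra
# ---------------------------------------------------------------------------

def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Matrix product for (m,n)@(n,k), (m,n)@(n,) and (n,)@(n,k)."""
    av, bv = a.value, b.value

    def bw(g):
        if a.requires_grad:
            if bv.ndim == 1:
                ga = np.outer(g, bv) if av.ndim == 2 else g * bv
            else:
                ga = (g[None, :] if av.ndim == 1 else g) @ bv.T
                if av.ndim == 1:
                    ga = ga[0]
            a._accum(ga)
        if b.requires_grad:
            if av.ndim == 1:
                gb = np.outer(av, g) if bv.ndim == 2 else g * av
            else:
                gb = av.T @ (g[:, None] if bv.ndim == 1 else g)
                if bv.ndim == 1:
                    gb = gb[:, 0]
            b._accum(gb)

    return Tensor._make(av @ bv, (a, b), bw)


def dot(a: Tensor, b: Tensor) -> Tensor:
    return matmul(a, b)


def getrow(x: Tensor, i: int) -> Tensor:
    def bw(g):
        full = np.zeros_like(x.value)
        full[i] = g
        x._accum(full)

    return Tensor._make(x.value[i], (x,), bw)


def max_with_index(x: Tensor) -> tuple[Tensor, int]:
    """Max of a 1-D tensor; ties resolve to the lowest index."""
    i = int(np.argmax(x.value))

    def bw(g):
        full = np.zeros_like(x.value)
        full[i] = g
        x._accum(full)

    return Tensor._make(x.value[i], (x,), bw), i


def normalize_rows(x: Tensor, eps: float = 1e-12) -> Tensor:
    """L2-normalize each row of a 2-D tensor."""
    norms = np.sqrt((x.value ** 2).sum(axis=1, keepdims=True))
    norms = np.maximum(norms, eps)
    y = x.value / norms

    def bw(g):
        dot = (g * y).sum(axis=1, keepdims=True)
        x._accum((g - y * dot) / norms)

    return Tensor._make(y, (x,), bw)


def linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """x @ w.T (+ b); w has shape (out, in)."""
    wv = w.value

    def bw(g):
        g2 = g[None, :] if x.value.ndim == 1 else g
        x2 = x.value[None, :] if x.value.ndim == 1 else x.value
        if x.requires_grad:
            gx = g2 @ wv
            x._accum(gx[0] if x.value.ndim == 1 else gx)
        if w.requires_grad:
            w._accum(g2.T @ x2)
        if b is not None and b.requires_grad:
            b._accum(g2.sum(axis=0))

    out = x.value @ wv.T
    if b is not None:
        out = out + b.value
    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out, parents, bw)


# ---------------------------------------------------------------------------
# convolution / pooling / batch norm (NCHW)
# ---------------------------------------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, pad: int = 1) -> Tensor:
    """2-D cross-correlation, stride 1, via im2col."""
    xv, wv = x.value, w.value
    n, c, h, wd = xv.shape
    oc, _, k, _ = wv.shape
    xp = np.pad(xv, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho, wo = h + 2 * pad - k + 1, wd + 2 * pad - k + 1
    win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (n,c,ho,wo,k,k)
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n * ho * wo, c * k * k)
    out = cols @ wv.reshape(oc, -1).T
    if b is not None:
        out = out + b.value
    out = out.reshape(n, ho, wo, oc).transpose(0, 3, 1, 2)

    def bw(g):
        gmat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(-1, oc)
        if w.requires_grad:
            w._accum((gmat.T @ cols).reshape(wv.shape))
        if b is not None and b.requires_grad:
            b._accum(gmat.sum(axis=0))
        if x.requires_grad:
            dcols = (gmat @ wv.reshape(oc, -1)).reshape(n, ho, wo, c, k, k)
            dxp = np.zeros_like(xp)
            for ki in range(k):
                for kj in range(k):
                    dxp[:, :, ki:ki + ho, kj:kj + wo] += dcols[
                        :, :, :, :, ki, kj].transpose(0, 3, 1, 2)
            x._accum(dxp[:, :, pad:pad + h, pad:pad + wd]
                     if pad else dxp)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out, parents, bw)


def maxpool2x2(x: Tensor) -> Tensor:
    v = x.value
    n, c, h, w = v.shape
    h2, w2 = h // 2, w // 2
    r = v[:, :, :h2 * 2, :w2 * 2].reshape(n, c, h2, 2, w2, 2)
    r = np.ascontiguousarray(r.transpose(0, 1, 2, 4, 3, 5)).reshape(n, c, h2, w2, 4)
    idx = r.argmax(axis=-1)
    out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]

    def bw(g):
        dr = np.zeros((n, c, h2, w2, 4))
        np.put_along_axis(dr, idx[..., None], g[..., None], axis=-1)
        dv = dr.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, h2 * 2, w2 * 2)
        if (h2 * 2, w2 * 2) != (h, w):
            full = np.zeros_like(v)
            full[:, :, :h2 * 2, :w2 * 2] = dv
            dv = full
        x._accum(dv)

    return Tensor._make(out, (x,), bw)


def batchnorm2d(x: Tensor, gamma: Tensor, beta: Tensor, running: dict,
                training: bool, momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Batch normalization over (N,H,W) per channel.

    `running` holds the running mean/var, updated in place in training mode.
    """
    v = x.value
    axes = (0, 2, 3)
    gshape = (1, -1, 1, 1)
    if training:
        mu = v.mean(axis=axes)
        var = v.var(axis=axes)
        m = v.shape[0] * v.shape[2] * v.shape[3]
        running["mean"] = (1 - momentum) * running["mean"] + momentum * mu
        unbiased = var * m / max(m - 1, 1)
        running["var"] = (1 - momentum) * running["var"] + momentum * unbiased
    else:
        mu, var = running["mean"], running["var"]
    std = np.sqrt(var + eps)
    xhat = (v - mu.reshape(gshape)) / std.reshape(gshape)
    out = gamma.value.reshape(gshape) * xhat + beta.value.reshape(gshape)

    def bw(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=axes))
        if beta.requires_grad:
            beta._accum(g.sum(axis=axes))
        if x.requires_grad:
            gs = gamma.value.reshape(gshape) / std.reshape(gshape)
            if training:
                m = v.shape[0] * v.shape[2] * v.shape[3]
                gmean = g.mean(axis=axes).reshape(gshape)
                gxhat = (g * xhat).mean(axis=axes).reshape(gshape)
                x._accum(gs * (g - gmean - xhat * gxhat))
            else:
                x._accum(gs * g)

    return Tensor._make(out, (x, gamma, beta), bw)


def bce_with_logits(logit: Tensor, target: float) -> Tensor:
    """Binary cross-entropy of sigmoid(logit) against a 0/1 target (stable)."""
    z = float(logit.value)
    loss = max(z, 0.0) - z * target + np.log1p(np.exp(-abs(z)))

    p = float(_sigmoid(np.array([z]))[0])

    def bw(g):
        logit._accum(g * (p - target))

    return Tensor._make(loss, (logit,), bw)


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adam with optional L2 weight decay folded into the gradient."""

    def __init__(self, params: list[Parameter], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.value
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
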