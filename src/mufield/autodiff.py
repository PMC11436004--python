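"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The attenuation-field networks here are small (a few dense layers, learnable
hash tables, a shallow conv stack), so a compact tape-based engine is all
that is needed: each op records its parents and a closure that maps the
output gradient to parent-gradient contributions; :meth:`Tensor.backward`
walks the tape in reverse topological order.  Only gradients with respect to
*parameters* are ever needed — sample positions and encoding weights enter
the graph as constants — which keeps the op set small.

All training code uses float32; gradient checks in the test-suite run the
same ops in float64 against central finite differences.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "matmul",
    "relu",
    "softplus",
    "exp",
    "take_rows",
    "conv2d",
    "avg_pool2x2",
    "Adam",
]


class Tensor:
    """An array with an optional gradient tape behind it."""

    __slots__ = ("data", "grad", "requires_grad", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        # list of (parent Tensor, grad_fn: out_grad -> parent_grad_contribution)
        self._parents: list[tuple["Tensor", object]] = []

    # -- infrastructure -----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        # reverse topological order over the tape
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent, _ in node._parents:
                if id(parent) not in seen:
                    stack.append((parent, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(order):
            if node.grad is None:
                continue
            g = node.grad
            for parent, grad_fn in node._parents:
                contrib = grad_fn(g)
                if parent.grad is None:
                    parent.grad = contrib
                else:
                    parent.grad = parent.grad + contrib

    # -- helpers ------------------------------------------------------------

    def _track(self, out: "Tensor", *pairs) -> "Tensor":
        for parent, grad_fn in pairs:
            if parent.requires_grad or parent._parents:
                out._parents.append((parent, grad_fn))
        return out

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other):
        other = _as_tensor(other, self.data.dtype)
        out = Tensor(self.data + other.data)
        return self._track(
            out,
            (self, lambda g: _unbroadcast(g, self.data.shape)),
            (other, lambda g: _unbroadcast(g, other.data.shape)),
        )

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data)
        return self._track(out, (self, lambda g: -g))

    def __sub__(self, other):
        return self + (-_as_tensor(other, self.data.dtype))

    def __rsub__(self, other):
        return _as_tensor(other, self.data.dtype) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other, self.data.dtype)
        out = Tensor(self.data * other.data)
        return self._track(
            out,
            (self, lambda g: _unbroadcast(g * other.data, self.data.shape)),
            (other, lambda g: _unbroadcast(g * self.data, other.data.shape)),
        )

    __rmul__ = __mul__

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims))

        def grad_fn(g):
            if axis is None:
                return np.broadcast_to(g, self.data.shape).astype(self.data.dtype)
            gg = g if keepdims else np.expand_dims(g, axis)
            return np.broadcast_to(gg, self.data.shape).astype(self.data.dtype)

        return self._track(out, (self, grad_fn))

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape))
        return self._track(out, (self, lambda g: g.reshape(self.data.shape)))

    def transpose(self, *axes):
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(*axes))
        return self._track(out, (self, lambda g: g.transpose(*inv)))


def _as_tensor(x, dtype) -> Tensor:
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=dtype))


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum a gradient over the axes that were broadcast in the forward pass."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def concat(tensors, axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis))
    splits = np.cumsum([d.shape[axis] for d in datas])[:-1]

    def make_grad_fn(i):
        def grad_fn(g):
            return np.split(g, splits, axis=axis)[i]

        return grad_fn

    for i, t in enumerate(tensors):
        if t.requires_grad or t._parents:
            out._parents.append((t, make_grad_fn(i)))
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """2D matrix product (the only shape the networks need)."""
    out = Tensor(a.data @ b.data)
    return out._track(
        out,
        (a, lambda g: g @ b.data.T),
        (b, lambda g: a.data.T @ g),
    )


def affine(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Fused dense layer ``x @ w + b`` (one tape node instead of two)."""
    out = Tensor(x.data @ w.data + b.data)
    return out._track(
        out,
        (x, lambda g: g @ w.data.T),
        (w, lambda g: x.data.T @ g),
        (b, lambda g: g.sum(axis=0)),
    )


def relu(x: Tensor) -> Tensor:
    out = Tensor(np.maximum(x.data, 0))
    return x._track(out, (x, lambda g: g * (x.data > 0)))


def softplus(x: Tensor) -> Tensor:
    """Numerically stable log(1 + exp(x)); gradient is the logistic sigmoid."""
    d = x.data
    out_data = np.where(d > 30, d, np.log1p(np.exp(np.minimum(d, 30))))
    out = Tensor(out_data.astype(d.dtype))
    sig = 1.0 / (1.0 + np.exp(-np.clip(d, -60, 60)))
    return x._track(out, (x, lambda g: g * sig.astype(d.dtype)))


def exp(x: Tensor) -> Tensor:
    out = Tensor(np.exp(x.data))
    return x._track(out, (x, lambda g: g * out.data))


def take_rows(table: Tensor, indices: np.ndarray) -> Tensor:
    """Row gather (embedding lookup); backward scatter-adds into the table.

    The scatter uses per-column ``bincount`` which is far faster than
    ``np.add.at`` for the few-feature-wide tables used by hash encodings.
    """
    indices = np.asarray(indices)
    out = Tensor(table.data[indices])

    def grad_fn(g):
        gt = np.zeros_like(table.data)
        flat_idx = indices.reshape(-1)
        flat_g = g.reshape(-1, table.data.shape[1])
        for j in range(table.data.shape[1]):
            gt[:, j] = np.bincount(
                flat_idx, weights=flat_g[:, j], minlength=table.data.shape[0]
            )
        return gt.astype(table.data.dtype)

    return table._track(out, (table, grad_fn))


def gather_blend(table: Tensor, indices: np.ndarray, weights: np.ndarray) -> Tensor:
    """Fused embedding gather + weighted corner reduction.

    ``indices``/``weights`` have shape (n, L, K); rows are gathered from
    ``table`` (R, F) and reduced over the K axis:
    ``out[n, l, f] = sum_k w[n, l, k] * table[idx[n, l, k], f]``.
    Backward scatter-adds ``g * w`` into the touched rows only.
    """
    n, l, k = indices.shape
    f = table.data.shape[1]
    feats = table.data.take(indices.reshape(-1), axis=0).reshape(n, l, k, f)
    out = Tensor(np.einsum("nlkf,nlk->nlf", feats, weights, optimize=True))

    def grad_fn(g):
        contrib = (g[:, :, None, :] * weights[..., None]).reshape(-1, f)
        flat_idx = indices.reshape(-1)
        gt = np.zeros_like(table.data)
        for j in range(f):
            gt[:, j] = np.bincount(
                flat_idx, weights=contrib[:, j], minlength=table.data.shape[0]
            )
        return gt.astype(table.data.dtype)

    return table._track(out, (table, grad_fn))


def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """(N, C, H, W) with same-padding -> (N*H*W, C*kh*kw) patches."""
    n, c, h, w = x.shape
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    # win: (N, C, H, W, kh, kw) -> (N, H, W, C, kh, kw)
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n * h * w, c * kh * kw
    )


def conv2d(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """Same-padded stride-1 2D convolution (cross-correlation).

    ``x``: (N, C_in, H, W); ``weight``: (C_out, C_in, kh, kw); ``bias``: (C_out,).
    """
    n, c_in, h, w = x.data.shape
    c_out, _, kh, kw = weight.data.shape
    cols = _im2col(x.data, kh, kw)  # (N*H*W, C_in*kh*kw)
    wmat = weight.data.reshape(c_out, -1)
    out_data = (cols @ wmat.T + bias.data).reshape(n, h, w, c_out).transpose(0, 3, 1, 2)
    out = Tensor(np.ascontiguousarray(out_data))

    def grad_x(g):
        gmat = g.transpose(0, 2, 3, 1).reshape(n * h * w, c_out)
        gcols = gmat @ wmat  # (N*H*W, C_in*kh*kw)
        gcols = gcols.reshape(n, h, w, c_in, kh, kw)
        ph, pw = kh // 2, kw // 2
        gx = np.zeros((n, c_in, h + 2 * ph, w + 2 * pw), dtype=x.data.dtype)
        for di in range(kh):
            for dj in range(kw):
                gx[:, :, di : di + h, dj : dj + w] += gcols[:, :, :, :, di, dj].transpose(
                    0, 3, 1, 2
                )
        return gx[:, :, ph : ph + h, pw : pw + w]

    def grad_w(g):
        gmat = g.transpose(0, 2, 3, 1).reshape(n * h * w, c_out)
        return (gmat.T @ cols).reshape(weight.data.shape).astype(weight.data.dtype)

    def grad_b(g):
        return g.sum(axis=(0, 2, 3)).astype(bias.data.dtype)

    return out._track(out, (x, grad_x), (weight, grad_w), (bias, grad_b))


def avg_pool2x2(x: Tensor) -> Tensor:
    """2x2 mean pooling on (N, C, H, W); H and W must be even."""
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"avg_pool2x2 needs even spatial dims, got {(h, w)}")
    out = Tensor(x.data.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5)))

    def grad_fn(g):
        return np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) * 0.25

    return x._track(out, (x, grad_fn))


class Adam:
    """Plain Adam over a list of parameter Tensors."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.beta1, self.beta2 = betas
        self.eps = float(eps)
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * (g * g)
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
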