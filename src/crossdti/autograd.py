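"""Reverse-mode automatic differentiation over numpy arrays.

A small define-by-run tape: every operation returns a :class:`Tensor` that
remembers its parents and a closure computing the parents' gradients from the
output gradient. ``Tensor.backward()`` walks the tape in reverse topological
order. Everything is float64; shapes follow numpy broadcasting rules.

The engine implements exactly the operations the interaction model needs
(lookups, 1-D convolution, masked softmax, layer normalisation, masked max
pooling, the usual pointwise maps) plus an Adam optimiser.
"""

from __future__ import annotations

import contextlib

import numpy as np

__all__ = [
    "Tensor",
    "default_dtype",
    "astensor",
    "parameter",
    "add",
    "mul",
    "matmul",
    "concat",
    "embedding",
    "conv1d",
    "relu",
    "leaky_relu",
    "sigmoid",
    "log",
    "clip",
    "dropout",
    "masked_softmax",
    "layer_norm",
    "masked_max",
    "sum_",
    "mean_",
    "Adam",
]


#: Float precision of all tensors. float64 is the default (and what the
#: finite-difference gradient checks assume); training loops may switch to
#: float32 for speed via :func:`default_dtype`.
_DTYPE = np.float64


@contextlib.contextmanager
def default_dtype(dtype):
    """Temporarily set the float dtype used by newly created tensors."""
    global _DTYPE
    prev = _DTYPE
    _DTYPE = np.dtype(dtype).type
    try:
        yield
    finally:
        _DTYPE = prev


class Tensor:
    """A numpy array with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward_fn",
                 "_grad_borrowed")

    def __init__(self, data, requires_grad=False, parents=(), backward_fn=None):
        self.data = np.asarray(data, dtype=_DTYPE)
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents
        )
        self.grad = None
        self._grad_borrowed = False
        self._parents = tuple(parents) if self.requires_grad else ()
        self._backward_fn = backward_fn if self.requires_grad else None

    # -- introspection -----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self):
        return float(self.data)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- autodiff ----------------------------------------------------------
    def backward(self, grad=None):
        """Accumulate gradients of ``self`` w.r.t. every reachable parameter."""
        if not self.requires_grad:
            raise ValueError("backward() on a tensor that requires no grad")
        if grad is None:
            if self.data.size != 1:
                raise ValueError("grad must be supplied for non-scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward_fn is None or node.grad is None:
                continue
            grads = node._backward_fn(node.grad)
            for parent, g in zip(node._parents, grads):
                if g is None or not parent.requires_grad:
                    continue
                # first contribution is kept by reference (copy-on-write on
                # the next accumulation), since backward closures hand out
                # fresh arrays or read-only views of finished gradients
                if parent.grad is None:
                    parent.grad = np.asarray(g)
                    parent._grad_borrowed = True
                elif parent._grad_borrowed:
                    parent.grad = parent.grad + g
                    parent._grad_borrowed = False
                else:
                    parent.grad += g

    def zero_grad(self):
        self.grad = None

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __neg__(self):
        return mul(self, -1.0)

    def __matmul__(self, other):
        return matmul(self, other)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def swapaxes(self, a, b):
        return swapaxes(self, a, b)


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def parameter(data) -> Tensor:
    return Tensor(data, requires_grad=True)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


# ---------------------------------------------------------------------------
# arithmetic
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    out = a.data + b.data

    def backward(g):
        return (_unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape))

    return Tensor(out, parents=(a, b), backward_fn=backward)


def mul(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    out = a.data * b.data

    def backward(g):
        return (
            _unbroadcast(g * b.data, a.data.shape),
            _unbroadcast(g * a.data, b.data.shape),
        )

    return Tensor(out, parents=(a, b), backward_fn=backward)


def matmul(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    out = a.data @ b.data

    def backward(g):
        ad, bd = a.data, b.data
        if ad.ndim == 1:
            ga = g @ np.swapaxes(bd, -1, -2) if bd.ndim > 1 else g * bd
        else:
            ga = g @ np.swapaxes(bd, -1, -2)
        gb = np.swapaxes(ad, -1, -2) @ g if ad.ndim > 1 else np.outer(ad, g)
        return (_unbroadcast(ga, ad.shape), _unbroadcast(gb, bd.shape))

    return Tensor(out, parents=(a, b), backward_fn=backward)


def reshape(t, shape) -> Tensor:
    t = astensor(t)
    out = t.data.reshape(shape)

    def backward(g):
        return (g.reshape(t.data.shape),)

    return Tensor(out, parents=(t,), backward_fn=backward)


def swapaxes(t, a, b) -> Tensor:
    t = astensor(t)
    out = np.swapaxes(t.data, a, b)

    def backward(g):
        return (np.swapaxes(g, a, b),)

    return Tensor(out, parents=(t,), backward_fn=backward)


def concat(tensors, axis=0) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(out, parents=tuple(tensors), backward_fn=backward)


# ---------------------------------------------------------------------------
# lookups and convolution
# ---------------------------------------------------------------------------

def embedding(table, indices) -> Tensor:
    """Row lookup ``table[indices]``; equivalent to one-hot matmul."""
    table = astensor(table)
    idx = np.asarray(indices, dtype=np.intp)
    out = table.data[idx]

    def backward(g):
        gt = np.zeros_like(table.data)
        np.add.at(gt, idx.ravel(), g.reshape(-1, table.data.shape[-1]))
        return (gt,)

    return Tensor(out, parents=(table,), backward_fn=backward)


def _windows(x: np.ndarray, k: int) -> np.ndarray:
    # x: (B, L, C) -> (B, L-k+1, C, k)
    return np.lib.stride_tricks.sliding_window_view(x, k, axis=1)


def conv1d(x, w, b=None, padding="same") -> Tensor:
    """1-D convolution along axis 1.

    x: (B, L, C_in); w: (K, C_in, C_out); b: (C_out,) or None.
    ``same`` keeps length L (zero padding, stride 1); ``valid`` yields L-K+1.
    """
    x, w = astensor(x), astensor(w)
    b = astensor(b) if b is not None else None
    k = w.data.shape[0]
    if padding == "same":
        left = (k - 1) // 2
        right = k - 1 - left
    elif padding == "valid":
        left = right = 0
        if x.data.shape[1] < k:
            raise ValueError(
                f"sequence length {x.data.shape[1]} shorter than kernel {k} "
                "with valid padding"
            )
    else:  # pragma: no cover
        raise ValueError(f"unknown padding mode {padding!r}")
    xp = np.pad(x.data, ((0, 0), (left, right), (0, 0)))
    win = _windows(xp, k)  # (B, Lout, C_in, K)
    out = np.einsum("blck,kco->blo", win, w.data, optimize=True)
    if b is not None:
        out = out + b.data

    def backward(g):
        gw = np.einsum("blck,blo->kco", win, g, optimize=True)
        gb = g.sum(axis=(0, 1)) if b is not None else None
        # full correlation of g with the flipped kernel gives grad w.r.t. xp
        gp = np.pad(g, ((0, 0), (k - 1, k - 1), (0, 0)))
        wf = w.data[::-1]  # (K, C_in, C_out)
        gwin = _windows(gp, k)  # (B, Lp, C_out, K)
        gxp = np.einsum("blok,kco->blc", gwin, wf, optimize=True)
        lp = xp.shape[1]
        gx = gxp[:, left : lp - right if right else lp]
        grads = [gx, gw]
        if b is not None:
            grads.append(gb)
        return tuple(grads)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor(out, parents=parents, backward_fn=backward)


# ---------------------------------------------------------------------------
# pointwise nonlinearities
# ---------------------------------------------------------------------------

def relu(t) -> Tensor:
    t = astensor(t)
    out = np.maximum(t.data, 0.0)

    def backward(g):
        return (g * (t.data > 0.0),)

    return Tensor(out, parents=(t,), backward_fn=backward)


def leaky_relu(t, slope=0.01) -> Tensor:
    t = astensor(t)
    out = np.where(t.data > 0.0, t.data, slope * t.data)

    def backward(g):
        return (g * np.where(t.data > 0.0, 1.0, slope),)

    return Tensor(out, parents=(t,), backward_fn=backward)


def sigmoid(t) -> Tensor:
    t = astensor(t)
    out = 1.0 / (1.0 + np.exp(-t.data))

    def backward(g):
        return (g * out * (1.0 - out),)

    return Tensor(out, parents=(t,), backward_fn=backward)


def log(t) -> Tensor:
    t = astensor(t)
    out = np.log(t.data)

    def backward(g):
        return (g / t.data,)

    return Tensor(out, parents=(t,), backward_fn=backward)


def clip(t, lo, hi) -> Tensor:
    t = astensor(t)
    out = np.clip(t.data, lo, hi)
    inside = (t.data > lo) & (t.data < hi)

    def backward(g):
        return (g * inside,)

    return Tensor(out, parents=(t,), backward_fn=backward)


def dropout(t, rate, rng, training) -> Tensor:
    """Inverted dropout; identity when not training or rate == 0."""
    t = astensor(t)
    if not training or rate == 0.0:
        return t
    keep = rng.random(t.data.shape) >= rate
    scale = 1.0 / (1.0 - rate)
    out = t.data * keep * scale

    def backward(g):
        return (g * keep * scale,)

    return Tensor(out, parents=(t,), backward_fn=backward)


# ---------------------------------------------------------------------------
# structured ops
# ---------------------------------------------------------------------------

def masked_softmax(t, mask=None) -> Tensor:
    """Softmax over the last axis; positions with ``mask`` False get weight 0.

    Rows whose keys are all masked come out as all-zero (no convex weights
    exist for them); their gradient is zero as well.
    """
    t = astensor(t)
    z = t.data
    if mask is not None:
        mask = np.broadcast_to(np.asarray(mask, dtype=bool), z.shape)
        z = np.where(mask, z, -np.inf)
    m = z.max(axis=-1, keepdims=True)
    np.copyto(m, 0.0, where=~np.isfinite(m))  # rows with every key masked
    e = np.exp(z - m)  # exp(-inf) underflows cleanly to 0
    s = e.sum(axis=-1, keepdims=True)
    np.copyto(s, 1.0, where=s == 0.0)
    out = e
    out /= s

    def backward(g):
        dot = (g * out).sum(axis=-1, keepdims=True)
        return (out * (g - dot),)

    return Tensor(out, parents=(t,), backward_fn=backward)


def layer_norm(t, gain, bias, eps=1e-5) -> Tensor:
    """Per-row (last axis) normalisation with learned affine parameters."""
    t, gain, bias = astensor(t), astensor(gain), astensor(bias)
    x = t.data
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x - mu) * inv
    out = xhat * gain.data + bias.data

    def backward(g):
        n = x.shape[-1]
        gy = g * gain.data
        gx = inv * (gy - gy.mean(axis=-1, keepdims=True)
                    - xhat * (gy * xhat).mean(axis=-1, keepdims=True))
        ggain = _unbroadcast(g * xhat, gain.data.shape)
        gbias = _unbroadcast(g, bias.data.shape)
        return (gx, ggain, gbias)

    return Tensor(out, parents=(t, gain, bias), backward_fn=backward)


def masked_max(t, mask) -> Tensor:
    """Per-channel max over axis 1, ignoring masked positions.

    t: (B, L, C); mask: (B, L) boolean. Every row must keep at least one
    unmasked position.
    """
    t = astensor(t)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any(axis=1).all():
        raise ValueError("masked_max: some row has every position masked")
    z = np.where(mask[:, :, None], t.data, -np.inf)
    arg = z.argmax(axis=1)  # (B, C)
    b_idx = np.arange(z.shape[0])[:, None]
    c_idx = np.arange(z.shape[2])[None, :]
    out = t.data[b_idx, arg, c_idx]

    def backward(g):
        gx = np.zeros_like(t.data)
        np.add.at(gx, (b_idx, arg, c_idx), g)
        return (gx,)

    return Tensor(out, parents=(t,), backward_fn=backward)


def sum_(t, axis=None, keepdims=False) -> Tensor:
    t = astensor(t)
    out = t.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            return (np.broadcast_to(g, t.data.shape).copy(),)
        g2 = g if keepdims else np.expand_dims(g, axis)
        return (np.broadcast_to(g2, t.data.shape).copy(),)

    return Tensor(out, parents=(t,), backward_fn=backward)


def mean_(t, axis=None, keepdims=False) -> Tensor:
    t = astensor(t)
    n = t.data.size if axis is None else t.data.shape[axis]
    return mul(sum_(t, axis=axis, keepdims=keepdims), 1.0 / n)


# ---------------------------------------------------------------------------
# optimiser
# ---------------------------------------------------------------------------

class Adam:
    """Adam with the standard bias correction (β1=0.9, β2=0.999, ε=1e-8)."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
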