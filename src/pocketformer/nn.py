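"""Tape-based reverse-mode automatic differentiation over numpy arrays.

The model sizes used in this package (two transformer blocks, 64-dim atom
track, at most a few dozen atoms per graph) are small enough that plain
numpy on one thread is fast, fully deterministic, and bit-reproducible —
properties the training-determinism contract relies on.

Only the operations the encoder, heads, and losses need are implemented.
Gradients are validated against central finite differences in the test
suite.  A global ``no_grad`` switch disables tape construction on inference
paths.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

__all__ = [
    "Tensor", "Module", "AdamW", "no_grad", "backward",
    "add", "sub", "mul", "div", "matmul", "exp", "log", "sqrt", "abs_",
    "relu", "softplus", "softmax", "layer_norm", "embedding", "gather_rows",
    "concat", "transpose", "reshape", "stopgrad",
]

_GRAD_ENABLED = True


class no_grad:
    """Context manager that disables tape construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_vjp")

    def __init__(self, data, requires_grad=False):
        self.data = data if isinstance(data, np.ndarray) else np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents = ()
        self._vjp = None

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def item(self):
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(other, self)

    def __neg__(self):
        return mul(self, -1.0)

    def __matmul__(self, other):
        return matmul(self, other)

    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean_(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        return transpose(self, axes)

    def __getitem__(self, key):
        return getitem(self, key)


def _as_tensor(x, like=None):
    if isinstance(x, Tensor):
        return x
    dtype = like.data.dtype if isinstance(like, Tensor) else None
    return Tensor(np.asarray(x, dtype=dtype))


def _node(data, parents, vjp):
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._vjp = vjp
    return out


def _unbroadcast(g, shape):
    """Sum gradient ``g`` down to ``shape`` (reverse of numpy broadcasting)."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, (a, b) in enumerate(zip(g.shape, shape)) if b == 1 and a != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


def stopgrad(x):
    return Tensor(x.data if isinstance(x, Tensor) else np.asarray(x))


# ---------------------------------------------------------------------------
# elementwise / arithmetic
# ---------------------------------------------------------------------------

def add(a, b):
    a = _as_tensor(a, like=b if isinstance(b, Tensor) else None)
    b = _as_tensor(b, like=a)
    data = a.data + b.data

    def vjp(g):
        return _unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape)

    return _node(data, (a, b), vjp)


def sub(a, b):
    a = _as_tensor(a, like=b if isinstance(b, Tensor) else None)
    b = _as_tensor(b, like=a)
    data = a.data - b.data

    def vjp(g):
        return _unbroadcast(g, a.data.shape), _unbroadcast(-g, b.data.shape)

    return _node(data, (a, b), vjp)


def mul(a, b):
    a = _as_tensor(a, like=b if isinstance(b, Tensor) else None)
    b = _as_tensor(b, like=a)
    data = a.data * b.data

    def vjp(g):
        return (_unbroadcast(g * b.data, a.data.shape),
                _unbroadcast(g * a.data, b.data.shape))

    return _node(data, (a, b), vjp)


def div(a, b):
    a = _as_tensor(a, like=b if isinstance(b, Tensor) else None)
    b = _as_tensor(b, like=a)
    data = a.data / b.data

    def vjp(g):
        return (_unbroadcast(g / b.data, a.data.shape),
                _unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))

    return _node(data, (a, b), vjp)


def exp(a):
    data = np.exp(a.data)

    def vjp(g):
        return (g * data,)

    return _node(data, (a,), vjp)


def log(a):
    data = np.log(a.data)

    def vjp(g):
        return (g / a.data,)

    return _node(data, (a,), vjp)


def sqrt(a):
    data = np.sqrt(a.data)

    def vjp(g):
        return (g * (0.5 / data),)

    return _node(data, (a,), vjp)


def abs_(a):
    data = np.abs(a.data)

    def vjp(g):
        return (g * np.sign(a.data),)

    return _node(data, (a,), vjp)


def relu(a):
    data = np.maximum(a.data, 0)

    def vjp(g):
        return (g * (a.data > 0),)

    return _node(data, (a,), vjp)


def softplus(a):
    # log(1 + e^x) computed stably; derivative is the logistic function
    data = np.logaddexp(0.0, a.data).astype(a.data.dtype)

    def vjp(g):
        return (g * expit(a.data),)

    return _node(data, (a,), vjp)


# ---------------------------------------------------------------------------
# shape ops
# ---------------------------------------------------------------------------

def reshape(a, shape):
    orig = a.data.shape
    data = a.data.reshape(shape)

    def vjp(g):
        return (g.reshape(orig),)

    return _node(data, (a,), vjp)


def transpose(a, axes):
    axes = tuple(axes)
    data = a.data.transpose(axes)
    inv = tuple(np.argsort(axes))

    def vjp(g):
        return (g.transpose(inv),)

    return _node(data, (a,), vjp)


def concat(tensors, axis=0):
    tensors = list(tensors)
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def vjp(g):
        return tuple(np.split(g, splits, axis=axis))

    return _node(data, tuple(tensors), vjp)


# ---------------------------------------------------------------------------
# reductions
# ---------------------------------------------------------------------------

def sum_(a, axis=None, keepdims=False):
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def vjp(g):
        if axis is None:
            return (np.broadcast_to(g, a.data.shape).copy(),)
        g2 = g
        if not keepdims:
            g2 = np.expand_dims(g2, axis)
        return (np.broadcast_to(g2, a.data.shape).copy(),)

    return _node(data, (a,), vjp)


def mean_(a, axis=None, keepdims=False):
    data = a.data.mean(axis=axis, keepdims=keepdims)
    if axis is None:
        count = a.data.size
    else:
        count = a.data.shape[axis]

    def vjp(g):
        if axis is None:
            return (np.broadcast_to(g / count, a.data.shape).copy(),)
        g2 = g
        if not keepdims:
            g2 = np.expand_dims(g2, axis)
        return (np.broadcast_to(g2 / count, a.data.shape).copy(),)

    return _node(data, (a,), vjp)


# ---------------------------------------------------------------------------
# linear algebra / indexing
# ---------------------------------------------------------------------------

def matmul(a, b):
    """Matrix product.  Supports (..., n, m) @ (m, k) and equal-batch
    (..., n, m) @ (..., m, k)."""
    data = a.data @ b.data

    if b.data.ndim == 2:
        def vjp(g):
            ga = g @ b.data.T
            a2 = a.data.reshape(-1, a.data.shape[-1])
            g2 = g.reshape(-1, g.shape[-1])
            gb = a2.T @ g2
            return ga, gb
    else:
        if a.data.shape[:-2] != b.data.shape[:-2]:
            raise ValueError("batched matmul requires equal leading dims")

        def vjp(g):
            ga = g @ np.swapaxes(b.data, -1, -2)
            gb = np.swapaxes(a.data, -1, -2) @ g
            return ga, gb

    return _node(data, (a, b), vjp)


def getitem(x, key):
    """Basic indexing with scatter-add gradient."""
    data = x.data[key]

    def vjp(g):
        gx = np.zeros_like(x.data)
        gx[key] += g  # basic indexing: no repeated positions
        return (gx,)

    return _node(data, (x,), vjp)


def embedding(weight, idx):
    """Row lookup ``weight[idx]`` with scatter-add gradient."""
    idx = np.asarray(idx)
    data = weight.data[idx]

    def vjp(g):
        gw = np.zeros_like(weight.data)
        np.add.at(gw, idx, g)
        return (gw,)

    return _node(data, (weight,), vjp)


def gather_rows(x, idx):
    """``out[b] = x[b, idx[b]]`` for a (B, n, ...) tensor."""
    idx = np.asarray(idx)
    B = x.data.shape[0]
    ar = np.arange(B)
    data = x.data[ar, idx]

    def vjp(g):
        gx = np.zeros_like(x.data)
        np.add.at(gx, (ar, idx), g)
        return (gx,)

    return _node(data, (x,), vjp)


# ---------------------------------------------------------------------------
# composites
# ---------------------------------------------------------------------------

def softmax(x, axis=-1):
    """Numerically stable softmax (max subtracted as a constant shift)."""
    m = Tensor(np.max(x.data, axis=axis, keepdims=True))
    e = exp(sub(x, m))
    s = sum_(e, axis=axis, keepdims=True)
    return div(e, s)


def layer_norm(x, gain, bias, eps=1e-5):
    mu = mean_(x, axis=-1, keepdims=True)
    xc = sub(x, mu)
    var = mean_(mul(xc, xc), axis=-1, keepdims=True)
    inv = div(1.0, sqrt(add(var, eps)))
    return add(mul(mul(xc, inv), gain), bias)


# ---------------------------------------------------------------------------
# backward pass
# ---------------------------------------------------------------------------

def backward(t, grad=None):
    """Reverse-mode sweep from scalar (or tensor) ``t``."""
    if grad is None:
        grad = np.ones_like(t.data)
    topo = []
    seen = set()
    stack = [(t, False)]
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
    t.grad = grad
    for node in reversed(topo):
        if node._vjp is None or node.grad is None:
            continue
        grads = node._vjp(node.grad)
        for p, g in zip(node._parents, grads):
            if not p.requires_grad or g is None:
                continue
            g = np.asarray(g, dtype=p.data.dtype)
            if p.grad is None:
                p.grad = g
            else:
                p.grad = p.grad + g
        if node is not t:
            node.grad = None  # free intermediate memory


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

class Module:
    """Lightweight parameter container.

    Parameters are ``Tensor`` attributes with ``requires_grad=True``;
    ``parameters()`` returns them in a deterministic, insertion-ordered
    mapping keyed by attribute path, which the optimizer and checkpoint
    code rely on.
    """

    def parameters(self):
        out = {}
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad:
                out[name] = val
            elif isinstance(val, Module):
                for k, v in val.parameters().items():
                    out[f"{name}.{k}"] = v
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        for k, v in item.parameters().items():
                            out[f"{name}.{i}.{k}"] = v
        return out

    def zero_grad(self):
        for p in self.parameters().values():
            p.grad = None


def glorot(rng, shape, dtype):
    fan_in, fan_out = shape[0], shape[-1]
    std = np.sqrt(2.0 / (fan_in + fan_out))
    return Tensor(rng.normal(0.0, std, size=shape).astype(dtype), requires_grad=True)


def zeros_param(shape, dtype):
    return Tensor(np.zeros(shape, dtype=dtype), requires_grad=True)


def ones_param(shape, dtype):
    return Tensor(np.ones(shape, dtype=dtype), requires_grad=True)


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class AdamW:
    """AdamW with decoupled weight decay.

    ``no_decay`` is a predicate on the parameter name; matching parameters
    (normalization gains, biases, the contrastive temperature) are exempt
    from decay.  Parameters whose gradient is ``None`` after a step are
    left completely untouched (no moment update, no decay), so objective
    masking touches only reachable parameters.
    """

    def __init__(self, params, weight_decay=0.05, betas=(0.9, 0.999),
                 eps=1e-8, no_decay=None):
        self.params = dict(params)
        self.weight_decay = weight_decay
        self.betas = betas
        self.eps = eps
        self.no_decay = no_decay or (lambda name: False)
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in self.params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in self.params.items()}

    def step(self, lr):
        self.t += 1
        b1, b2 = self.betas
        c1 = 1.0 - b1 ** self.t
        c2 = 1.0 - b2 ** self.t
        for name, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad.astype(np.float64)
            m = self.m[name] = b1 * self.m[name] + (1 - b1) * g
            v = self.v[name] = b2 * self.v[name] + (1 - b2) * (g * g)
            update = (m / c1) / (np.sqrt(v / c2) + self.eps)
            new = p.data.astype(np.float64) - lr * update
            if self.weight_decay and not self.no_decay(name):
                new = new - lr * self.weight_decay * p.data.astype(np.float64)
            p.data = new.astype(p.data.dtype)

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None

    def state_dict(self):
        return {
            "t": self.t,
            "m": {k: v.copy() for k, v in self.m.items()},
            "v": {k: v.copy() for k, v in self.v.items()},
        }

    def load_state_dict(self, state):
        self.t = int(state["t"])
        for k in self.m:
            self.m[k] = np.asarray(state["m"][k]).copy()
            self.v[k] = np.asarray(state["v"][k]).copy()
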