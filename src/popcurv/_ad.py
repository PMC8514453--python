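"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations needed by the variational curvature fit and
the geodesic path optimizer: broadcasting elementwise arithmetic, the usual
transcendental functions, reductions, matmul/einsum, gather, logsumexp and
linear solves.  Every function dispatches: called on plain numpy arrays (or
scalars) it computes with numpy directly; called on at least one
:class:`Tensor` it records the operation on a tape for backpropagation.

This is intentionally small and has no notion of devices, dtypes other than
float64, or higher-order derivatives.  Gradient correctness is verified
against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "add", "sub", "mul", "div", "neg", "power", "exp", "log",
    "sqrt", "sin", "cos", "sinh", "cosh", "softplus", "tanh", "square",
    "sum", "mean", "matmul", "reshape", "transpose", "stack", "concatenate",
    "getitem", "logsumexp", "maximum", "minimum", "einsum2", "solve", "dot",
    "norm", "backward", "value",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` over axes that were broadcast from `shape`."""
    grad = np.asarray(grad, dtype=float)
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
    """Node in the autodiff graph wrapping a float64 numpy array."""

    __slots__ = ("value", "grad", "_parents", "_vjp", "requires_grad")

    def __init__(self, value, parents=(), vjp=None, requires_grad=False):
        self.value = np.asarray(value, dtype=float)
        self.grad = None
        self._parents = parents
        self._vjp = vjp  # callable(grad_out) -> tuple of parent grads
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.value.shape

    @property
    def ndim(self):
        return self.value.ndim

    # convenience operators
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
        return neg(self)

    def __pow__(self, p):
        return power(self, p)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def __matmul__(self, other):
        return matmul(self, other)


def value(x):
    """The numpy array behind `x` (identity for plain arrays)."""
    return x.value if isinstance(x, Tensor) else np.asarray(x, dtype=float)


def _is_t(*xs):
    return any(isinstance(x, Tensor) for x in xs)


def _wrap(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def backward(out: Tensor):
    """Backpropagate from scalar tensor `out`, filling `.grad` on leaves."""
    topo, seen = [], set()

    def visit(node):
        stack = [(node, False)]
        while stack:
            n, processed = stack.pop()
            if processed:
                topo.append(n)
                continue
            if id(n) in seen or not n.requires_grad:
                continue
            seen.add(id(n))
            stack.append((n, True))
            for p in n._parents:
                stack.append((p, False))

    visit(out)
    grads = {id(out): np.ones_like(out.value)}
    for node in reversed(topo):
        g = grads.pop(id(node), None)
        if g is None:
            continue
        if node._vjp is None:
            node.grad = g if node.grad is None else node.grad + g
            continue
        for parent, pg in zip(node._parents, node._vjp(g)):
            if pg is None or not parent.requires_grad:
                continue
            key = id(parent)
            if key in grads:
                grads[key] = grads[key] + pg
            else:
                grads[key] = pg


# ---------------------------------------------------------------- elementwise

def _binary(a, b, fwd, vjp_a, vjp_b):
    if not _is_t(a, b):
        return fwd(np.asarray(a, float), np.asarray(b, float))
    ta, tb = _wrap(a), _wrap(b)
    out = fwd(ta.value, tb.value)

    def vjp(g):
        ga = _unbroadcast(vjp_a(g, ta.value, tb.value, out), ta.shape) \
            if ta.requires_grad else None
        gb = _unbroadcast(vjp_b(g, ta.value, tb.value, out), tb.shape) \
            if tb.requires_grad else None
        return ga, gb

    return Tensor(out, (ta, tb), vjp)


def add(a, b):
    return _binary(a, b, np.add, lambda g, a, b, o: g, lambda g, a, b, o: g)


def sub(a, b):
    return _binary(a, b, np.subtract, lambda g, a, b, o: g, lambda g, a, b, o: -g)


def mul(a, b):
    return _binary(a, b, np.multiply,
                   lambda g, a, b, o: g * b, lambda g, a, b, o: g * a)


def div(a, b):
    return _binary(a, b, np.divide,
                   lambda g, a, b, o: g / b, lambda g, a, b, o: -g * a / b ** 2)


def _unary(x, fwd, vjp_fn):
    if not _is_t(x):
        return fwd(np.asarray(x, float))
    tx = _wrap(x)
    out = fwd(tx.value)
    return Tensor(out, (tx,), lambda g: (vjp_fn(g, tx.value, out),))


def neg(x):
    return _unary(x, np.negative, lambda g, x, o: -g)


def power(x, p):
    p = float(p)
    return _unary(x, lambda v: v ** p, lambda g, x, o: g * p * x ** (p - 1.0))


def square(x):
    return _unary(x, np.square, lambda g, x, o: 2.0 * g * x)


def exp(x):
    return _unary(x, np.exp, lambda g, x, o: g * o)


def log(x):
    return _unary(x, np.log, lambda g, x, o: g / x)


def sqrt(x):
    return _unary(x, np.sqrt, lambda g, x, o: 0.5 * g / o)


def sin(x):
    return _unary(x, np.sin, lambda g, x, o: g * np.cos(x))


def cos(x):
    return _unary(x, np.cos, lambda g, x, o: -g * np.sin(x))


def sinh(x):
    return _unary(x, np.sinh, lambda g, x, o: g * np.cosh(x))


def cosh(x):
    return _unary(x, np.cosh, lambda g, x, o: g * np.sinh(x))


def tanh(x):
    return _unary(x, np.tanh, lambda g, x, o: g * (1.0 - o ** 2))


def _softplus_np(v):
    # overflow-safe log(1 + e^v)
    return np.logaddexp(0.0, v)


def softplus(x):
    return _unary(x, _softplus_np,
                  lambda g, x, o: g / (1.0 + np.exp(-x)))


def maximum(a, b):
    return _binary(a, b, np.maximum,
                   lambda g, a, b, o: g * (a >= b),
                   lambda g, a, b, o: g * (b > a))


def minimum(a, b):
    return _binary(a, b, np.minimum,
                   lambda g, a, b, o: g * (a <= b),
                   lambda g, a, b, o: g * (b < a))


# ---------------------------------------------------------------- reductions

def sum(x, axis=None, keepdims=False):
    if not _is_t(x):
        return np.sum(np.asarray(x, float), axis=axis, keepdims=keepdims)
    tx = _wrap(x)
    out = np.sum(tx.value, axis=axis, keepdims=keepdims)

    def vjp(g):
        g = np.asarray(g, float)
        if axis is None:
            return (np.broadcast_to(g, tx.shape).copy(),)
        ax = axis if isinstance(axis, tuple) else (axis,)
        if not keepdims:
            g = np.expand_dims(g, ax)
        return (np.broadcast_to(g, tx.shape).copy(),)

    return Tensor(out, (tx,), vjp)


def mean(x, axis=None, keepdims=False):
    n = value(x).size if axis is None else np.prod(
        [value(x).shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
    return div(sum(x, axis=axis, keepdims=keepdims), float(n))


def logsumexp(x, axis, b=None):
    """log(sum(b * exp(x), axis)); `b` is an optional constant weight array."""
    xv = value(x)
    m = np.max(xv, axis=axis, keepdims=True)
    m = np.where(np.isfinite(m), m, 0.0)
    e = np.exp(xv - m)
    if b is not None:
        e = e * b
    s = np.sum(e, axis=axis)
    out = np.log(s) + np.squeeze(m, axis=axis)
    if not _is_t(x):
        return out
    tx = _wrap(x)

    def vjp(g):
        w = e / np.expand_dims(s, axis)
        return (np.expand_dims(np.asarray(g, float), axis) * w,)

    return Tensor(out, (tx,), vjp)


# ------------------------------------------------------------- shape & index

def reshape(x, shape):
    if not _is_t(x):
        return np.reshape(np.asarray(x, float), shape)
    tx = _wrap(x)
    return Tensor(np.reshape(tx.value, shape), (tx,),
                  lambda g: (np.reshape(g, tx.shape),))


def transpose(x, axes=None):
    if not _is_t(x):
        return np.transpose(np.asarray(x, float), axes)
    tx = _wrap(x)
    inv = None if axes is None else np.argsort(axes)
    return Tensor(np.transpose(tx.value, axes), (tx,),
                  lambda g: (np.transpose(g, inv),))


def getitem(x, idx):
    if not _is_t(x):
        return np.asarray(x, float)[idx]
    tx = _wrap(x)

    def vjp(g):
        out = np.zeros(tx.shape)
        np.add.at(out, idx, g)
        return (out,)

    return Tensor(tx.value[idx], (tx,), vjp)


def stack(xs, axis=0):
    if not _is_t(*xs):
        return np.stack([np.asarray(x, float) for x in xs], axis=axis)
    ts = [_wrap(x) for x in xs]
    out = np.stack([t.value for t in ts], axis=axis)

    def vjp(g):
        return tuple(np.take(g, i, axis=axis) for i in range(len(ts)))

    return Tensor(out, tuple(ts), vjp)


def concatenate(xs, axis=0):
    if not _is_t(*xs):
        return np.concatenate([np.asarray(x, float) for x in xs], axis=axis)
    ts = [_wrap(x) for x in xs]
    out = np.concatenate([t.value for t in ts], axis=axis)
    sizes = [t.shape[axis] for t in ts]
    splits = np.cumsum(sizes)[:-1]

    def vjp(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(out, tuple(ts), vjp)


# ------------------------------------------------------------- linear algebra

def matmul(a, b):
    if not _is_t(a, b):
        return np.asarray(a, float) @ np.asarray(b, float)
    ta, tb = _wrap(a), _wrap(b)
    out = ta.value @ tb.value

    def vjp(g):
        av, bv = ta.value, tb.value
        if av.ndim == 1 and bv.ndim == 1:
            return g * bv, g * av
        if av.ndim == 1:  # (k,) @ (..., k, n)
            ga = (g[..., None, :] * bv).sum(axis=-1)
            gb = av[:, None] * g[..., None, :]
            return _unbroadcast(ga, ta.shape), _unbroadcast(gb, tb.shape)
        if bv.ndim == 1:  # (..., m, k) @ (k,)
            ga = g[..., :, None] * bv
            gb = (g[..., :, None] * av).sum(axis=tuple(range(av.ndim - 1)))
            return _unbroadcast(ga, ta.shape), _unbroadcast(gb, tb.shape)
        ga = g @ np.swapaxes(bv, -1, -2)
        gb = np.swapaxes(av, -1, -2) @ g
        return _unbroadcast(ga, ta.shape), _unbroadcast(gb, tb.shape)

    return Tensor(out, (ta, tb), vjp)


def dot(a, b):
    """Inner product over the last axis (batched)."""
    return sum(mul(a, b), axis=-1)


def norm(x, axis=-1):
    return sqrt(sum(square(x), axis=axis))


def einsum2(spec: str, a, b):
    """Two-operand einsum with autodiff.

    Requires every index of each operand to appear in the other operand or in
    the output (no internal sums within one operand), which holds for all the
    contraction patterns this package uses.
    """
    if not _is_t(a, b):
        return np.einsum(spec, np.asarray(a, float), np.asarray(b, float))
    ta, tb = _wrap(a), _wrap(b)
    ins, out_spec = spec.split("->")
    sa, sb = ins.split(",")
    out = np.einsum(spec, ta.value, tb.value, optimize=True)

    def vjp(g):
        ga = np.einsum(f"{out_spec},{sb}->{sa}", g, tb.value,
                       optimize=True) if ta.requires_grad else None
        gb = np.einsum(f"{out_spec},{sa}->{sb}", g, ta.value,
                       optimize=True) if tb.requires_grad else None
        return ga, gb

    return Tensor(out, (ta, tb), vjp)


def _solve_np(a, b):
    if b.ndim == a.ndim - 1:  # batched vector rhs
        return np.linalg.solve(a, b[..., None])[..., 0]
    return np.linalg.solve(a, b)


def solve(a, b):
    """x = a^{-1} b for square `a`; b a vector or matrix (both batchable)."""
    if not _is_t(a, b):
        return _solve_np(np.asarray(a, float), np.asarray(b, float))
    ta, tb = _wrap(a), _wrap(b)
    x = _solve_np(ta.value, tb.value)

    def vjp(g):
        gb = _solve_np(np.swapaxes(ta.value, -1, -2), np.asarray(g, float))
        if x.ndim == ta.value.ndim - 1:  # vector rhs
            ga = -gb[..., :, None] * x[..., None, :]
        else:
            ga = -gb @ np.swapaxes(x, -1, -2)
        return (_unbroadcast(ga, ta.shape) if ta.requires_grad else None,
                _unbroadcast(gb, tb.shape) if tb.requires_grad else None)

    return Tensor(x, (ta, tb), vjp)
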