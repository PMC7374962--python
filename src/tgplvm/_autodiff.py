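"""Minimal reverse-mode automatic differentiation on numpy arrays.

The variational optimizer needs gradients of a Monte-Carlo ELBO that flows
through kernel evaluations, a Cholesky factorization and triangular solves.
This module provides exactly the operations that computation uses: a small
tape-based `Node` type with vector-Jacobian products for elementwise
arithmetic, broadcasting, reductions, matrix products, `cholesky` and
`solve_lower`.  All values are float64 ndarrays; graphs are DAGs built
eagerly and differentiated with :func:`backward`.

Every VJP is finite-difference checked in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import solve_triangular

__all__ = [
    "Node",
    "as_node",
    "backward",
    "grad",
    "abs_",
    "cholesky",
    "clip_min",
    "diag_embed",
    "diagonal",
    "exp",
    "log",
    "log1p",
    "matmul",
    "reshape",
    "solve_lower",
    "sqrt",
    "square",
    "sum_",
    "take_rows",
    "transpose",
    "tril",
]


class Node:
    """A value in the computation graph."""

    __slots__ = ("value", "_parents", "_vjps", "grad", "requires_grad")

    # make `ndarray <op> Node` dispatch to our reflected operators instead
    # of numpy broadcasting over an object array
    __array_ufunc__ = None

    def __init__(self, value, parents=(), vjps=(), requires_grad=False):
        self.value = np.asarray(value, dtype=float)
        self._parents = parents
        self._vjps = vjps
        self.grad = None
        # leaf constants default to False; op nodes inherit from parents so
        # backward() can skip gradient work into constant subgraphs
        self.requires_grad = requires_grad or any(
            p.requires_grad for p in parents
        )

    @property
    def shape(self):
        return self.value.shape

    @property
    def ndim(self):
        return self.value.ndim

    # -- operator sugar -------------------------------------------------
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

    def __pow__(self, exponent):
        return power(self, exponent)

    def __matmul__(self, other):
        return matmul(self, other)

    def __rmatmul__(self, other):
        return matmul(other, self)

    @property
    def T(self):
        return transpose(self)

    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis=axis, keepdims=keepdims)

    def __repr__(self):  # pragma: no cover
        return f"Node(shape={self.shape})"


def as_node(x) -> Node:
    return x if isinstance(x, Node) else Node(x)


def _unbroadcast(g, shape):
    """Sum gradient `g` down to broadcast source `shape`."""
    g = np.asarray(g, dtype=float)
    if g.shape == shape:
        return g
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g.reshape(shape)


def _identity(g):
    return g


# -- elementwise binary ops --------------------------------------------


def add(a, b):
    a, b = as_node(a), as_node(b)
    out = a.value + b.value
    vjp_a = _identity if a.value.shape == out.shape else (lambda g: _unbroadcast(g, a.shape))
    vjp_b = _identity if b.value.shape == out.shape else (lambda g: _unbroadcast(g, b.shape))
    return Node(out, (a, b), (vjp_a, vjp_b))


def sub(a, b):
    a, b = as_node(a), as_node(b)
    return Node(
        a.value - b.value,
        (a, b),
        (lambda g: _unbroadcast(g, a.shape), lambda g: _unbroadcast(-g, b.shape)),
    )


def mul(a, b):
    a, b = as_node(a), as_node(b)
    return Node(
        a.value * b.value,
        (a, b),
        (
            lambda g: _unbroadcast(g * b.value, a.shape),
            lambda g: _unbroadcast(g * a.value, b.shape),
        ),
    )


def div(a, b):
    a, b = as_node(a), as_node(b)
    return Node(
        a.value / b.value,
        (a, b),
        (
            lambda g: _unbroadcast(g / b.value, a.shape),
            lambda g: _unbroadcast(-g * a.value / b.value**2, b.shape),
        ),
    )


# -- elementwise unary ops ---------------------------------------------


def neg(a):
    a = as_node(a)
    return Node(-a.value, (a,), (lambda g: -g,))


def power(a, exponent: float):
    a = as_node(a)
    c = float(exponent)
    return Node(a.value**c, (a,), (lambda g: g * c * a.value ** (c - 1.0),))


def exp(a):
    a = as_node(a)
    out = np.exp(a.value)
    return Node(out, (a,), (lambda g: g * out,))


def log(a):
    a = as_node(a)
    return Node(np.log(a.value), (a,), (lambda g: g / a.value,))


def log1p(a):
    a = as_node(a)
    return Node(np.log1p(a.value), (a,), (lambda g: g / (1.0 + a.value),))


def sqrt(a):
    a = as_node(a)
    out = np.sqrt(a.value)
    return Node(out, (a,), (lambda g: g * 0.5 / out,))


def square(a):
    a = as_node(a)
    return Node(a.value**2, (a,), (lambda g: g * 2.0 * a.value,))


def abs_(a):
    a = as_node(a)
    return Node(np.abs(a.value), (a,), (lambda g: g * np.sign(a.value),))


def clip_min(a, floor: float):
    """max(a, floor); gradient flows only where a > floor."""
    a = as_node(a)
    mask = a.value > floor
    return Node(np.maximum(a.value, floor), (a,), (lambda g: g * mask,))


# -- shape ops ----------------------------------------------------------


def reshape(a, shape):
    a = as_node(a)
    old = a.shape
    return Node(a.value.reshape(shape), (a,), (lambda g: g.reshape(old),))


def transpose(a):
    a = as_node(a)
    return Node(a.value.T, (a,), (lambda g: np.asarray(g).T,))


def sum_(a, axis=None, keepdims=False):
    a = as_node(a)
    out = a.value.sum(axis=axis, keepdims=keepdims)

    def vjp(g):
        g = np.asarray(g, dtype=float)
        if axis is None:
            return np.broadcast_to(g, a.shape)
        ax = axis if isinstance(axis, tuple) else (axis,)
        if not keepdims:
            for dim in sorted(d % a.ndim for d in ax):
                g = np.expand_dims(g, dim)
        return np.broadcast_to(g, a.shape)

    return Node(out, (a,), (vjp,))


def take_rows(a, idx):
    """Fancy-index along axis 0; VJP scatter-adds into the source."""
    a = as_node(a)
    idx = np.asarray(idx)

    def vjp(g):
        z = np.zeros(a.shape)
        np.add.at(z, idx, g)
        return z

    return Node(a.value[idx], (a,), (vjp,))


def diag_embed(v):
    v = as_node(v)
    return Node(np.diag(v.value), (v,), (lambda g: np.diagonal(g).copy(),))


def diagonal(a):
    a = as_node(a)
    return Node(np.diagonal(a.value).copy(), (a,), (lambda g: np.diag(np.asarray(g)),))


def tril(a, k=0):
    a = as_node(a)
    return Node(np.tril(a.value, k), (a,), (lambda g: np.tril(np.asarray(g), k),))


def scaled_sqdist(X, Z, log_len):
    """r2[i,j] = sum_q (X[i,q] - Z[j,q])^2 * exp(-2 log_len_q).

    Fused op for the ARD-weighted squared distance: forward and reverse
    are small matrix products (no N x M x Q intermediate).
    """
    X, Z, log_len = as_node(X), as_node(Z), as_node(log_len)
    Xv, Zv = X.value, Z.value
    w = np.exp(-2.0 * log_len.value)
    Xw = (Xv**2) @ w
    Zw = (Zv**2) @ w
    cross = (Xv * w) @ Zv.T
    r2 = Xw[:, None] + Zw[None, :] - 2.0 * cross

    def vjp_X(g):
        g = np.asarray(g)
        return 2.0 * w * (Xv * g.sum(axis=1)[:, None] - g @ Zv)

    def vjp_Z(g):
        g = np.asarray(g)
        return 2.0 * w * (Zv * g.sum(axis=0)[:, None] - g.T @ Xv)

    def vjp_len(g):
        g = np.asarray(g)
        s = (
            (Xv**2).T @ g.sum(axis=1)
            + (Zv**2).T @ g.sum(axis=0)
            - 2.0 * (Xv * (g @ Zv)).sum(axis=0)
        )
        return -2.0 * w * s

    return Node(r2, (X, Z, log_len), (vjp_X, vjp_Z, vjp_len))


# -- linear algebra ----------------------------------------------------


def matmul(a, b):
    a, b = as_node(a), as_node(b)
    return Node(
        a.value @ b.value,
        (a, b),
        (lambda g: np.asarray(g) @ b.value.T, lambda g: a.value.T @ np.asarray(g)),
    )


def cholesky(a):
    """Lower Cholesky factor; reverse rule after Murray (2016)."""
    a = as_node(a)
    L = np.linalg.cholesky(a.value)

    def vjp(g):
        Lbar = np.asarray(g)
        P = L.T @ Lbar
        phi = np.tril(P)
        np.fill_diagonal(phi, 0.5 * np.diagonal(P))
        # Abar = L^{-T} phi L^{-1}, symmetrized (A is built entrywise symmetric)
        tmp = solve_triangular(L, phi, lower=True, trans="T")
        Abar = solve_triangular(L, tmp.T, lower=True, trans="T").T
        return 0.5 * (Abar + Abar.T)

    return Node(L, (a,), (vjp,))


def solve_lower(L, B):
    """X = L^{-1} B with L lower triangular."""
    L, B = as_node(L), as_node(B)
    X = solve_triangular(L.value, B.value, lower=True)

    def vjp_L(g):
        Bbar = solve_triangular(L.value, np.asarray(g), lower=True, trans="T")
        return -np.tril(Bbar @ X.T)

    def vjp_B(g):
        return solve_triangular(L.value, np.asarray(g), lower=True, trans="T")

    return Node(X, (L, B), (vjp_L, vjp_B))


# -- backward pass ------------------------------------------------------


def backward(root: Node) -> None:
    """Accumulate gradients of scalar `root` into the graph's `.grad` fields."""
    order: list[Node] = []
    visited: set[int] = set()
    stack: list[tuple[Node, bool]] = [(root, False)]
    while stack:
        node, done = stack.pop()
        if done:
            order.append(node)
            continue
        if id(node) in visited:
            continue
        visited.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            if id(p) not in visited:
                stack.append((p, False))
    for node in order:
        node.grad = None
    root.grad = np.ones_like(root.value)
    for node in reversed(order):
        if node.grad is None:
            continue
        for parent, vjp in zip(node._parents, node._vjps):
            if not parent.requires_grad:
                continue
            g = vjp(node.grad)
            parent.grad = g if parent.grad is None else parent.grad + g


def grad(fn, args, wrt=None):
    """Convenience: gradients of scalar fn(*nodes) w.r.t. selected inputs."""
    nodes = [Node(np.asarray(a, dtype=float), requires_grad=True) for a in args]
    out = fn(*nodes)
    backward(out)
    sel = range(len(nodes)) if wrt is None else wrt
    return out.value, [
        nodes[i].grad if nodes[i].grad is not None else np.zeros(nodes[i].shape)
        for i in sel
    ]
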