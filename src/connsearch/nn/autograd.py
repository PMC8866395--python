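"""Compact reverse-mode automatic differentiation over numpy arrays.

Only the operations needed by the deep classifiers in this package are
implemented: broadcast arithmetic, matrix products, pointwise
nonlinearities, reductions, shape ops, and the edge-to-edge /
edge-to-node / node-to-graph contractions used by the connectivity CNN.
Gradients are checked against finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "narrow", "relu", "leaky_relu", "tanh",
           "sigmoid", "softplus", "e2e", "e2n", "n2g"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce a broadcast gradient back to the original operand shape."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """Node in the computation graph; `backward()` fills `.grad` on leaves."""

    __slots__ = ("data", "grad", "_parents", "_grad_fn")

    def __init__(self, data, _parents=(), _grad_fn=None):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self._parents = _parents
        self._grad_fn = _grad_fn

    @property
    def shape(self):
        return self.data.shape

    # -- graph traversal ----------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, float)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t.grad is None:
                t.grad = g.copy()
            else:
                t.grad = t.grad + g
            if t._grad_fn is None:
                continue
            for p, pg in zip(t._parents, t._grad_fn(g)):
                if pg is None:
                    continue
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg

    def zero_grad(self):
        self.grad = None

    # -- arithmetic ----------------------------------------------------------
    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data, (self, other),
                     lambda g: (_unbroadcast(g, self.data.shape),
                                _unbroadcast(g, other.data.shape)))
        return out

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data, (self, other),
                     lambda g: (_unbroadcast(g * other.data, self.data.shape),
                                _unbroadcast(g * self.data, other.data.shape)))
        return out

    __rmul__ = __mul__

    def __matmul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data @ other.data, (self, other),
                     lambda g: (g @ other.data.T, self.data.T @ g))
        return out

    # -- reductions / shape ----------------------------------------------------
    def sum(self):
        return Tensor(self.data.sum(), (self,),
                      lambda g: (np.broadcast_to(g, self.data.shape).copy(),))

    def mean(self):
        n = self.data.size
        return Tensor(self.data.mean(), (self,),
                      lambda g: (np.broadcast_to(g / n, self.data.shape).copy(),))

    def reshape(self, *shape):
        old = self.data.shape
        return Tensor(self.data.reshape(*shape), (self,),
                      lambda g: (g.reshape(old),))


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def grad_fn(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                  tuple(tensors), grad_fn)


def narrow(t: Tensor, start: int, size: int, axis: int = -1) -> Tensor:
    """Contiguous slice along one axis (used to split LSTM gate blocks)."""
    idx = [slice(None)] * t.data.ndim
    idx[axis] = slice(start, start + size)
    idx = tuple(idx)

    def grad_fn(g):
        full = np.zeros_like(t.data)
        full[idx] = g
        return (full,)

    return Tensor(t.data[idx], (t,), grad_fn)


def relu(t: Tensor) -> Tensor:
    mask = t.data > 0
    return Tensor(t.data * mask, (t,), lambda g: (g * mask,))


def leaky_relu(t: Tensor, slope: float = 0.1) -> Tensor:
    factor = np.where(t.data > 0, 1.0, slope)
    return Tensor(t.data * factor, (t,), lambda g: (g * factor,))


def tanh(t: Tensor) -> Tensor:
    y = np.tanh(t.data)
    return Tensor(y, (t,), lambda g: (g * (1 - y * y),))


def sigmoid(t: Tensor) -> Tensor:
    y = np.where(t.data >= 0, 1.0 / (1.0 + np.exp(-np.abs(t.data))),
                 np.exp(-np.abs(t.data)) / (1.0 + np.exp(-np.abs(t.data))))
    return Tensor(y, (t,), lambda g: (g * y * (1 - y),))


def softplus(t: Tensor) -> Tensor:
    y = np.maximum(t.data, 0) + np.log1p(np.exp(-np.abs(t.data)))
    s = np.where(t.data >= 0, 1.0 / (1.0 + np.exp(-np.abs(t.data))),
                 np.exp(-np.abs(t.data)) / (1.0 + np.exp(-np.abs(t.data))))
    return Tensor(y, (t,), lambda g: (g * s,))


# ---------------------------------------------------------------------------
# Connectivity-matrix contractions (edge-to-edge CNN layers)
# ---------------------------------------------------------------------------

def e2e(A: Tensor, r: Tensor, s: Tensor) -> Tensor:
    """Edge-to-edge layer: cross-shaped filters on connectivity matrices.

    A: (N, C, R, R); r, s: (O, C, R) row/column filter weights.
    out[n,o,i,j] = sum_{c,k} r[o,c,k] A[n,c,i,k] + s[o,c,k] A[n,c,k,j]
    """
    row = np.einsum("ncik,ock->noi", A.data, r.data)
    col = np.einsum("nckj,ock->noj", A.data, s.data)
    out = row[:, :, :, None] + col[:, :, None, :]

    def grad_fn(g):
        grow = g.sum(axis=3)
        gcol = g.sum(axis=2)
        dA = (np.einsum("noi,ock->ncik", grow, r.data)
              + np.einsum("noj,ock->nckj", gcol, s.data))
        dr = np.einsum("noi,ncik->ock", grow, A.data)
        ds = np.einsum("noj,nckj->ock", gcol, A.data)
        return dA, dr, ds

    return Tensor(out, (A, r, s), grad_fn)


def e2n(A: Tensor, w: Tensor) -> Tensor:
    """Edge-to-node layer: per-channel row reduction. A: (N,C,R,R), w: (C,R)."""
    out = np.einsum("ncij,cj->nci", A.data, w.data)

    def grad_fn(g):
        dA = np.einsum("nci,cj->ncij", g, w.data)
        dw = np.einsum("nci,ncij->cj", g, A.data)
        return dA, dw

    return Tensor(out, (A, w), grad_fn)


def n2g(H: Tensor, v: Tensor) -> Tensor:
    """Node-to-graph layer: per-channel node pooling. H: (N,C,R), v: (C,R)."""
    out = np.einsum("nci,ci->nc", H.data, v.data)

    def grad_fn(g):
        dH = np.einsum("nc,ci->nci", g, v.data)
        dv = np.einsum("nc,nci->ci", g, H.data)
        return dH, dv

    return Tensor(out, (H, v), grad_fn)
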