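"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operator set the package's models need: broadcasted
arithmetic, matmul, the ELU/sigmoid/softplus nonlinearities, reductions,
reshapes, row/column gathers and segment sums (the graph-aggregation
primitives), all with float64 precision so runs are bit-reproducible on a
single device.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "segment_sum", "take_rows", "take_cols"]


def _as_array(x) -> np.ndarray:
    return np.asarray(x, dtype=np.float64)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple = ()

    # -- graph plumbing ------------------------------------------------
    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        # out-of-place accumulation: incoming grad arrays are never mutated,
        # so aliasing them on first touch is safe and avoids large copies
        if self.grad is None:
            self.grad = grad
        else:
            self.grad = self.grad + grad

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
        self._accum(_as_array(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    @property
    def shape(self):
        return self.data.shape

    # -- arithmetic ----------------------------------------------------
    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        a, b = self, Tensor._coerce(other)

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))

        return Tensor._make(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def backward(g):
            a._accum(-g)

        return Tensor._make(-a.data, (a,), backward)

    def __sub__(self, other):
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other):
        return Tensor._coerce(other) + (-self)

    def __mul__(self, other):
        a, b = self, Tensor._coerce(other)

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._make(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        a, b = self, Tensor._coerce(other)

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / (b.data**2), b.data.shape))

        return Tensor._make(a.data / b.data, (a, b), backward)

    def __rtruediv__(self, other):
        return Tensor._coerce(other) / self

    def __pow__(self, p: float):
        a = self

        def backward(g):
            a._accum(g * p * a.data ** (p - 1))

        return Tensor._make(a.data**p, (a,), backward)

    def __matmul__(self, other):
        a, b = self, Tensor._coerce(other)

        def backward(g):
            if a.requires_grad:
                a._accum(g @ b.data.T)
            if b.requires_grad:
                b._accum(a.data.T @ g)

        return Tensor._make(a.data @ b.data, (a, b), backward)

    # -- elementwise nonlinearities ------------------------------------
    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def backward(g):
            a._accum(g * out_data)

        return Tensor._make(out_data, (a,), backward)

    def log(self):
        a = self

        def backward(g):
            a._accum(g / a.data)

        return Tensor._make(np.log(a.data), (a,), backward)

    def sqrt(self):
        a = self
        out_data = np.sqrt(a.data)

        def backward(g):
            a._accum(g * 0.5 / out_data)

        return Tensor._make(out_data, (a,), backward)

    def sigmoid(self):
        a = self
        s = _sigmoid(a.data)

        def backward(g):
            a._accum(g * s * (1.0 - s))

        return Tensor._make(s, (a,), backward)

    def softplus(self):
        """log(1 + e^x), computed without overflow."""
        a = self
        out_data = np.logaddexp(0.0, a.data)

        def backward(g):
            a._accum(g * _sigmoid(a.data))

        return Tensor._make(out_data, (a,), backward)

    def elu(self, alpha: float = 1.0):
        a = self
        neg = alpha * (np.exp(np.minimum(a.data, 0.0)) - 1.0)
        out_data = np.where(a.data > 0, a.data, neg)

        def backward(g):
            a._accum(g * np.where(a.data > 0, 1.0, neg + alpha))

        return Tensor._make(out_data, (a,), backward)

    def relu(self):
        a = self

        def backward(g):
            a._accum(g * (a.data > 0))

        return Tensor._make(np.maximum(a.data, 0.0), (a,), backward)

    # -- reductions / shape --------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def backward(g):
            if axis is None:
                a._accum(np.broadcast_to(g, a.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                a._accum(np.broadcast_to(gg, a.data.shape).copy())

        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def reshape(self, *shape):
        a = self

        def backward(g):
            a._accum(g.reshape(a.data.shape))

        return Tensor._make(a.data.reshape(*shape), (a,), backward)

    @property
    def T(self):
        a = self

        def backward(g):
            a._accum(g.T)

        return Tensor._make(a.data.T, (a,), backward)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Parameter(Tensor):
    __slots__ = ()

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def _scatter_add_rows(g: np.ndarray, idx: np.ndarray, n_rows: int) -> np.ndarray:
    """Row-wise scatter-add via one flat bincount pass (faster than ufunc.at)."""
    g2 = g.reshape(len(idx), -1)
    ncol = g2.shape[1]
    flat = (idx[:, None] * ncol + np.arange(ncol)[None, :]).ravel()
    out = np.bincount(flat, weights=g2.ravel(), minlength=n_rows * ncol)
    return out.reshape((n_rows,) + g.shape[1:])


def take_rows(t: Tensor, idx: np.ndarray) -> Tensor:
    """Gather rows (axis 0); backward scatter-adds into the source."""
    idx = np.asarray(idx, dtype=np.intp)

    def backward(g):
        t._accum(_scatter_add_rows(g, idx, t.data.shape[0]))

    return Tensor._make(t.data[idx], (t,), backward)


def take_cols(t: Tensor, idx: np.ndarray) -> Tensor:
    """Gather columns (axis 1) of a 2-d tensor."""
    idx = np.asarray(idx, dtype=np.intp)

    def backward(g):
        B, D = t.data.shape
        flat = (np.arange(B)[:, None] * D + idx[None, :]).ravel()
        grad = np.bincount(flat, weights=g.ravel(), minlength=B * D)
        t._accum(grad.reshape(B, D))

    return Tensor._make(t.data[:, idx], (t,), backward)


def segment_sum(t: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of `t` into `num_segments` buckets given per-row ids."""
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    out_data = _scatter_add_rows(t.data, segment_ids, num_segments)

    def backward(g):
        t._accum(g[segment_ids])

    return Tensor._make(out_data, (t,), backward)
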