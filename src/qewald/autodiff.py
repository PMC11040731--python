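"""Compact reverse-mode automatic differentiation on NumPy arrays.

A tape-based engine providing exactly the primitives the potential-energy
models need: broadcasting arithmetic, matmul, reductions, the shifted
softplus activation, trigonometric kernels (including a numerically safe
``sinc``), row gather and segment-sum scatter.  Gradients are accumulated
into ``Tensor.grad`` by :meth:`Tensor.backward` via a topological sweep.

The engine is deliberately minimal: float64 throughout, no graph reuse,
no in-place mutation of node data after creation.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "segment_sum", "concat", "no_grad_data"]

_LN2 = float(np.log(2.0))


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach its shape."""
    if grad.shape == shape:
        return grad
    # sum away leading extra dims
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _parents)
        self._parents = tuple(_parents)
        self._backward = _backward

    # -- introspection ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autograd mechanics ----------------------------------------------
    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this node (defaults to d(self)/d(self)=1)."""
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
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(-g)

        out._backward = bwd
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data, _parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        out._backward = bwd
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        assert np.isscalar(p)
        out = Tensor(self.data**p, _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * p * self.data ** (p - 1))

        out._backward = bwd
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        out._backward = bwd
        return out

    # -- elementwise functions -------------------------------------------
    def exp(self):
        out = Tensor(np.exp(self.data), _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * out.data)

        out._backward = bwd
        return out

    def sin(self):
        out = Tensor(np.sin(self.data), _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * np.cos(self.data))

        out._backward = bwd
        return out

    def cos(self):
        out = Tensor(np.cos(self.data), _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(-g * np.sin(self.data))

        out._backward = bwd
        return out

    def sqrt(self):
        out = Tensor(np.sqrt(self.data), _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * 0.5 / out.data)

        out._backward = bwd
        return out

    def ssp(self):
        """Shifted softplus ln(0.5 e^x + 0.5); ssp(0)=0, ssp'(x)=sigmoid(x)."""
        out = Tensor(np.logaddexp(0.0, self.data) - _LN2, _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                sig = 1.0 / (1.0 + np.exp(-self.data))
                self._accumulate(g * sig)

        out._backward = bwd
        return out

    def sinc(self):
        """sin(x)/x with the limit 1 at x=0 (x in radians, not numpy's sinc)."""
        x = self.data
        small = np.abs(x) < 1e-6
        safe = np.where(small, 1.0, x)
        val = np.where(small, 1.0 - x * x / 6.0, np.sin(safe) / safe)
        out = Tensor(val, _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                # d/dx sin(x)/x = (x cos x - sin x)/x^2, -> -x/3 near 0
                deriv = np.where(
                    small, -x / 3.0, (safe * np.cos(safe) - np.sin(safe)) / safe**2
                )
                self._accumulate(g * deriv)

        out._backward = bwd
        return out

    # -- reductions & shaping --------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.data.shape))

        out._backward = bwd
        return out

    def gather(self, idx: np.ndarray):
        """Select rows (axis 0) by an integer index array; scatter-adds back."""
        idx = np.asarray(idx, dtype=np.intp)
        out = Tensor(self.data[idx], _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                acc = np.zeros_like(self.data)
                np.add.at(acc, idx, g)
                self._accumulate(acc)

        out._backward = bwd
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def segment_sum(x: Tensor, seg_ids: np.ndarray, n_segments: int) -> Tensor:
    """Sum rows of ``x`` into ``n_segments`` buckets given by ``seg_ids``."""
    seg_ids = np.asarray(seg_ids, dtype=np.intp)
    out_data = np.zeros((n_segments,) + x.data.shape[1:], dtype=np.float64)
    np.add.at(out_data, seg_ids, x.data)
    out = Tensor(out_data, _parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g[seg_ids])

    out._backward = bwd
    return out


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), _parents=tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    out._backward = bwd
    return out


def no_grad_data(x) -> np.ndarray:
    """The underlying ndarray of a Tensor, or the array itself."""
    return x.data if isinstance(x, Tensor) else np.asarray(x, dtype=np.float64)
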