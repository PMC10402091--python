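"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Supports exactly the operations the graph-attention network needs: dense
linear algebra, elementwise nonlinearities, reductions, concatenation, row
gathering and segment (scatter-add) sums for message passing, and a
numerically stable segment softmax. Gradients are accumulated by a
topological-order backward sweep; broadcasting is handled by summing
gradients back to the operand shape.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "gather_rows", "segment_sum", "segment_softmax"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    # ---- graph plumbing ------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor):
            stack = [(t, iter(t._parents))]
            if id(t) in seen:
                return
            seen.add(id(t))
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if id(p) not in seen:
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(node)
                    stack.pop()

        visit(self)
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=float)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is None:
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if pg is None:
                    continue
                pg = _unbroadcast(pg, parent.data.shape)
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg

    def zero_grad(self) -> None:
        self.grad = None

    # ---- arithmetic ----------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)
        return Tensor(
            self.data + other.data,
            parents=(self, other),
            backward=lambda g: (g, g),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, parents=(self,), backward=lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        return Tensor(
            self.data * other.data,
            parents=(self, other),
            backward=lambda g: (g * other.data, g * self.data),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        return Tensor(
            self.data / other.data,
            parents=(self, other),
            backward=lambda g: (
                g / other.data,
                -g * self.data / other.data**2,
            ),
        )

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __matmul__(self, other):
        other = self._lift(other)
        return Tensor(
            self.data @ other.data,
            parents=(self, other),
            backward=lambda g: (g @ other.data.T, self.data.T @ g),
        )

    def square(self):
        return self * self

    def sqrt(self):
        out = np.sqrt(self.data)
        return Tensor(out, parents=(self,), backward=lambda g: (g * 0.5 / np.sqrt(self.data),))

    def exp(self):
        out = np.exp(self.data)
        return Tensor(out, parents=(self,), backward=lambda g: (g * out,))

    def log(self):
        return Tensor(
            np.log(self.data), parents=(self,), backward=lambda g: (g / self.data,)
        )

    # ---- reductions ----------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def back(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.data.shape).copy(),)

        return Tensor(out, parents=(self,), backward=back)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ---- nonlinearities ------------------------------------------------

    def leaky_relu(self, slope: float = 0.2):
        mask = np.where(self.data > 0, 1.0, slope)
        return Tensor(self.data * mask, parents=(self,), backward=lambda g: (g * mask,))

    def elu(self, alpha: float = 1.0):
        out = np.where(self.data > 0, self.data, alpha * (np.exp(np.minimum(self.data, 0)) - 1))
        deriv = np.where(self.data > 0, 1.0, out + alpha)
        return Tensor(out, parents=(self,), backward=lambda g: (g * deriv,))

    def sigmoid(self):
        out = 0.5 * (1.0 + np.tanh(0.5 * self.data))
        return Tensor(out, parents=(self,), backward=lambda g: (g * out * (1 - out),))

    def softplus(self):
        # log(1 + e^x), stable
        out = np.logaddexp(0.0, self.data)
        sig = 0.5 * (1.0 + np.tanh(0.5 * self.data))
        return Tensor(out, parents=(self,), backward=lambda g: (g * sig,))

    def __getitem__(self, key):
        out = self.data[key]

        def back(g):
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            return (full,)

        return Tensor(out, parents=(self,), backward=back)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def back(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(out, parents=tuple(tensors), backward=back)


def gather_rows(t: Tensor, idx: np.ndarray) -> Tensor:
    idx = np.asarray(idx, dtype=int)
    out = t.data[idx]

    def back(g):
        full = np.zeros_like(t.data)
        np.add.at(full, idx, g)
        return (full,)

    return Tensor(out, parents=(t,), backward=back)


def segment_sum(t: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of ``t`` into ``num_segments`` buckets (scatter-add)."""
    segment_ids = np.asarray(segment_ids, dtype=int)
    out = np.zeros((num_segments,) + t.data.shape[1:])
    np.add.at(out, segment_ids, t.data)

    def back(g):
        return (g[segment_ids],)

    return Tensor(out, parents=(t,), backward=back)


def segment_softmax(scores: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Softmax of ``scores`` (shape (E,) or (E,1)) within each segment.

    Stabilized by subtracting the per-segment maximum (treated as constant,
    which leaves the gradient exact by shift invariance of softmax).
    """
    segment_ids = np.asarray(segment_ids, dtype=int)
    flat = scores.data.reshape(-1)
    seg_max = np.full(num_segments, -np.inf)
    np.maximum.at(seg_max, segment_ids, flat)
    seg_max[~np.isfinite(seg_max)] = 0.0
    shift = Tensor(seg_max[segment_ids].reshape(scores.data.shape))
    ex = (scores - shift).exp()
    denom = segment_sum(ex, segment_ids, num_segments)
    return ex / gather_rows(denom, segment_ids)
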