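"""Minimal reverse-mode automatic differentiation over numpy arrays.

Provides exactly the operator set the package's models need: broadcasted
arithmetic, (batched) matrix products, reductions, the usual nonlinearities,
a numerically stable softmax, reshaping/indexing and concatenation.  All
tensors hold float64 data; gradients are accumulated in float64 as well,
which keeps training deterministic across runs on the same platform.

Gradient correctness is established by central-difference checks in the
test-suite rather than by construction, so every primitive added here must
come with a finite-difference test.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "no_grad", "concatenate", "is_grad_enabled"]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Context manager disabling graph construction (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over axes that were broadcast to reach `grad.shape`."""
    if grad.shape == shape:
        return grad
    # leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # ---- factory -------------------------------------------------------
    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # ---- autodiff driver ----------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that requires no grad")
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("grad must be supplied for non-scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep (many blocks/steps)
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
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    # ---- arithmetic ----------------------------------------------------
    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.shape))

        return Tensor._make(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def backward(g):
            a._accumulate(-g)

        return Tensor._make(-a.data, (a,), backward)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.shape))

        return Tensor._make(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g / b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(-g * a.data / b.data**2, b.shape))

        return Tensor._make(a.data / b.data, (a, b), backward)

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, exponent: float):
        a = self
        e = float(exponent)

        def backward(g):
            a._accumulate(g * e * a.data ** (e - 1.0))

        return Tensor._make(a.data**e, (a,), backward)

    def __matmul__(self, other):
        other = self._coerce(other)
        a, b = self, other
        out_data = a.data @ b.data

        def backward(g):
            if a.requires_grad:
                if b.data.ndim == 1:
                    ga = np.multiply.outer(g, b.data) if a.data.ndim > 1 else g * b.data
                else:
                    ga = g @ np.swapaxes(b.data, -1, -2)
                a._accumulate(_unbroadcast(np.asarray(ga), a.shape))
            if b.requires_grad:
                if a.data.ndim == 1:
                    gb = np.multiply.outer(a.data, g) if b.data.ndim > 1 else a.data * g
                else:
                    gb = np.swapaxes(a.data, -1, -2) @ g
                b._accumulate(_unbroadcast(np.asarray(gb), b.shape))

        return Tensor._make(out_data, (a, b), backward)

    # ---- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def backward(g):
            if axis is None:
                grad = np.broadcast_to(g, a.shape).copy()
            else:
                g_exp = np.expand_dims(g, axis) if not keepdims else g
                grad = np.broadcast_to(g_exp, a.shape).copy()
            a._accumulate(grad)

        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    # ---- elementwise nonlinearities ------------------------------------
    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def backward(g):
            a._accumulate(g * out_data)

        return Tensor._make(out_data, (a,), backward)

    def log(self):
        a = self

        def backward(g):
            a._accumulate(g / a.data)

        return Tensor._make(np.log(a.data), (a,), backward)

    def sqrt(self):
        a = self
        out_data = np.sqrt(a.data)

        def backward(g):
            a._accumulate(g * 0.5 / out_data)

        return Tensor._make(out_data, (a,), backward)

    def relu(self):
        a = self
        mask = a.data > 0

        def backward(g):
            a._accumulate(g * mask)

        return Tensor._make(np.where(mask, a.data, 0.0), (a,), backward)

    def gelu(self):
        """Gaussian-error linear unit, tanh approximation."""
        a = self
        c = np.sqrt(2.0 / np.pi)
        x = a.data
        inner = c * (x + 0.044715 * x**3)
        t = np.tanh(inner)
        out_data = 0.5 * x * (1.0 + t)

        def backward(g):
            dinner = c * (1.0 + 3 * 0.044715 * x**2)
            grad = 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t**2) * dinner
            a._accumulate(g * grad)

        return Tensor._make(out_data, (a,), backward)

    def softplus(self):
        """log(1 + e^x), numerically stable; derivative is the sigmoid."""
        a = self
        out_data = np.logaddexp(0.0, a.data)

        def backward(g):
            a._accumulate(g / (1.0 + np.exp(-np.clip(a.data, -500, 500))))

        return Tensor._make(out_data, (a,), backward)

    def tanh(self):
        a = self
        t = np.tanh(a.data)

        def backward(g):
            a._accumulate(g * (1.0 - t**2))

        return Tensor._make(t, (a,), backward)

    def sigmoid(self):
        a = self
        s = 1.0 / (1.0 + np.exp(-np.clip(a.data, -500, 500)))

        def backward(g):
            a._accumulate(g * s * (1.0 - s))

        return Tensor._make(s, (a,), backward)

    def softmax(self, axis: int = -1):
        """Numerically stable softmax along `axis` (graph-aware primitive)."""
        a = self
        z = a.data - a.data.max(axis=axis, keepdims=True)
        ez = np.exp(z)
        s = ez / ez.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * s).sum(axis=axis, keepdims=True)
            a._accumulate(s * (g - dot))

        return Tensor._make(s, (a,), backward)

    # ---- shape ops -----------------------------------------------------
    def reshape(self, *shape):
        a = self
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def backward(g):
            a._accumulate(g.reshape(a.shape))

        return Tensor._make(a.data.reshape(shape), (a,), backward)

    def transpose(self, *axes):
        a = self
        ax = axes if axes else None

        def backward(g):
            if ax is None:
                a._accumulate(g.T)
            else:
                inv = np.argsort(ax)
                a._accumulate(g.transpose(inv))

        return Tensor._make(a.data.transpose(ax) if ax else a.data.T, (a,), backward)

    def swapaxes(self, ax1: int, ax2: int):
        a = self

        def backward(g):
            a._accumulate(np.swapaxes(g, ax1, ax2))

        return Tensor._make(np.swapaxes(a.data, ax1, ax2), (a,), backward)

    def __getitem__(self, idx):
        a = self

        def backward(g):
            grad = np.zeros_like(a.data)
            np.add.at(grad, idx, g)
            a._accumulate(grad)

        return Tensor._make(a.data[idx], (a,), backward)


def concatenate(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = [Tensor._coerce(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor._make(np.concatenate([t.data for t in ts], axis=axis), ts, backward)
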