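"""A small reverse-mode automatic differentiation engine on NumPy arrays.

The model in this package is tiny (tens of thousands of parameters, inputs of
a few hundred nodes), so a dynamic define-by-run tape over float64 NumPy
arrays is both fast enough and exactly reproducible across runs. The engine
supports the operations the network needs: broadcasting arithmetic, (batched)
matrix products, row gathers for embedding lookups, elementwise
nonlinearities, reductions, reshapes and concatenation.

Gradients are accumulated into ``Tensor.grad`` by :meth:`Tensor.backward`,
which seeds the output with ones and walks the tape in reverse topological
order. Gradient correctness is verified against central finite differences in
the test-suite.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "as_tensor"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over broadcast dimensions so it matches `shape`."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A NumPy array with an attached gradient tape node."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: tuple["Tensor", ...] = (),
        _backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = _parents
        self._backward = _backward

    # -- basic protocol ----------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def numpy(self) -> np.ndarray:
        return self.data

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.data, dtype=dtype)

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- graph bookkeeping -------------------------------------------------

    def _accumulate(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad, dtype=np.float64), self.data.shape)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        """Backpropagate from this (typically scalar) tensor."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent in node._parents:
                if id(parent) not in seen:
                    stack.append((parent, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(
            self.data + other.data,
            requires_grad=self.requires_grad or other.requires_grad,
            _parents=(self, other),
        )

        def backward(g: np.ndarray) -> None:
            self._accumulate(g)
            other._accumulate(g)

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.data, self.requires_grad, (self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(
            self.data * other.data,
            requires_grad=self.requires_grad or other.requires_grad,
            _parents=(self, other),
        )

        def backward(g: np.ndarray) -> None:
            self._accumulate(g * other.data)
            other._accumulate(g * self.data)

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(
            self.data / other.data,
            requires_grad=self.requires_grad or other.requires_grad,
            _parents=(self, other),
        )

        def backward(g: np.ndarray) -> None:
            self._accumulate(g / other.data)
            other._accumulate(-g * self.data / (other.data**2))

        out._backward = backward
        return out

    def __rtruediv__(self, other) -> "Tensor":
        return as_tensor(other) / self

    def pow(self, exponent: float) -> "Tensor":
        out = Tensor(self.data**exponent, self.requires_grad, (self,))
        out._backward = lambda g: self._accumulate(
            g * exponent * self.data ** (exponent - 1)
        )
        return out

    __pow__ = pow

    def sqrt(self) -> "Tensor":
        return self.pow(0.5)

    def __matmul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(
            self.data @ other.data,
            requires_grad=self.requires_grad or other.requires_grad,
            _parents=(self, other),
        )

        def backward(g: np.ndarray) -> None:
            self._accumulate(g @ np.swapaxes(other.data, -1, -2))
            other._accumulate(np.swapaxes(self.data, -1, -2) @ g)

        out._backward = backward
        return out

    # -- elementwise nonlinearities ---------------------------------------

    def exp(self) -> "Tensor":
        value = np.exp(self.data)
        out = Tensor(value, self.requires_grad, (self,))
        out._backward = lambda g: self._accumulate(g * value)
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), self.requires_grad, (self,))
        out._backward = lambda g: self._accumulate(g / self.data)
        return out

    def tanh(self) -> "Tensor":
        value = np.tanh(self.data)
        out = Tensor(value, self.requires_grad, (self,))
        out._backward = lambda g: self._accumulate(g * (1.0 - value**2))
        return out

    def relu(self) -> "Tensor":
        mask = self.data > 0
        out = Tensor(np.where(mask, self.data, 0.0), self.requires_grad, (self,))
        out._backward = lambda g: self._accumulate(g * mask)
        return out

    def sigmoid(self) -> "Tensor":
        # numerically stable logistic
        value = np.empty_like(self.data)
        pos = self.data >= 0
        value[pos] = 1.0 / (1.0 + np.exp(-self.data[pos]))
        ez = np.exp(self.data[~pos])
        value[~pos] = ez / (1.0 + ez)
        out = Tensor(value, self.requires_grad, (self,))
        out._backward = lambda g: self._accumulate(g * value * (1.0 - value))
        return out

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), self.requires_grad, (self,))

        def backward(g: np.ndarray) -> None:
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape))
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape))

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            count = self.data.size
        else:
            count = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    # -- shape manipulation ------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), self.requires_grad, (self,))
        out._backward = lambda g: self._accumulate(g.reshape(self.data.shape))
        return out

    def transpose(self, *axes) -> "Tensor":
        if not axes:
            axes = tuple(reversed(range(self.data.ndim)))
        elif len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inverse = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), self.requires_grad, (self,))
        out._backward = lambda g: self._accumulate(g.transpose(inverse))
        return out

    @property
    def T(self) -> "Tensor":
        return self.transpose()

    def take_rows(self, indices) -> "Tensor":
        """Gather rows (axis 0); the embedding-lookup primitive."""
        idx = np.asarray(indices, dtype=np.intp)
        out = Tensor(self.data[idx], self.requires_grad, (self,))

        def backward(g: np.ndarray) -> None:
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accumulate(full)

        out._backward = backward
        return out

    def slice(self, key) -> "Tensor":
        out = Tensor(self.data[key], self.requires_grad, (self,))

        def backward(g: np.ndarray) -> None:
            full = np.zeros_like(self.data)
            full[key] = g
            self._accumulate(full)

        out._backward = backward
        return out

    # -- composites --------------------------------------------------------

    def softmax(self, axis: int = -1) -> "Tensor":
        # constant shift: softmax is invariant to it, so treating the max as
        # a constant leaves both the value and the gradient exact
        shift = Tensor(self.data.max(axis=axis, keepdims=True))
        e = (self - shift).exp()
        return e / e.sum(axis=axis, keepdims=True)


def as_tensor(value) -> Tensor:
    return value if isinstance(value, Tensor) else Tensor(value)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    """Concatenate tensors along `axis`, differentiably."""
    tensors = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor(
        data,
        requires_grad=any(t.requires_grad for t in tensors),
        _parents=tuple(tensors),
    )
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g: np.ndarray) -> None:
        for t, start, stop in zip(tensors, offsets[:-1], offsets[1:]):
            index = [slice(None)] * g.ndim
            index[axis] = slice(start, stop)
            t._accumulate(g[tuple(index)])

    out._backward = backward
    return out
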