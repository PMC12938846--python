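"""A minimal reverse-mode autodiff engine on NumPy ndarrays.

Only the operations needed by this package are implemented.  Tensors hold a
NumPy array in ``data``; calling :meth:`Tensor.backward` on a scalar output
accumulates gradients into ``grad`` of every reachable tensor created with
``requires_grad=True`` (or depending on one).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "concat", "stack", "pad", "no_grad"]

_GRAD_ENABLED = [True]


class no_grad:
    """Context manager disabling graph construction (inference/evaluation)."""

    def __enter__(self):
        _GRAD_ENABLED.append(False)
        return self

    def __exit__(self, *exc):
        _GRAD_ENABLED.pop()
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndim_extra = grad.ndim - len(shape)
    if ndim_extra > 0:
        grad = grad.sum(axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)



def _wrap(other, like: "Tensor") -> "Tensor":
    """Coerce an operand; python scalars adopt the tensor's float dtype."""
    if isinstance(other, Tensor):
        return other
    arr = np.asarray(other)
    if arr.ndim == 0 and arr.dtype.kind in "fiu" and like.data.dtype.kind == "f":
        arr = arr.astype(like.data.dtype)
    return Tensor(arr)

class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = (
            bool(requires_grad) or any(p.requires_grad for p in _parents)
        ) and _GRAD_ENABLED[-1]
        self._parents = _parents if self.requires_grad else ()
        self._backward = _backward if self.requires_grad else None

    # -- introspection -----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self):
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- autograd ----------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
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
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray):
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    def zero_grad(self):
        self.grad = None

    # -- elementwise arithmetic -------------------------------------------
    def __add__(self, other):
        other = _wrap(other, self)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = _wrap(other, self)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-_wrap(other, self))

    def __rsub__(self, other):
        return _wrap(other, self) + (-self)

    def __truediv__(self, other):
        other = _wrap(other, self)
        out = Tensor(self.data / other.data, _parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data**2, other.data.shape))

        out._backward = backward
        return out

    def __rtruediv__(self, other):
        return _wrap(other, self) / self

    def __pow__(self, exponent: float):
        out = Tensor(self.data**exponent, _parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1))

        out._backward = backward
        return out

    def exp(self):
        out_data = np.exp(self.data)
        out = Tensor(out_data, _parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data)

        out._backward = backward
        return out

    def log(self):
        out = Tensor(np.log(self.data), _parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        out._backward = backward
        return out

    def sqrt(self):
        return self**0.5

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(out_data, _parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        out._backward = backward
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0), _parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g * (self.data > 0))

        out._backward = backward
        return out

    def tanh(self):
        out_data = np.tanh(self.data)
        out = Tensor(out_data, _parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g * (1.0 - out_data**2))

        out._backward = backward
        return out

    # -- linear algebra ----------------------------------------------------
    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape))

        out._backward = backward
        return out

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).copy())

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def max(self, axis=None, keepdims=False):
        out_data = self.data.max(axis=axis, keepdims=keepdims)
        out = Tensor(out_data, _parents=(self,))

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                m = out_data
                gg = np.asarray(g)
            else:
                m = out_data if keepdims else np.expand_dims(out_data, axis)
                gg = g if keepdims else np.expand_dims(g, axis)
            mask = (self.data == m).astype(self.data.dtype)
            mask /= mask.sum(axis=axis, keepdims=True) if axis is not None else mask.sum()
            self._accum(mask * gg)

        out._backward = backward
        return out

    # -- shaping -----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), _parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(self.data.shape))

        out._backward = backward
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        if not axes:
            axes = tuple(reversed(range(self.ndim)))
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), _parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        out._backward = backward
        return out

    @property
    def T(self):
        return self.transpose()

    def __getitem__(self, key):
        out = Tensor(self.data[key], _parents=(self,))

        def backward(g):
            if self.requires_grad:
                gx = np.zeros_like(self.data)
                np.add.at(gx, key, g)
                self._accum(gx)

        out._backward = backward
        return out

    def take(self, indices: np.ndarray, axis: int):
        """Gather along ``axis`` with an integer index array (scatter-add backward)."""
        indices = np.asarray(indices)
        out = Tensor(np.take(self.data, indices, axis=axis), _parents=(self,))

        def backward(g):
            if not self.requires_grad:
                return
            gx = np.zeros_like(self.data)
            key = [slice(None)] * self.ndim
            key[axis] = indices
            np.add.at(gx, tuple(key), g)
            self._accum(gx)

        out._backward = backward
        return out


def as_tensor(x, dtype=None) -> Tensor:
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=dtype))


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _parents=tuple(tensors))

    def backward(g):
        splits = np.cumsum([t.data.shape[axis] for t in tensors])[:-1]
        for t, gpart in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(gpart)

    out._backward = backward
    return out


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors], axis=axis), _parents=tuple(tensors))

    def backward(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(g, i, axis=axis))

    out._backward = backward
    return out


def pad(t: Tensor, pad_width) -> Tensor:
    """Zero padding; ``pad_width`` as for :func:`numpy.pad`."""
    t = as_tensor(t)
    pw = tuple(tuple(p) for p in pad_width)
    out = Tensor(np.pad(t.data, pw), _parents=(t,))

    def backward(g):
        if t.requires_grad:
            key = tuple(slice(lo, g.shape[i] - hi) for i, (lo, hi) in enumerate(pw))
            t._accum(g[key])

    out._backward = backward
    return out
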