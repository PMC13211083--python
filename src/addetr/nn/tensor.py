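"""Reverse-mode automatic differentiation over numpy arrays.

A deliberately small engine: a :class:`Tensor` wraps an ``ndarray`` and
records a backward closure per operation.  ``Tensor.backward()`` runs a
topological sweep and accumulates gradients into ``.grad``.  Broadcasting
follows numpy semantics; gradients are summed back to the parent shape.

Only the operations the detection models need are implemented.  Custom
fused operations (convolution, batch norm, spectral downsampling) build
their own nodes through :func:`from_op`.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "from_op",
    "as_tensor",
    "concat",
    "stack",
    "maximum",
    "minimum",
    "where",
    "softmax",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    axes = tuple(i for i, (g, s) in enumerate(zip(grad.shape, shape)) if s == 1 and g != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    # Make numpy defer binary ops to Tensor's reflected operators instead
    # of broadcasting Tensors into object arrays.
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data, dtype=np.float64 if np.asarray(data).dtype.kind != "f" else None)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    @property
    def dtype(self):
        return self.data.dtype

    def __len__(self):
        return len(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    # -- autograd driver -----------------------------------------------
    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        else:
            grad = np.asarray(grad, dtype=self.data.dtype)

        # Post-order DFS (iterative): topo lists parents before consumers,
        # so the reversed sweep sees every consumer before its inputs.
        topo: list[Tensor] = []
        seen: set[int] = set()
        work: list[tuple[Tensor, bool]] = [(self, False)]
        while work:
            node, emitted = work.pop()
            if emitted:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            work.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    work.append((p, False))

        self.grad = grad if self.grad is None else self.grad + grad
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ----------------------------------------------------
    # python scalars take a fast path (and keep float32 graphs float32:
    # wrapping them as 0-d float64 arrays would upcast every result)
    def __add__(self, other):
        if isinstance(other, (int, float)):
            out = from_op(self.data + other, (self,), None)
            if out.requires_grad:
                out._backward = lambda g: _acc(self, g)
            return out
        other = as_tensor(other)
        out = from_op(self.data + other.data, (self, other), None)
        if out.requires_grad:
            def bw(g):
                if self.requires_grad:
                    _acc(self, _unbroadcast(g, self.data.shape))
                if other.requires_grad:
                    _acc(other, _unbroadcast(g, other.data.shape))
            out._backward = bw
        return out

    __radd__ = __add__

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            out = from_op(self.data * other, (self,), None)
            if out.requires_grad:
                out._backward = lambda g: _acc(self, g * other)
            return out
        other = as_tensor(other)
        out = from_op(self.data * other.data, (self, other), None)
        if out.requires_grad:
            def bw(g):
                if self.requires_grad:
                    _acc(self, _unbroadcast(g * other.data, self.data.shape))
                if other.requires_grad:
                    _acc(other, _unbroadcast(g * self.data, other.data.shape))
            out._backward = bw
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return self * (1.0 / other)
        other = as_tensor(other)
        out = from_op(self.data / other.data, (self, other), None)
        if out.requires_grad:
            def bw(g):
                if self.requires_grad:
                    _acc(self, _unbroadcast(g / other.data, self.data.shape))
                if other.requires_grad:
                    _acc(other, _unbroadcast(-g * self.data / (other.data ** 2), other.data.shape))
            out._backward = bw
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        out = from_op(self.data ** exponent, (self,), None)
        if out.requires_grad:
            def bw(g):
                _acc(self, _unbroadcast(g * exponent * self.data ** (exponent - 1), self.data.shape))
            out._backward = bw
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = from_op(self.data @ other.data, (self, other), None)
        if out.requires_grad:
            def bw(g):
                if self.requires_grad:
                    ga = g @ np.swapaxes(other.data, -1, -2)
                    _acc(self, _unbroadcast(ga, self.data.shape))
                if other.requires_grad:
                    gb = np.swapaxes(self.data, -1, -2) @ g
                    _acc(other, _unbroadcast(gb, other.data.shape))
            out._backward = bw
        return out

    def __getitem__(self, idx):
        out = from_op(self.data[idx], (self,), None)
        if out.requires_grad:
            def bw(g):
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                _acc(self, full)
            out._backward = bw
        return out

    # -- shape ops -----------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = from_op(self.data.reshape(shape), (self,), None)
        if out.requires_grad:
            out._backward = lambda g: _acc(self, g.reshape(self.data.shape))
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        axes = tuple(a % self.data.ndim for a in axes)
        inv = np.argsort(axes)
        out = from_op(self.data.transpose(axes), (self,), None)
        if out.requires_grad:
            out._backward = lambda g: _acc(self, g.transpose(inv))
        return out

    def swapaxes(self, a, b):
        axes = list(range(self.data.ndim))
        axes[a], axes[b] = axes[b], axes[a]
        return self.transpose(*axes)

    # -- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = from_op(self.data.sum(axis=axis, keepdims=keepdims), (self,), None)
        if out.requires_grad:
            def bw(g):
                if axis is None:
                    _acc(self, np.broadcast_to(g, self.data.shape).copy())
                    return
                ax = axis if isinstance(axis, tuple) else (axis,)
                if not keepdims:
                    g = np.expand_dims(g, ax)
                _acc(self, np.broadcast_to(g, self.data.shape).copy())
            out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- elementwise nonlinearities -------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        out = from_op(out_data, (self,), None)
        if out.requires_grad:
            out._backward = lambda g: _acc(self, g * out_data)
        return out

    def log(self):
        out = from_op(np.log(self.data), (self,), None)
        if out.requires_grad:
            out._backward = lambda g: _acc(self, g / self.data)
        return out

    def sqrt(self):
        out_data = np.sqrt(self.data)
        out = from_op(out_data, (self,), None)
        if out.requires_grad:
            out._backward = lambda g: _acc(self, g * 0.5 / out_data)
        return out

    def abs(self):
        out = from_op(np.abs(self.data), (self,), None)
        if out.requires_grad:
            out._backward = lambda g: _acc(self, g * np.sign(self.data))
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -80.0, 80.0)))
        out = from_op(s, (self,), None)
        if out.requires_grad:
            out._backward = lambda g: _acc(self, g * s * (1.0 - s))
        return out

    def tanh(self):
        t = np.tanh(self.data)
        out = from_op(t, (self,), None)
        if out.requires_grad:
            out._backward = lambda g: _acc(self, g * (1.0 - t * t))
        return out

    def relu(self):
        out = from_op(np.maximum(self.data, 0.0), (self,), None)
        if out.requires_grad:
            out._backward = lambda g: _acc(self, g * (self.data > 0))
        return out

    def silu(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -80.0, 80.0)))
        out = from_op(self.data * s, (self,), None)
        if out.requires_grad:
            out._backward = lambda g: _acc(self, g * (s + self.data * s * (1.0 - s)))
        return out

    def sin(self):
        out = from_op(np.sin(self.data), (self,), None)
        if out.requires_grad:
            out._backward = lambda g: _acc(self, g * np.cos(self.data))
        return out

    def cos(self):
        out = from_op(np.cos(self.data), (self,), None)
        if out.requires_grad:
            out._backward = lambda g: _acc(self, -g * np.sin(self.data))
        return out

    def arcsin(self):
        out = from_op(np.arcsin(self.data), (self,), None)
        if out.requires_grad:
            out._backward = lambda g: _acc(self, g / np.sqrt(np.maximum(1.0 - self.data ** 2, 1e-12)))
        return out

    def arctan(self):
        out = from_op(np.arctan(self.data), (self,), None)
        if out.requires_grad:
            out._backward = lambda g: _acc(self, g / (1.0 + self.data ** 2))
        return out


def _acc(node: Tensor, g: np.ndarray) -> None:
    node.grad = g if node.grad is None else node.grad + g


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def from_op(data: np.ndarray, parents: tuple[Tensor, ...], backward) -> Tensor:
    out = Tensor(data)
    out.requires_grad = any(p.requires_grad for p in parents)
    if out.requires_grad:
        out._parents = tuple(parents)
        out._backward = backward
    return out


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = from_op(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), None)
    if out.requires_grad:
        sizes = [t.data.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)

        def bw(g):
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(lo, hi)
                    _acc(t, g[tuple(sl)])
        out._backward = bw
    return out


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = from_op(np.stack([t.data for t in tensors], axis=axis), tuple(tensors), None)
    if out.requires_grad:
        def bw(g):
            for i, t in enumerate(tensors):
                if t.requires_grad:
                    _acc(t, np.take(g, i, axis=axis))
        out._backward = bw
    return out


def maximum(a, b) -> Tensor:
    if isinstance(a, (int, float)):
        a, b = b, a
    if isinstance(b, (int, float)):
        a = as_tensor(a)
        out = from_op(np.maximum(a.data, b), (a,), None)
        if out.requires_grad:
            mask = a.data >= b
            out._backward = lambda g: _acc(a, g * mask)
        return out
    a, b = as_tensor(a), as_tensor(b)
    out = from_op(np.maximum(a.data, b.data), (a, b), None)
    if out.requires_grad:
        mask = a.data >= b.data

        def bw(g):
            if a.requires_grad:
                _acc(a, _unbroadcast(g * mask, a.data.shape))
            if b.requires_grad:
                _acc(b, _unbroadcast(g * ~mask, b.data.shape))
        out._backward = bw
    return out


def minimum(a, b) -> Tensor:
    if isinstance(a, (int, float)):
        a, b = b, a
    if isinstance(b, (int, float)):
        a = as_tensor(a)
        out = from_op(np.minimum(a.data, b), (a,), None)
        if out.requires_grad:
            mask = a.data <= b
            out._backward = lambda g: _acc(a, g * mask)
        return out
    a, b = as_tensor(a), as_tensor(b)
    out = from_op(np.minimum(a.data, b.data), (a, b), None)
    if out.requires_grad:
        mask = a.data <= b.data

        def bw(g):
            if a.requires_grad:
                _acc(a, _unbroadcast(g * mask, a.data.shape))
            if b.requires_grad:
                _acc(b, _unbroadcast(g * ~mask, b.data.shape))
        out._backward = bw
    return out


def where(cond: np.ndarray, a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    cond = np.asarray(cond, dtype=bool)
    out = from_op(np.where(cond, a.data, b.data), (a, b), None)
    if out.requires_grad:
        def bw(g):
            if a.requires_grad:
                _acc(a, _unbroadcast(g * cond, a.data.shape))
            if b.requires_grad:
                _acc(b, _unbroadcast(g * ~cond, b.data.shape))
        out._backward = bw
    return out


def softmax(t: Tensor, axis: int = -1) -> Tensor:
    t = as_tensor(t)
    z = t.data - t.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)
    out = from_op(s, (t,), None)
    if out.requires_grad:
        def bw(g):
            dot = (g * s).sum(axis=axis, keepdims=True)
            _acc(t, s * (g - dot))
        out._backward = bw
    return out
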