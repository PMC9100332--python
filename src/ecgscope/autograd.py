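"""Reverse-mode automatic differentiation over NumPy arrays.

A compact tape-based engine: every operation on :class:`Tensor` records a
backward closure; :meth:`Tensor.backward` walks the tape in reverse
topological order.  Only the primitives needed by the network layers in
:mod:`ecgscope.nn` are implemented (broadcast arithmetic, batched matmul,
reductions, relu/sigmoid/exp/log, softmax, max-pooling, concatenation,
slicing).  Gradients are accumulated in the same dtype as the data;
float32 is used throughout the model for speed, float64 in gradient-check
tests.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "layer_norm", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling tape recording (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum away prepended axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were broadcast from size 1
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # ------------------------------------------------------------------ util
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other))

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # ------------------------------------------------------------- arithmetic
    # python-scalar fast paths keep the array dtype (no float64 upcast)
    def __add__(self, other):
        if isinstance(other, (int, float)):
            return self._make(self.data + other, (self,), lambda g: (g,))
        other = self._wrap(other)
        data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.data.shape),
                    _unbroadcast(g, other.data.shape))

        return self._make(data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            return self._make(self.data * other, (self,),
                              lambda g: (g * other,))
        other = self._wrap(other)
        data = self.data * other.data

        def backward(g):
            return (_unbroadcast(g * other.data, self.data.shape),
                    _unbroadcast(g * self.data, other.data.shape))

        return self._make(data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return self * (1.0 / other)
        other = self._wrap(other)
        data = self.data / other.data

        def backward(g):
            return (_unbroadcast(g / other.data, self.data.shape),
                    _unbroadcast(-g * self.data / other.data ** 2,
                                 other.data.shape))

        return self._make(data, (self, other), backward)

    def __pow__(self, p: float):
        data = self.data ** p

        def backward(g):
            return (g * p * self.data ** (p - 1),)

        return self._make(data, (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)
        data = np.matmul(self.data, other.data)

        def backward(g):
            a, b = self.data, other.data
            if a.ndim == 1:
                a = a[None, :]
            if b.ndim == 1:
                b = b[:, None]
            gm = g
            if self.data.ndim == 1:
                gm = np.expand_dims(gm, -2)
            if other.data.ndim == 1:
                gm = np.expand_dims(gm, -1)
            ga = np.matmul(gm, np.swapaxes(b, -1, -2))
            gb = np.matmul(np.swapaxes(a, -1, -2), gm)
            return (_unbroadcast(ga, self.data.shape).reshape(self.data.shape),
                    _unbroadcast(gb, other.data.shape).reshape(other.data.shape))

        return self._make(data, (self, other), backward)

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims=False):
        data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.data.shape).copy(),)
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            return (np.broadcast_to(gg, self.data.shape).copy(),)

        return self._make(data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ----------------------------------------------------------- nonlinearities
    def relu(self):
        mask = self.data > 0
        return self._make(self.data * mask, (self,), lambda g: (g * mask,))

    def exp(self):
        data = np.exp(self.data)
        return self._make(data, (self,), lambda g: (g * data,))

    def log(self):
        return self._make(np.log(self.data), (self,),
                          lambda g: (g / self.data,))

    def sigmoid(self):
        data = 1.0 / (1.0 + np.exp(-self.data))
        return self._make(data, (self,), lambda g: (g * data * (1.0 - data),))

    def sqrt(self):
        data = np.sqrt(self.data)
        return self._make(data, (self,), lambda g: (g * 0.5 / data,))

    def softmax(self, axis: int = -1):
        """Numerically stable softmax along `axis`."""
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * s).sum(axis=axis, keepdims=True)
            return (s * (g - dot),)

        return self._make(s, (self,), backward)

    # --------------------------------------------------------------- reshaping
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        return self._make(self.data.reshape(shape), (self,),
                          lambda g: (g.reshape(orig),))

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        return self._make(self.data.transpose(axes), (self,),
                          lambda g: (g.transpose(inv),))

    def swapaxes(self, a: int, b: int):
        return self._make(np.swapaxes(self.data, a, b), (self,),
                          lambda g: (np.swapaxes(g, a, b),))

    def __getitem__(self, idx):
        data = self.data[idx]

        def backward(g):
            out = np.zeros_like(self.data)
            np.add.at(out, idx, g)
            return (out,)

        return self._make(data, (self,), backward)

    def maxpool1d(self, kernel: int, stride: int):
        """Max pooling along axis 1 of a (B, L, C) tensor.

        Requires L to be a multiple of `stride` windows of size `kernel`
        with kernel == stride (non-overlapping), which is the only case
        the network uses.
        """
        if kernel != stride:
            raise NotImplementedError("only non-overlapping pooling")
        b, length, c = self.data.shape
        n = length // kernel
        x = self.data[:, : n * kernel].reshape(b, n, kernel, c)
        arg = x.argmax(axis=2)
        data = np.take_along_axis(x, arg[:, :, None, :], axis=2)[:, :, 0, :]

        def backward(g):
            gx = np.zeros((b, n, kernel, c), dtype=self.data.dtype)
            np.put_along_axis(gx, arg[:, :, None, :], g[:, :, None, :], axis=2)
            out = np.zeros_like(self.data)
            out[:, : n * kernel] = gx.reshape(b, n * kernel, c)
            return (out,)

        return self._make(data, (self,), backward)

    # ----------------------------------------------------------------- engine
    def backward(self, grad=None, retain_graph: bool = False):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                if node.grad is None:
                    node.grad = g.copy()
                else:
                    node.grad = node.grad + g
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if not parent.requires_grad:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg
        if not retain_graph:
            # release the tape: closures capture large intermediates
            for node in topo:
                node._backward = None
                node._parents = ()


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Fused layer normalization over the last axis with analytic backward."""
    mu = x.data.mean(-1, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    data = xhat * gamma.data + beta.data

    def backward(g):
        gxh = g * gamma.data
        m1 = gxh.mean(-1, keepdims=True)
        m2 = (gxh * xhat).mean(-1, keepdims=True)
        gx = inv * (gxh - m1 - xhat * m2)
        axes = tuple(range(g.ndim - 1))
        return gx, (g * xhat).sum(axis=axes), g.sum(axis=axes)

    return x._make(data, (x, gamma, beta), backward)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    """Concatenate tensors along `axis` with gradient routing."""
    datas = [t.data for t in tensors]
    data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    out = Tensor(data)
    if _GRAD_ENABLED and any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        out._backward = lambda g: tuple(np.split(g, splits, axis=axis))
    return out
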