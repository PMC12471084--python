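"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the registration network needs: elementwise
arithmetic, matmul, reductions, shape ops, activations, and (in sibling
modules) custom ops for convolution, pooling, resizing, and warping.
Gradients are accumulated in float32 unless the forward data is float64.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "concat", "stack", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = [True]


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        _GRAD_ENABLED.append(False)
        return self

    def __exit__(self, *exc):
        _GRAD_ENABLED.pop()
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED[-1]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading axes
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    # sum axes that were size-1 in shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) and is_grad_enabled()
        self._backward = None
        self._parents = ()

    # -- plumbing ---------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self):
        return self.data.item()

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.array(
                np.broadcast_to(g, self.data.shape),
                dtype=np.result_type(self.data, np.float32),
            )
        else:
            self.grad += g

    def backward(self, grad=None):
        if grad is None:
            if self.size != 1:
                raise ValueError("backward() without gradient requires a scalar tensor")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    # -- op construction helper ------------------------------------------


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def make_op(out_data, parents, backward_fn) -> Tensor:
    """Create an output tensor with a backward closure.

    backward_fn(gy) must return a tuple of gradients aligned with `parents`
    (None entries allowed).
    """
    out = Tensor(out_data)
    req = is_grad_enabled() and any(p.requires_grad for p in parents)
    if req:
        out.requires_grad = True
        out._parents = tuple(p for p in parents if p.requires_grad)

        def _backward(gy):
            grads = backward_fn(gy)
            for p, g in zip(parents, grads):
                if p.requires_grad and g is not None:
                    p._accumulate(g)

        out._backward = _backward
    return out


# -- arithmetic -----------------------------------------------------------


def _add(a: Tensor, b: Tensor) -> Tensor:
    return make_op(
        a.data + b.data,
        (a, b),
        lambda gy: (_unbroadcast(gy, a.shape), _unbroadcast(gy, b.shape)),
    )


def _mul(a: Tensor, b: Tensor) -> Tensor:
    return make_op(
        a.data * b.data,
        (a, b),
        lambda gy: (
            _unbroadcast(gy * b.data, a.shape),
            _unbroadcast(gy * a.data, b.shape),
        ),
    )


def _pow(a: Tensor, n: float) -> Tensor:
    return make_op(
        a.data ** n,
        (a,),
        lambda gy: (gy * n * a.data ** (n - 1),),
    )


def _matmul(a: Tensor, b: Tensor) -> Tensor:
    def backward(gy):
        ad, bd = a.data, b.data
        if ad.ndim == 1:
            ga = gy @ np.swapaxes(bd, -1, -2) if bd.ndim > 1 else gy * bd
        else:
            ga = gy @ np.swapaxes(bd, -1, -2)
        gb = np.swapaxes(ad, -1, -2) @ gy if ad.ndim > 1 else np.outer(ad, gy)
        return _unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape)

    return make_op(a.data @ b.data, (a, b), backward)


Tensor.__add__ = lambda a, b: _add(a, as_tensor(b))
Tensor.__radd__ = lambda a, b: _add(as_tensor(b), a)
Tensor.__mul__ = lambda a, b: _mul(a, as_tensor(b))
Tensor.__rmul__ = lambda a, b: _mul(as_tensor(b), a)
Tensor.__neg__ = lambda a: _mul(a, Tensor(np.asarray(-1.0, dtype=a.data.dtype)))
Tensor.__sub__ = lambda a, b: _add(a, -as_tensor(b))
Tensor.__rsub__ = lambda a, b: _add(as_tensor(b), -a)
Tensor.__pow__ = _pow
Tensor.__truediv__ = lambda a, b: _mul(a, as_tensor(b) ** -1.0)
Tensor.__rtruediv__ = lambda a, b: _mul(as_tensor(b), a ** -1.0)
Tensor.__matmul__ = lambda a, b: _matmul(a, as_tensor(b))
Tensor.__rmatmul__ = lambda a, b: _matmul(as_tensor(b), a)


# -- reductions -----------------------------------------------------------


def _sum(a: Tensor, axis=None, keepdims=False) -> Tensor:
    def backward(gy):
        g = gy
        if axis is not None and not keepdims:
            ax = axis if isinstance(axis, tuple) else (axis,)
            ax = tuple(x % a.ndim for x in ax)
            g = np.expand_dims(g, ax)
        return (np.broadcast_to(g, a.shape).copy(),)

    return make_op(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)


def _mean(a: Tensor, axis=None, keepdims=False) -> Tensor:
    n = a.size if axis is None else np.prod(
        [a.shape[x % a.ndim] for x in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return _sum(a, axis=axis, keepdims=keepdims) * (1.0 / float(n))


def _max(a: Tensor, axis=None, keepdims=False) -> Tensor:
    out_data = a.data.max(axis=axis, keepdims=keepdims)

    def backward(gy):
        od, g = out_data, gy
        if axis is not None and not keepdims:
            ax = axis if isinstance(axis, tuple) else (axis,)
            ax = tuple(x % a.ndim for x in ax)
            od = np.expand_dims(od, ax)
            g = np.expand_dims(g, ax)
        mask = (a.data == od).astype(a.data.dtype)
        mask /= mask.sum(axis=axis, keepdims=True) if axis is not None else mask.sum()
        return (mask * g,)

    return make_op(out_data, (a,), backward)


Tensor.sum = _sum
Tensor.mean = _mean
Tensor.max = _max


# -- shape ops ------------------------------------------------------------


def _reshape(a: Tensor, *shape) -> Tensor:
    if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
        shape = tuple(shape[0])
    return make_op(a.data.reshape(shape), (a,), lambda gy: (gy.reshape(a.shape),))


def _transpose(a: Tensor, axes) -> Tensor:
    inv = np.argsort(axes)
    return make_op(
        a.data.transpose(axes), (a,), lambda gy: (gy.transpose(inv),)
    )


def _getitem(a: Tensor, idx) -> Tensor:
    def backward(gy):
        g = np.zeros_like(a.data, dtype=np.result_type(a.data, np.float32))
        np.add.at(g, idx, gy)
        return (g,)

    return make_op(a.data[idx], (a,), backward)


def concat(tensors, axis=0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offs = np.cumsum([0] + sizes)

    def backward(gy):
        grads = []
        for t, o, s in zip(tensors, offs[:-1], sizes):
            sl = [slice(None)] * gy.ndim
            sl[axis] = slice(o, o + s)
            grads.append(gy[tuple(sl)])
        return tuple(grads)

    return make_op(np.concatenate([t.data for t in tensors], axis=axis), tensors, backward)


def stack(tensors, axis=0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]

    def backward(gy):
        moved = np.moveaxis(gy, axis, 0)
        return tuple(moved[i] for i in range(len(tensors)))

    return make_op(np.stack([t.data for t in tensors], axis=axis), tensors, backward)


Tensor.reshape = _reshape
Tensor.transpose = _transpose
Tensor.__getitem__ = _getitem


# -- activations / elementwise functions ---------------------------------


def _exp(a: Tensor) -> Tensor:
    out_data = np.exp(a.data)
    return make_op(out_data, (a,), lambda gy: (gy * out_data,))


def _log(a: Tensor) -> Tensor:
    return make_op(np.log(a.data), (a,), lambda gy: (gy / a.data,))


def _sigmoid(a: Tensor) -> Tensor:
    out_data = 1.0 / (1.0 + np.exp(-a.data))
    return make_op(out_data, (a,), lambda gy: (gy * out_data * (1.0 - out_data),))


def _tanh(a: Tensor) -> Tensor:
    out_data = np.tanh(a.data)
    return make_op(out_data, (a,), lambda gy: (gy * (1.0 - out_data ** 2),))


def _leaky_relu(a: Tensor, slope: float = 0.2) -> Tensor:
    mask = np.where(a.data >= 0, 1.0, slope).astype(a.data.dtype)
    return make_op(a.data * mask, (a,), lambda gy: (gy * mask,))


def _relu(a: Tensor) -> Tensor:
    mask = (a.data > 0).astype(a.data.dtype)
    return make_op(a.data * mask, (a,), lambda gy: (gy * mask,))


def _softmax(a: Tensor, axis=-1) -> Tensor:
    z = a - Tensor(a.data.max(axis=axis, keepdims=True))
    e = _exp(z)
    return e / e.sum(axis=axis, keepdims=True)


Tensor.exp = _exp
Tensor.log = _log
Tensor.sigmoid = _sigmoid
Tensor.tanh = _tanh
Tensor.leaky_relu = _leaky_relu
Tensor.relu = _relu
Tensor.softmax = _softmax
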