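"""Reverse-mode automatic differentiation on NumPy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it so that :meth:`Tensor.backward` can propagate gradients through the tape.
Only the operations the segmentation network needs are implemented; all of
them support NumPy broadcasting where it makes sense.  Arrays are kept in
``float32`` by default — the convolution workloads are BLAS-bound and single
precision halves both time and memory.
"""

from __future__ import annotations

import contextlib

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def _as_array(value, dtype) -> np.ndarray:
    if dtype is None:
        arr = np.asarray(value)
        # keep float64 when the caller supplies it (oracle tests); default float32
        return arr if arr.dtype in (np.float32, np.float64) else arr.astype(np.float32)
    if isinstance(value, np.ndarray):
        return value.astype(dtype, copy=False)
    return np.asarray(value, dtype=dtype)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, dtype=None):
        self.data = _as_array(data, dtype)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._backward = None
        self._parents = ()

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def as_tensor(value, dtype=None) -> "Tensor":
        return value if isinstance(value, Tensor) else Tensor(value, dtype=dtype)

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

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph plumbing -------------------------------------------------------

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        """Create an op result; attaches the tape node only when tracking."""
        track = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        out = Tensor(data)
        if track:
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, grad: np.ndarray):
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar tensor")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()
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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        other = Tensor.as_tensor(other)
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
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other):
        other = Tensor.as_tensor(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.shape))

        return Tensor._make(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor.as_tensor(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g / b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(-g * a.data / (b.data * b.data), b.shape))

        return Tensor._make(a.data / b.data, (a, b), backward)

    def __rtruediv__(self, other):
        return Tensor.as_tensor(other) / self

    def __pow__(self, exponent: float):
        a = self
        out_data = a.data ** exponent

        def backward(g):
            a._accumulate(g * exponent * a.data ** (exponent - 1))

        return Tensor._make(out_data, (a,), backward)

    def __matmul__(self, other):
        other = Tensor.as_tensor(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accumulate(g @ b.data.swapaxes(-1, -2))
            if b.requires_grad:
                b._accumulate(a.data.swapaxes(-1, -2) @ g)

        return Tensor._make(a.data @ b.data, (a, b), backward)

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        a = self

        def backward(g):
            if axis is None:
                grad = np.broadcast_to(g, a.shape)
            else:
                g_exp = g if keepdims else np.expand_dims(g, axis)
                grad = np.broadcast_to(g_exp, a.shape)
            a._accumulate(grad)

        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[ax] for ax in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    # -- elementwise nonlinearities -------------------------------------------

    def clip(self, lo=None, hi=None):
        a = self
        out_data = np.clip(a.data, lo, hi)
        mask = np.ones_like(a.data)
        if lo is not None:
            mask = mask * (a.data > lo)
        if hi is not None:
            mask = mask * (a.data < hi)

        def backward(g):
            a._accumulate(g * mask)

        return Tensor._make(out_data, (a,), backward)

    def relu(self):
        a = self
        mask = a.data > 0

        def backward(g):
            a._accumulate(g * mask)

        return Tensor._make(a.data * mask, (a,), backward)

    def relu6(self):
        """min(max(x, 0), 6) — the MobileNetV2 activation."""
        return self.clip(0.0, 6.0)

    def sigmoid(self):
        a = self
        # clip to the float32-safe exp range; saturation is exact there anyway
        out_data = 1.0 / (1.0 + np.exp(-np.clip(a.data, -88.0, 88.0)))

        def backward(g):
            a._accumulate(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (a,), backward)

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
        return self ** 0.5

    def softmax(self, axis=-1):
        a = self
        shifted = a.data - a.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            a._accumulate(out_data * (g - dot))

        return Tensor._make(out_data, (a,), backward)

    # -- shape ops ------------------------------------------------------------

    def reshape(self, *shape):
        a = self
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def backward(g):
            a._accumulate(g.reshape(a.shape))

        return Tensor._make(a.data.reshape(shape), (a,), backward)

    def transpose(self, *axes):
        a = self
        axes = axes or None
        inv = np.argsort(axes) if axes else None

        def backward(g):
            a._accumulate(g.transpose(inv) if inv is not None else g.transpose())

        return Tensor._make(a.data.transpose(axes) if axes else a.data.T, (a,), backward)

    def pad2d(self, pad_h: tuple, pad_w: tuple):
        """Zero-pad the two spatial axes of an NHWC tensor."""
        a = self
        widths = ((0, 0), pad_h, pad_w, (0, 0))
        out_data = np.pad(a.data, widths)
        h0, h1 = pad_h
        w0, w1 = pad_w

        def backward(g):
            H, W = a.shape[1], a.shape[2]
            a._accumulate(g[:, h0:h0 + H, w0:w0 + W, :])

        return Tensor._make(out_data, (a,), backward)


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [Tensor.as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward
    )
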