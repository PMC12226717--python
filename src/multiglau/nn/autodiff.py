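"""Compact reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operator set the fusion networks need: broadcast
arithmetic, batched matmul, 2-D convolution and max-pooling, ReLU /
sigmoid / exp / log, reductions, reshaping, slicing and concatenation.
Gradients accumulate into ``Tensor.grad`` after ``backward()``.

``guided_relu_mode()`` switches every ReLU's backward rule to the
guided-backpropagation variant (gradients pass only where both the
forward activation and the incoming gradient are positive), which the
saliency module uses.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

__all__ = ["Tensor", "concat", "guided_relu_mode"]

_GUIDED = False


@contextmanager
def guided_relu_mode():
    """Within this context every ReLU backprops with the guided rule."""
    global _GUIDED
    prev = _GUIDED
    _GUIDED = True
    try:
        yield
    finally:
        _GUIDED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents: tuple = ()
        self._backward = None

    # -- plumbing ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    @staticmethod
    def _wrap(other):
        return other if isinstance(other, Tensor) else Tensor(other)

    @staticmethod
    def _result(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self, grad=None) -> None:
        if grad is None:
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
        self._accum(np.asarray(grad, dtype=np.float64))
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return self._result(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            if self.requires_grad:
                self._accum(-g)
        return self._result(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return self._result(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data ** 2, other.shape))

        return self._result(self.data / other.data, (self, other), bw)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, p: float):
        def bw(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))
        return self._result(self.data ** p, (self,), bw)

    def __matmul__(self, other):
        other = self._wrap(other)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.shape))

        return self._result(self.data @ other.data, (self, other), bw)

    # -- elementwise nonlinearities ------------------------------------
    def relu(self):
        mask = self.data > 0

        def bw(g):
            if self.requires_grad:
                gg = g * mask
                if _GUIDED:
                    gg = gg * (g > 0)
                self._accum(gg)

        return self._result(self.data * mask, (self,), bw)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def bw(g):
            if self.requires_grad:
                self._accum(g * s * (1.0 - s))

        return self._result(s, (self,), bw)

    def exp(self):
        e = np.exp(np.clip(self.data, -700, 700))

        def bw(g):
            if self.requires_grad:
                self._accum(g * e)

        return self._result(e, (self,), bw)

    def log(self):
        def bw(g):
            if self.requires_grad:
                self._accum(g / self.data)
        return self._result(np.log(self.data), (self,), bw)

    def sqrt(self):
        return self ** 0.5

    # -- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def bw(g):
            if not self.requires_grad:
                return
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                for ax in sorted(a % self.ndim for a in axes):
                    gg = np.expand_dims(gg, ax)
            self._accum(np.broadcast_to(gg, self.shape).copy())

        return self._result(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            count = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            count = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def max(self, axis, keepdims=False):
        """Max over a single axis; ties send gradient to the first argmax."""
        ax = axis % self.ndim
        idx = np.argmax(self.data, axis=ax)
        out = np.take_along_axis(self.data, np.expand_dims(idx, ax), ax)

        def bw(g):
            if not self.requires_grad:
                return
            gg = np.asarray(g)
            if not keepdims:
                gg = np.expand_dims(gg, ax)
            grad = np.zeros_like(self.data)
            np.put_along_axis(grad, np.expand_dims(idx, ax), gg, ax)
            self._accum(grad)

        return self._result(out if keepdims else np.squeeze(out, ax), (self,), bw)

    def softmax(self, axis=-1):
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    # -- shape ops -----------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def bw(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return self._result(self.data.reshape(shape), (self,), bw)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bw(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return self._result(self.data.transpose(axes), (self,), bw)

    def __getitem__(self, key):
        def bw(g):
            if self.requires_grad:
                grad = np.zeros_like(self.data)
                np.add.at(grad, key, g)
                self._accum(grad)

        return self._result(self.data[key], (self,), bw)

    # -- spatial primitives --------------------------------------------
    def conv2d(self, weight: "Tensor", bias: "Tensor" = None,
               stride: int = 1, padding: int = 0) -> "Tensor":
        """2-D cross-correlation: x (N,C,H,W) * w (F,C,kh,kw) -> (N,F,Ho,Wo)."""
        x, w = self.data, weight.data
        N, C, H, W = x.shape
        F, Cw, kh, kw = w.shape
        if C != Cw:
            raise ValueError(f"channel mismatch: input {C}, weight {Cw}")
        xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        Ho = (H + 2 * padding - kh) // stride + 1
        Wo = (W + 2 * padding - kw) // stride + 1
        wins = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
        wins = wins[:, :, ::stride, ::stride][:, :, :Ho, :Wo]  # N,C,Ho,Wo,kh,kw
        out = np.einsum("nchwij,fcij->nfhw", wins, w, optimize=True)
        if bias is not None:
            out = out + bias.data[None, :, None, None]
        parents = (self, weight) + ((bias,) if bias is not None else ())

        def bw(g):
            if weight.requires_grad:
                weight._accum(np.einsum("nfhw,nchwij->fcij", g, wins, optimize=True))
            if bias is not None and bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2, 3)))
            if self.requires_grad:
                dcols = np.einsum("nfhw,fcij->nchwij", g, w, optimize=True)
                dxp = np.zeros_like(xp)
                for i in range(kh):
                    for j in range(kw):
                        dxp[:, :, i:i + Ho * stride:stride,
                            j:j + Wo * stride:stride] += dcols[:, :, :, :, i, j]
                if padding:
                    dxp = dxp[:, :, padding:-padding, padding:-padding]
                self._accum(dxp)

        return self._result(out, parents, bw)

    def maxpool2d(self, kernel: int = 2, stride: int = None) -> "Tensor":
        stride = stride or kernel
        x = self.data
        N, C, H, W = x.shape
        Ho = (H - kernel) // stride + 1
        Wo = (W - kernel) // stride + 1
        wins = np.lib.stride_tricks.sliding_window_view(x, (kernel, kernel), axis=(2, 3))
        wins = wins[:, :, ::stride, ::stride][:, :, :Ho, :Wo]
        flat = wins.reshape(N, C, Ho, Wo, kernel * kernel)
        idx = np.argmax(flat, axis=-1)
        out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

        def bw(g):
            if not self.requires_grad:
                return
            grad = np.zeros_like(x)
            onehot = np.zeros_like(flat)
            np.put_along_axis(onehot, idx[..., None], g[..., None], axis=-1)
            onehot = onehot.reshape(N, C, Ho, Wo, kernel, kernel)
            for i in range(kernel):
                for j in range(kernel):
                    grad[:, :, i:i + Ho * stride:stride,
                         j:j + Wo * stride:stride] += onehot[:, :, :, :, i, j]
            self._accum(grad)

        return self._result(out, (self,), bw)


def concat(tensors: list, axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._result(np.concatenate([t.data for t in tensors], axis=axis),
                          tuple(tensors), bw)
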