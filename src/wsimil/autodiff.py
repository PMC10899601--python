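"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the tile encoder, projection head,
gated-attention pooling and task heads need: broadcasting elementwise
arithmetic, matmul, 2-D convolution (im2col), the usual activations,
reductions, concatenation and slicing.  Gradients are accumulated by a
topological backward sweep; every op's backward is checked against central
finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "tensor", "cat"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # -- graph construction helpers ------------------------------------
    @staticmethod
    def _wrap(other):
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data, parents, backward):
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    # -- arithmetic -----------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._wrap(other)

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __truediv__(self, other):
        return self * self._wrap(other).pow(-1.0)

    def __rtruediv__(self, other):
        return self._wrap(other) * self.pow(-1.0)

    def pow(self, p: float):
        def backward(g):
            return (g * p * np.power(self.data, p - 1.0),)

        return self._make(np.power(self.data, p), (self,), backward)

    def sqrt(self):
        return self.pow(0.5)

    def __matmul__(self, other):
        other = self._wrap(other)

        def backward(g):
            ga = g @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            return (_unbroadcast(ga, self.shape), _unbroadcast(gb, other.shape))

        return self._make(self.data @ other.data, (self, other), backward)

    # -- activations ----------------------------------------------------
    def relu(self):
        mask = self.data > 0

        def backward(g):
            return (g * mask,)

        return self._make(self.data * mask, (self,), backward)

    def tanh(self):
        out = np.tanh(self.data)

        def backward(g):
            return (g * (1.0 - out * out),)

        return self._make(out, (self,), backward)

    def sigmoid(self):
        out = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def backward(g):
            return (g * out * (1.0 - out),)

        return self._make(out, (self,), backward)

    def exp(self):
        out = np.exp(self.data)

        def backward(g):
            return (g * out,)

        return self._make(out, (self,), backward)

    def log(self):
        def backward(g):
            return (g / self.data,)

        return self._make(np.log(self.data), (self,), backward)

    # -- reductions / shape ---------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            gg = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(gg, self.shape).copy(),)

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        def backward(g):
            return (g.reshape(self.shape),)

        return self._make(self.data.reshape(*shape), (self,), backward)

    def transpose(self, *axes):
        axes = axes or None

        def backward(g):
            inv = np.argsort(axes) if axes else None
            return (g.transpose(inv) if inv is not None else g.T,)

        return self._make(self.data.transpose(axes), (self,), backward)

    @property
    def T(self):
        return self.transpose()

    def __getitem__(self, idx):
        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)

        return self._make(self.data[idx], (self,), backward)

    # -- composites used throughout the models --------------------------
    def logsumexp(self, axis=-1, keepdims=False):
        """Numerically stabilized log-sum-exp (max subtraction; the shift is
        treated as a constant, which has zero net gradient)."""
        m = np.max(self.data, axis=axis, keepdims=True)
        shifted = self + Tensor(-m)
        out = shifted.exp().sum(axis=axis, keepdims=True).log() + Tensor(m)
        if not keepdims:
            out = out.reshape(*np.squeeze(out.data, axis=axis).shape)
        return out

    def softmax(self, axis=-1):
        return (self - self.logsumexp(axis=axis, keepdims=True)).exp()

    def l2_normalize(self, axis=-1, eps=1e-12):
        norm = (self * self).sum(axis=axis, keepdims=True).pow(0.5)
        return self / (norm + eps)

    # -- backward sweep --------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def build(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                build(p)
            topo.append(t)

        build(self)
        for t in topo:
            t.grad = None
        self.grad = np.asarray(grad, dtype=np.float64)
        for t in reversed(topo):
            if t._backward is None:
                continue
            gs = t._backward(t.grad)
            for p, g in zip(t._parents, gs):
                if not p.requires_grad:
                    continue
                p.grad = g if p.grad is None else p.grad + g

    def detach(self):
        return Tensor(self.data.copy())

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def tensor(data, requires_grad=False):
    return Tensor(data, requires_grad=requires_grad)


def cat(tensors, axis=0):
    """Concatenate tensors along an axis (differentiable)."""
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    out = Tensor(np.concatenate(datas, axis=axis))
    out.requires_grad = any(t.requires_grad for t in tensors)
    if out.requires_grad:
        out._parents = tuple(tensors)

        def backward(g):
            return tuple(np.split(g, splits, axis=axis))

        out._backward = backward
    return out


# -- convolution ---------------------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1, pad: int = 0) -> Tensor:
    """2-D convolution, NCHW layout, via im2col.

    x: (B, C, H, W); w: (F, C, k, k); b: (F,).  Returns (B, F, Ho, Wo).
    """
    B, C, H, W = x.data.shape
    F, _, k, _ = w.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    Ho = (H + 2 * pad - k) // stride + 1
    Wo = (W + 2 * pad - k) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]                     # (B,C,Ho,Wo,k,k)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B, Ho * Wo, C * k * k)
    wmat = w.data.reshape(F, C * k * k)
    out = cols @ wmat.T + b.data                            # (B, Ho*Wo, F)
    out = out.transpose(0, 2, 1).reshape(B, F, Ho, Wo)

    res = Tensor(out)
    res.requires_grad = x.requires_grad or w.requires_grad or b.requires_grad
    if res.requires_grad:
        res._parents = (x, w, b)

        def backward(g):
            gf = g.reshape(B, F, Ho * Wo).transpose(0, 2, 1)    # (B,Ho*Wo,F)
            gw = np.einsum("bnf,bnc->fc", gf, cols).reshape(w.data.shape)
            gb = gf.sum(axis=(0, 1))
            gcols = gf @ wmat                                   # (B,Ho*Wo,C*k*k)
            gcols = gcols.reshape(B, Ho, Wo, C, k, k)
            gxp = np.zeros_like(xp)
            for i in range(k):
                for j in range(k):
                    gxp[:, :, i : i + Ho * stride : stride, j : j + Wo * stride : stride] += (
                        gcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                    )
            gx = gxp[:, :, pad : pad + H, pad : pad + W] if pad else gxp
            return gx, gw, gb

        res._backward = backward
    return res
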