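"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operator set the contact-map enhancement network
needs: broadcasting arithmetic, matmul, the pointwise nonlinearities
(GELU, SiLU, softplus), cumulative sums for the chunked state-space scan,
shape surgery (reshape/transpose/flip/slice/concat), and three structured
convolution primitives (same-padding k x k correlation, 2x2 stride-2
downsampling, 2x2 stride-2 transposed upsampling).  Gradients accumulate
into ``Tensor.grad`` after calling :meth:`Tensor.backward`.

The engine is deliberately eager and single-threaded: numerical
reproducibility (bit-identical forward passes for identical inputs) is a
contract of the surrounding package.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents = tuple(parents)
        self._backward = backward

    # -- bookkeeping ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        g = g.astype(self.data.dtype, copy=False)
        if self.grad is None:
            self.grad = g.copy() if g.base is not None else g
        else:
            self.grad = self.grad + g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor through the recorded graph."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free graph-internal gradients eagerly to bound memory
                if node._parents and node is not self:
                    node.grad = None
                node._backward = None
                node._parents = ()

    # -- arithmetic -----------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out_req = self.requires_grad or other.requires_grad
        out = Tensor(self.data + other.data, out_req, (self, other))
        if out_req:
            def bw(g):
                if self.requires_grad:
                    self._accumulate(_unbroadcast(g, self.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(g, other.shape))
            out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))
        if self.requires_grad:
            out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out_req = self.requires_grad or other.requires_grad
        out = Tensor(self.data * other.data, out_req, (self, other))
        if out_req:
            def bw(g):
                if self.requires_grad:
                    self._accumulate(_unbroadcast(g * other.data, self.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(g * self.data, other.shape))
            out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out_req = self.requires_grad or other.requires_grad
        out = Tensor(self.data / other.data, out_req, (self, other))
        if out_req:
            def bw(g):
                if self.requires_grad:
                    self._accumulate(_unbroadcast(g / other.data, self.shape))
                if other.requires_grad:
                    other._accumulate(
                        _unbroadcast(-g * self.data / (other.data ** 2), other.shape)
                    )
            out._backward = bw
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, self.requires_grad, (self,))
        if self.requires_grad:
            out._backward = lambda g: self._accumulate(g * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out_req = self.requires_grad or other.requires_grad
        out = Tensor(np.matmul(self.data, other.data), out_req, (self, other))
        if out_req:
            def bw(g):
                if self.requires_grad:
                    ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                    self._accumulate(_unbroadcast(ga, self.shape))
                if other.requires_grad:
                    gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                    other._accumulate(_unbroadcast(gb, other.shape))
            out._backward = bw
        return out

    # -- pointwise ------------------------------------------------------
    def exp(self):
        out = Tensor(np.exp(self.data), self.requires_grad, (self,))
        if self.requires_grad:
            out._backward = lambda g: self._accumulate(g * out.data)
        return out

    def expm1(self):
        out = Tensor(np.expm1(self.data), self.requires_grad, (self,))
        if self.requires_grad:
            out._backward = lambda g: self._accumulate(g * np.exp(self.data))
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, (self,))
        if self.requires_grad:
            out._backward = lambda g: self._accumulate(g / self.data)
        return out

    def abs(self):
        out = Tensor(np.abs(self.data), self.requires_grad, (self,))
        if self.requires_grad:
            out._backward = lambda g: self._accumulate(g * np.sign(self.data))
        return out

    def tanh(self):
        out = Tensor(np.tanh(self.data), self.requires_grad, (self,))
        if self.requires_grad:
            out._backward = lambda g: self._accumulate(g * (1.0 - out.data ** 2))
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, self.requires_grad, (self,))
        if self.requires_grad:
            out._backward = lambda g: self._accumulate(g * s * (1.0 - s))
        return out

    def softplus(self):
        out = Tensor(np.logaddexp(0.0, self.data), self.requires_grad, (self,))
        if self.requires_grad:
            s = 1.0 / (1.0 + np.exp(-self.data))
            out._backward = lambda g: self._accumulate(g * s)
        return out

    def gelu(self):
        # tanh approximation; gelu(0) == 0 exactly
        c = np.sqrt(2.0 / np.pi)
        x = self.data
        inner = c * (x + 0.044715 * x ** 3)
        t = np.tanh(inner)
        out = Tensor(0.5 * x * (1.0 + t), self.requires_grad, (self,))
        if self.requires_grad:
            def bw(g):
                dinner = c * (1.0 + 3 * 0.044715 * x ** 2)
                d = 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t ** 2) * dinner
                self._accumulate(g * d)
            out._backward = bw
        return out

    def silu(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(self.data * s, self.requires_grad, (self,))
        if self.requires_grad:
            out._backward = lambda g: self._accumulate(g * (s + self.data * s * (1 - s)))
        return out

    def clip(self, lo=None, hi=None):
        out = Tensor(np.clip(self.data, lo, hi), self.requires_grad, (self,))
        if self.requires_grad:
            mask = np.ones_like(self.data)
            if lo is not None:
                mask = mask * (self.data >= lo)
            if hi is not None:
                mask = mask * (self.data <= hi)
            out._backward = lambda g: self._accumulate(g * mask)
        return out

    def astype(self, dtype):
        out = Tensor(self.data.astype(dtype), self.requires_grad, (self,))
        if self.requires_grad:
            out._backward = lambda g: self._accumulate(g.astype(self.data.dtype))
        return out

    # -- reductions -----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))
        if self.requires_grad:
            def bw(g):
                if axis is not None and not keepdims:
                    axes = axis if isinstance(axis, tuple) else (axis,)
                    g = np.expand_dims(g, axes)
                self._accumulate(np.broadcast_to(g, self.shape))
            out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def cumsum(self, axis: int):
        out = Tensor(np.cumsum(self.data, axis=axis), self.requires_grad, (self,))
        if self.requires_grad:
            def bw(g):
                rev = np.flip(np.cumsum(np.flip(g, axis=axis), axis=axis), axis=axis)
                self._accumulate(rev)
            out._backward = bw
        return out

    # -- shape surgery --------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), self.requires_grad, (self,))
        if self.requires_grad:
            out._backward = lambda g: self._accumulate(g.reshape(self.shape))
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), self.requires_grad, (self,))
        if self.requires_grad:
            out._backward = lambda g: self._accumulate(g.transpose(inv))
        return out

    def flip(self, axis: int):
        out = Tensor(np.flip(self.data, axis=axis), self.requires_grad, (self,))
        if self.requires_grad:
            out._backward = lambda g: self._accumulate(np.flip(g, axis=axis))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], self.requires_grad, (self,))
        if self.requires_grad:
            def bw(g):
                full = np.zeros_like(self.data)
                full[idx] += g
                self._accumulate(full)
            out._backward = bw
        return out

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def concatenate(tensors: list[Tensor], axis: int) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    req = any(t.requires_grad for t in tensors)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), req, tuple(tensors))
    if req:
        sizes = [t.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)
        def bw(g):
            for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(a, b)
                    t._accumulate(g[tuple(sl)])
        out._backward = bw
    return out


def stack_sum(tensors: list[Tensor]) -> Tensor:
    """Elementwise sum of same-shape tensors."""
    out = tensors[0]
    for t in tensors[1:]:
        out = out + t
    return out


# -- structured convolutions -------------------------------------------

def conv2d(x: Tensor, w: Tensor, pad: int) -> Tensor:
    """Same-stride correlation of (B,Cin,H,W) with (Cout,Cin,k,k), stride 1."""
    xd, wd = x.data, w.data
    k = wd.shape[-1]
    if k == 1:
        # pointwise: pure channel matmul, much faster path
        B, C, H, W = xd.shape
        y = np.einsum("bchw,oc->bohw", xd, wd[:, :, 0, 0], optimize=True)
        req = x.requires_grad or w.requires_grad
        out = Tensor(y, req, (x, w))
        if req:
            def bw(g):
                if x.requires_grad:
                    x._accumulate(np.einsum("bohw,oc->bchw", g, wd[:, :, 0, 0],
                                            optimize=True))
                if w.requires_grad:
                    gw = np.einsum("bohw,bchw->oc", g, xd, optimize=True)
                    w._accumulate(gw[:, :, None, None])
            out._backward = bw
        return out
    xp = np.pad(xd, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # win: (B, Cin, Ho, Wo, k, k)
    y = np.einsum("bcijpq,ocpq->boij", win, wd, optimize=True)
    req = x.requires_grad or w.requires_grad
    out = Tensor(y, req, (x, w))
    if req:
        Ho, Wo = y.shape[2], y.shape[3]
        def bw(g):
            if w.requires_grad:
                gw = np.einsum("bcijpq,boij->ocpq", win, g, optimize=True)
                w._accumulate(gw)
            if x.requires_grad:
                gxp = np.zeros_like(xp)
                for p in range(k):
                    for q in range(k):
                        gxp[:, :, p:p + Ho, q:q + Wo] += np.einsum(
                            "boij,oc->bcij", g, wd[:, :, p, q], optimize=True)
                if pad:
                    gxp = gxp[:, :, pad:-pad, pad:-pad]
                x._accumulate(gxp)
        out._backward = bw
    return out


def down2x2(x: Tensor, w: Tensor) -> Tensor:
    """2x2 stride-2 convolution; w has shape (Cout, Cin, 2, 2)."""
    xd, wd = x.data, w.data
    B, C, H, W = xd.shape
    xr = xd.reshape(B, C, H // 2, 2, W // 2, 2)
    y = np.einsum("bcipjq,ocpq->boij", xr, wd, optimize=True)
    req = x.requires_grad or w.requires_grad
    out = Tensor(y, req, (x, w))
    if req:
        def bw(g):
            if x.requires_grad:
                gx = np.einsum("boij,ocpq->bcipjq", g, wd, optimize=True)
                x._accumulate(gx.reshape(B, C, H, W))
            if w.requires_grad:
                w._accumulate(np.einsum("bcipjq,boij->ocpq", xr, g, optimize=True))
        out._backward = bw
    return out


def up2x2(x: Tensor, w: Tensor) -> Tensor:
    """2x2 stride-2 transposed convolution; w has shape (Cin, Cout, 2, 2)."""
    xd, wd = x.data, w.data
    B, C, H, W = xd.shape
    y = np.einsum("bcij,copq->boipjq", xd, wd, optimize=True)
    O = wd.shape[1]
    yr = y.reshape(B, O, 2 * H, 2 * W)
    req = x.requires_grad or w.requires_grad
    out = Tensor(yr, req, (x, w))
    if req:
        def bw(g):
            gr = g.reshape(B, O, H, 2, W, 2).transpose(0, 1, 2, 4, 3, 5)
            # gr: (B, O, H, W, 2, 2)
            if x.requires_grad:
                x._accumulate(np.einsum("boijpq,copq->bcij", gr, wd, optimize=True))
            if w.requires_grad:
                w._accumulate(np.einsum("boijpq,bcij->copq", gr, xd, optimize=True))
        out._backward = bw
    return out
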