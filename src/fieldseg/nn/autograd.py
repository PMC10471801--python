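"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps a float32 ndarray and records the operations that
produced it on a tape; :meth:`Tensor.backward` replays the tape in reverse
topological order.  Only the operations needed by the segmentation network
are provided: broadcast arithmetic, the sigmoid/ReLU family, reductions,
2-D convolution (dense and depthwise, with stride/padding/dilation),
channel concatenation, bilinear resizing and a channel softmax.

Convolutions are lowered to matrix multiplies through an explicit im2col
built by looping over the (small) kernel support, so both the forward and
the column-scatter backward stay vectorised numpy.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv2d", "depthwise_conv2d", "bilinear_resize",
           "softmax_channels"]


def _as_f32(x) -> np.ndarray:
    a = np.asarray(x, dtype=np.float32)
    return a


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_f32(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- graph plumbing ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(_as_f32(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_graph(self) -> None:
        self._backward = None
        self._prev = ()
        self.grad = None

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(parents)
            out._backward = backward
        return out

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * np.float32(-1.0)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __truediv__(self, other):
        other = self._lift(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / (other.data ** 2), other.shape))

        return self._make(out_data, (self, other), backward)

    def square(self):
        return self * self

    # -- activations ------------------------------------------------------
    def relu(self):
        mask = self.data > 0
        out_data = self.data * mask

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return self._make(out_data, (self,), backward)

    def relu6(self):
        out_data = np.clip(self.data, 0.0, 6.0)
        mask = (self.data > 0) & (self.data < 6.0)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return self._make(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), backward)

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).astype(np.float32))
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).astype(np.float32))

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * np.float32(1.0 / n)

    def max_spatial(self):
        """Global max over the trailing (H, W) axes of an NCHW tensor."""
        n, c, h, w = self.shape
        flat = self.data.reshape(n, c, h * w)
        idx = flat.argmax(axis=2)
        out_data = np.take_along_axis(flat, idx[:, :, None], axis=2)[:, :, 0]
        out_data = out_data.reshape(n, c, 1, 1)

        def backward(g):
            if not self.requires_grad:
                return
            gi = np.zeros_like(flat)
            np.put_along_axis(gi, idx[:, :, None], g.reshape(n, c, 1), axis=2)
            self._accumulate(gi.reshape(self.shape))

        return self._make(out_data, (self,), backward)

    def reshape(self, *shape):
        out_data = self.data.reshape(*shape)
        orig = self.shape

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.reshape(orig))

        return self._make(out_data, (self,), backward)

    def broadcast_to(self, shape):
        out_data = np.broadcast_to(self.data, shape)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))

        return self._make(np.ascontiguousarray(out_data), (self,), backward)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


# -- structural ops -------------------------------------------------------

def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    out = Tensor(out_data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._prev = tuple(tensors)
        out._backward = backward
    return out


def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int, dilation: int,
            oh: int, ow: int) -> np.ndarray:
    """(N, C, Hp, Wp) padded input -> (N, C, kh, kw, oh, ow) columns."""
    n, c = xp.shape[:2]
    cols = np.empty((n, c, kh, kw, oh, ow), dtype=np.float32)
    for i in range(kh):
        for j in range(kw):
            hi = i * dilation
            wj = j * dilation
            cols[:, :, i, j] = xp[:, :, hi:hi + (oh - 1) * stride + 1:stride,
                                  wj:wj + (ow - 1) * stride + 1:stride]
    return cols


def _col_scatter(dcols: np.ndarray, xp_shape, kh, kw, stride, dilation, oh, ow):
    dxp = np.zeros(xp_shape, dtype=np.float32)
    for i in range(kh):
        for j in range(kw):
            hi = i * dilation
            wj = j * dilation
            dxp[:, :, hi:hi + (oh - 1) * stride + 1:stride,
                wj:wj + (ow - 1) * stride + 1:stride] += dcols[:, :, i, j]
    return dxp


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int | tuple[int, int] = 0,
           dilation: int = 1) -> Tensor:
    """Dense 2-D convolution; weight is (Cout, Cin, kh, kw)."""
    n, c, h, w = x.shape
    co, ci, kh, kw = weight.shape
    if ci != c:
        raise ValueError(f"conv2d channel mismatch: input {c}, weight {ci}")
    ph, pw = (padding, padding) if isinstance(padding, int) else padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    oh = (h + 2 * ph - dilation * (kh - 1) - 1) // stride + 1
    ow = (w + 2 * pw - dilation * (kw - 1) - 1) // stride + 1
    cols = _im2col(xp, kh, kw, stride, dilation, oh, ow)
    cols2 = cols.reshape(n, c * kh * kw, oh * ow)
    w2 = weight.data.reshape(co, c * kh * kw)
    out_data = np.matmul(w2, cols2).reshape(n, co, oh, ow)
    if bias is not None:
        out_data += bias.data.reshape(1, co, 1, 1)

    def backward(g):
        g2 = g.reshape(n, co, oh * ow)
        if weight.requires_grad:
            dw = np.matmul(g2, cols2.transpose(0, 2, 1)).sum(axis=0)
            weight._accumulate(dw.reshape(weight.shape))
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcols = np.matmul(w2.T, g2).reshape(n, c, kh, kw, oh, ow)
            dxp = _col_scatter(dcols, xp.shape, kh, kw, stride, dilation, oh, ow)
            if ph or pw:
                dxp = dxp[:, :, ph:ph + h, pw:pw + w]
            x._accumulate(dxp)

    parents = (x, weight) if bias is None else (x, weight, bias)
    out = Tensor(out_data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._prev = parents
        out._backward = backward
    return out


def depthwise_conv2d(x: Tensor, weight: Tensor, stride: int = 1,
                     padding: int = 0, dilation: int = 1) -> Tensor:
    """Depthwise convolution; weight is (C, kh, kw), one filter per channel."""
    n, c, h, w = x.shape
    cw, kh, kw = weight.shape
    if cw != c:
        raise ValueError("depthwise weight channels must match input")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    oh = (h + 2 * padding - dilation * (kh - 1) - 1) // stride + 1
    ow = (w + 2 * padding - dilation * (kw - 1) - 1) // stride + 1
    out_data = np.zeros((n, c, oh, ow), dtype=np.float32)
    views = {}
    for i in range(kh):
        for j in range(kw):
            hi, wj = i * dilation, j * dilation
            v = xp[:, :, hi:hi + (oh - 1) * stride + 1:stride,
                   wj:wj + (ow - 1) * stride + 1:stride]
            views[(i, j)] = v
            out_data += v * weight.data[None, :, i, j, None, None]

    def backward(g):
        if weight.requires_grad:
            dw = np.empty_like(weight.data)
            for (i, j), v in views.items():
                dw[:, i, j] = (g * v).sum(axis=(0, 2, 3))
            weight._accumulate(dw)
        if x.requires_grad:
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    hi, wj = i * dilation, j * dilation
                    dxp[:, :, hi:hi + (oh - 1) * stride + 1:stride,
                        wj:wj + (ow - 1) * stride + 1:stride] += \
                        g * weight.data[None, :, i, j, None, None]
            if padding:
                dxp = dxp[:, :, padding:padding + h, padding:padding + w]
            x._accumulate(dxp)

    out = Tensor(out_data)
    if x.requires_grad or weight.requires_grad:
        out.requires_grad = True
        out._prev = (x, weight)
        out._backward = backward
    return out


def _interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Row-stochastic (n_out, n_in) bilinear interpolation matrix
    (half-pixel centers, matching align_corners=False)."""
    m = np.zeros((n_out, n_in), dtype=np.float32)
    if n_in == 1:
        m[:, 0] = 1.0
        return m
    src = (np.arange(n_out, dtype=np.float64) + 0.5) * (n_in / n_out) - 0.5
    src = np.clip(src, 0.0, n_in - 1)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = (src - lo).astype(np.float32)
    m[np.arange(n_out), lo] += 1.0 - frac
    m[np.arange(n_out), hi] += frac
    return m


def bilinear_resize(x: Tensor, out_hw: tuple[int, int]) -> Tensor:
    n, c, h, w = x.shape
    oh, ow = out_hw
    if (oh, ow) == (h, w):
        return x
    mh = _interp_matrix(oh, h)
    mw = _interp_matrix(ow, w)
    tmp = np.einsum("oh,nchw->ncow", mh, x.data, optimize=True)
    out_data = np.einsum("pw,ncow->ncop", mw, tmp, optimize=True)

    def backward(g):
        if not x.requires_grad:
            return
        t = np.einsum("pw,ncop->ncow", mw, g, optimize=True)
        x._accumulate(np.einsum("oh,ncow->nchw", mh, t, optimize=True))

    out = Tensor(out_data)
    if x.requires_grad:
        out.requires_grad = True
        out._prev = (x,)
        out._backward = backward
    return out


def softmax_channels(x: Tensor) -> Tensor:
    """Softmax over axis 1 of an NCHW tensor."""
    z = x.data - x.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    out_data = e / e.sum(axis=1, keepdims=True)

    def backward(g):
        if x.requires_grad:
            dot = (g * out_data).sum(axis=1, keepdims=True)
            x._accumulate(out_data * (g - dot))

    out = Tensor(out_data)
    if x.requires_grad:
        out.requires_grad = True
        out._prev = (x,)
        out._backward = backward
    return out
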