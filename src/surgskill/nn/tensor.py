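"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operator set needed by the segmentation and scoring
networks: broadcasted arithmetic, matmul, reductions, elementwise
nonlinearities, reshaping/indexing, concatenation, 1-D/2-D convolution
(im2col) and nearest-neighbour upsampling. Gradients accumulate into
``Tensor.grad`` after ``backward()`` on a scalar.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "concatenate", "stack"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph bookkeeping -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        while stack:  # iterative DFS; graphs can be deep
            node = stack[-1]
            if id(node) in seen:
                stack.pop()
                continue
            pending = [p for p in node._parents
                       if p.requires_grad and id(p) not in seen]
            if pending:
                stack.extend(pending)
            else:
                seen.add(id(node))
                topo.append(node)
                stack.pop()
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    def _accum(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)

        def backward(g):
            self._accum(_unbroadcast(g, self.shape))
            other._accum(_unbroadcast(g, other.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)

        def backward(g):
            self._accum(_unbroadcast(g * other.data, self.shape))
            other._accum(_unbroadcast(g * self.data, other.shape))

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)

        def backward(g):
            self._accum(_unbroadcast(g / other.data, self.shape))
            other._accum(
                _unbroadcast(-g * self.data / other.data**2, other.shape))

        return self._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        def backward(g):
            self._accum(g * p * self.data ** (p - 1))

        return self._make(self.data**p, (self,), backward)

    def __matmul__(self, other):
        other = as_tensor(other)

        def backward(g):
            if self.requires_grad:
                gs = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(gs, self.shape))
            if other.requires_grad:
                go = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(go, other.shape))

        return self._make(self.data @ other.data, (self, other), backward)

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def backward(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims),
                          (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- elementwise nonlinearities ---------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accum(g * out_data)

        return self._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            self._accum(g * mask)

        return self._make(self.data * mask, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            self._accum(g * (1.0 - out_data**2))

        return self._make(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def backward(g):
            self._accum(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), backward)

    def softmax(self, axis: int = -1):
        """Numerically stable softmax along ``axis``."""
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            self._accum(out_data * (g - dot))

        return self._make(out_data, (self,), backward)

    def log_softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
        out_data = shifted - lse
        sm = np.exp(out_data)

        def backward(g):
            self._accum(g - sm * g.sum(axis=axis, keepdims=True))

        return self._make(out_data, (self,), backward)

    # -- shape manipulation ------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def backward(g):
            self._accum(g.reshape(old))

        return self._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            self._accum(g.transpose(inv))

        return self._make(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, idx):
        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        return self._make(self.data[idx], (self,), backward)

    # -- convolution -------------------------------------------------------
    def conv2d(self, weight: "Tensor", stride: int = 1, padding: int = 0):
        """2-D cross-correlation: self (B,C,H,W) with weight (O,C,kh,kw)."""
        x, w = self.data, weight.data
        B, C, H, W = x.shape
        O, _, kh, kw = w.shape
        if padding:
            x = np.pad(x, ((0, 0), (0, 0), (padding,) * 2, (padding,) * 2))
        Hp, Wp = x.shape[2], x.shape[3]
        Ho = (Hp - kh) // stride + 1
        Wo = (Wp - kw) // stride + 1
        s = x.strides
        cols = np.lib.stride_tricks.as_strided(
            x, (B, C, kh, kw, Ho, Wo),
            (s[0], s[1], s[2], s[3], s[2] * stride, s[3] * stride))
        cols2 = cols.reshape(B, C * kh * kw, Ho * Wo)
        out_data = (w.reshape(O, -1) @ cols2).reshape(B, O, Ho, Wo)

        def backward(g):
            g2 = g.reshape(B, O, Ho * Wo)
            if weight.requires_grad:
                gw = np.einsum("bof,bcf->oc", g2, cols2,
                               optimize=True).reshape(w.shape)
                weight._accum(gw)
            if self.requires_grad:
                dcols = np.einsum("oc,bof->bcf", w.reshape(O, -1), g2,
                                  optimize=True)
                dcols = dcols.reshape(B, C, kh, kw, Ho, Wo)
                gx = np.zeros((B, C, Hp, Wp))
                for i in range(kh):
                    for j in range(kw):
                        gx[:, :, i:i + Ho * stride:stride,
                           j:j + Wo * stride:stride] += dcols[:, :, i, j]
                if padding:
                    gx = gx[:, :, padding:-padding, padding:-padding]
                self._accum(gx)

        return self._make(out_data, (self, weight), backward)

    def conv1d(self, weight: "Tensor", stride: int = 1, padding: int = 0):
        """1-D cross-correlation: self (B,C,T) with weight (O,C,k)."""
        x4 = self.reshape(self.shape[0], self.shape[1], 1, self.shape[2])
        w4 = weight.reshape(weight.shape[0], weight.shape[1], 1,
                            weight.shape[2])
        out = Tensor.conv2d(x4, w4, stride=stride, padding=0) \
            if padding == 0 else None
        if padding:
            xp = _pad_last(self, padding)
            x4 = xp.reshape(xp.shape[0], xp.shape[1], 1, xp.shape[2])
            out = Tensor.conv2d(x4, w4, stride=stride, padding=0)
        return out.reshape(out.shape[0], out.shape[1], out.shape[3])

    def upsample2x(self):
        """Nearest-neighbour 2x spatial upsampling of a (B,C,H,W) map."""
        out_data = self.data.repeat(2, axis=2).repeat(2, axis=3)

        def backward(g):
            B, C, H2, W2 = g.shape
            gr = g.reshape(B, C, H2 // 2, 2, W2 // 2, 2).sum(axis=(3, 5))
            self._accum(gr)

        return self._make(out_data, (self,), backward)


def _pad_last(t: Tensor, p: int) -> Tensor:
    """Zero-pad the last axis of ``t`` by ``p`` on both sides."""
    pads = [(0, 0)] * (t.ndim - 1) + [(p, p)]

    def backward(g):
        sl = tuple(slice(None) for _ in range(t.ndim - 1)) + (slice(p, -p),)
        t._accum(g[sl])

    return t._make(np.pad(t.data, pads), (t,), backward)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concatenate(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)

        def backward(g):
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

        out._backward = backward
    return out


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors], axis=axis))
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)

        def backward(g):
            for i, t in enumerate(tensors):
                t._accum(np.take(g, i, axis=axis))

        out._backward = backward
    return out
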