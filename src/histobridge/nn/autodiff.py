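"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operations the denoising U-Net needs: broadcasting
arithmetic, matmul, 3x3/1x1 convolution via im2col, pooling/upsampling,
activations, reductions and concatenation.  Gradients are accumulated by a
topological backward sweep over the implicit tape built during the forward
pass.  Everything is deterministic: identical inputs and parameters give
bit-identical outputs and gradients.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "concat", "narrow", "conv2d", "avg_pool2d",
           "upsample_nearest"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = data if isinstance(data, np.ndarray) else np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = _parents
        self._backward = _backward

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    @staticmethod
    def _lift(other, like: "Tensor") -> "Tensor":
        if isinstance(other, Tensor):
            return other
        return Tensor(np.asarray(other, dtype=like.data.dtype))

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (default seed: ones)."""
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
                if id(p) not in seen:
                    stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self.grad = grad
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        # grads may be views/broadcasts; own the buffer before later += hits it
        if self.grad is None:
            self.grad = np.array(grad)
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = Tensor._lift(other, self)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def _bw(g):
            if self.requires_grad or self._parents:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad or other._parents:
                other._accum(_unbroadcast(g, other.data.shape))
        out._backward = _bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))

        def _bw(g):
            self._accum(-g)
        out._backward = _bw
        return out

    def __sub__(self, other):
        return self + (-Tensor._lift(other, self))

    def __rsub__(self, other):
        return Tensor._lift(other, self) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other, self)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def _bw(g):
            if self.requires_grad or self._parents:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad or other._parents:
                other._accum(_unbroadcast(g * self.data, other.data.shape))
        out._backward = _bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other, self)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return Tensor._lift(other, self) * self ** -1.0

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, self.requires_grad, (self,))

        def _bw(g):
            self._accum(g * p * self.data ** (p - 1.0))
        out._backward = _bw
        return out

    def __matmul__(self, other):
        other = Tensor._lift(other, self)
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def _bw(g):
            if self.requires_grad or self._parents:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad or other._parents:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape))
        out._backward = _bw
        return out

    # -------------------------------------------------------------- reshaping
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), self.requires_grad, (self,))

        def _bw(g):
            self._accum(g.reshape(self.data.shape))
        out._backward = _bw
        return out

    def transpose(self, *axes):
        out = Tensor(self.data.transpose(axes), self.requires_grad, (self,))
        inv = np.argsort(axes)

        def _bw(g):
            self._accum(g.transpose(inv))
        out._backward = _bw
        return out

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))

        def _bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())
        out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # ------------------------------------------------------------- activations
    def silu(self):
        sig = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(self.data * sig, self.requires_grad, (self,))

        def _bw(g):
            self._accum(g * (sig * (1.0 + self.data * (1.0 - sig))))
        out._backward = _bw
        return out

    def exp(self):
        e = np.exp(self.data)
        out = Tensor(e, self.requires_grad, (self,))

        def _bw(g):
            self._accum(g * e)
        out._backward = _bw
        return out

    def sqrt(self):
        return self ** 0.5

    def softmax_lastdim(self):
        """Numerically stable softmax over the last axis (max treated as constant)."""
        shifted = self - Tensor(self.data.max(axis=-1, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=-1, keepdims=True)


class Parameter(Tensor):
    """A leaf tensor updated by the optimizer."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


# ---------------------------------------------------------------------- concat
def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor(data, any(t.requires_grad or t._parents for t in tensors), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(a, b)
            t._accum(g[tuple(idx)])
    out._backward = _bw
    return out


def narrow(x: Tensor, axis: int, start: int, length: int) -> Tensor:
    """Contiguous slice ``x[..., start:start+length, ...]`` along `axis`."""
    idx = [slice(None)] * x.data.ndim
    idx[axis] = slice(start, start + length)
    idx = tuple(idx)
    out = Tensor(x.data[idx], x.requires_grad, (x,))

    def _bw(g):
        full = np.zeros_like(x.data)
        full[idx] = g
        x._accum(full)
    out._backward = _bw
    return out


# ------------------------------------------------------------------ conv2d ops
def _padded(x: np.ndarray, pad: int) -> np.ndarray:
    if not pad:
        return np.ascontiguousarray(x)
    b, c, h, w = x.shape
    xp = np.zeros((b, c, h + 2 * pad, w + 2 * pad), dtype=x.dtype)
    xp[:, :, pad:pad + h, pad:pad + w] = x
    return xp


def conv2d(x: Tensor, w: Tensor, b: Tensor, pad: int) -> Tensor:
    """Stride-1 'same'-style 2-D convolution, NCHW layout, square kernel.

    Computed as k*k shifted batched matmuls, which keeps every temporary at
    activation size (no im2col buffer) so the allocator recycles pages.
    """
    k = w.data.shape[-1]
    xp = _padded(x.data, pad)
    bsz, c, hp, wp = xp.shape
    h, wd = hp - k + 1, wp - k + 1
    o = w.data.shape[0]
    wk = w.data
    acc = np.zeros((bsz, o, h * wd), dtype=xp.dtype)
    for i in range(k):
        for j in range(k):
            slab = np.ascontiguousarray(xp[:, :, i:i + h, j:j + wd]
                                        ).reshape(bsz, c, h * wd)
            acc += wk[:, :, i, j] @ slab
    out_data = acc.reshape(bsz, o, h, wd) + b.data[None, :, None, None]
    out = Tensor(out_data, True, (x, w, b))
    del xp, acc

    def _bw(g):
        gm = np.ascontiguousarray(g).reshape(bsz, o, h * wd)
        gm_t = gm.transpose(0, 2, 1)
        xp2 = _padded(x.data, pad)
        need_dx = x.requires_grad or x._parents
        dxp = np.zeros_like(xp2) if need_dx else None
        dw = np.empty_like(wk)
        for i in range(k):
            for j in range(k):
                slab = np.ascontiguousarray(xp2[:, :, i:i + h, j:j + wd]
                                            ).reshape(bsz, c, h * wd)
                dw[:, :, i, j] = np.einsum("bcn,bno->oc", slab, gm_t,
                                           optimize=True)
                if need_dx:
                    dxp[:, :, i:i + h, j:j + wd] += (
                        wk[:, :, i, j].T @ gm).reshape(bsz, c, h, wd)
        w._accum(dw)
        b._accum(g.sum(axis=(0, 2, 3)))
        if need_dx:
            x._accum(dxp[:, :, pad:hp - pad, pad:wp - pad] if pad else dxp)
    out._backward = _bw
    return out


def avg_pool2d(x: Tensor, k: int = 2) -> Tensor:
    b, c, h, w = x.data.shape
    v = x.data.reshape(b, c, h // k, k, w // k, k).mean(axis=(3, 5))
    out = Tensor(v, x.requires_grad, (x,))

    def _bw(g):
        self_g = np.repeat(np.repeat(g, k, axis=2), k, axis=3) / (k * k)
        x._accum(self_g)
    out._backward = _bw
    return out


def upsample_nearest(x: Tensor, k: int = 2) -> Tensor:
    v = np.repeat(np.repeat(x.data, k, axis=2), k, axis=3)
    out = Tensor(v, x.requires_grad, (x,))
    b, c, h, w = x.data.shape

    def _bw(g):
        x._accum(g.reshape(b, c, h, k, w, k).sum(axis=(3, 5)))
    out._backward = _bw
    return out
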