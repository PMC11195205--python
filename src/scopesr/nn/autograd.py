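"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operations the restoration models and their training
loss need: broadcast arithmetic, 2-D convolution (im2col + GEMM), pixel
shuffle, average pooling, nearest-neighbour upsampling, separable blurring,
channel concatenation, ReLU and reductions. Tensors carry float32 data; the
backward pass walks a topologically sorted tape.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "concat", "conv2d"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and grad.shape[i] != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @staticmethod
    def _result(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))

        return self._result(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(-g)

        return self._result(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))

        return self._result(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))

        return self._result(self.data / other.data, (self, other), backward)

    def __pow__(self, exponent: float):
        out_data = self.data**exponent

        def backward(g, a=self, e=exponent, od=out_data):
            if a.requires_grad:
                a._accum(g * e * a.data ** (e - 1.0))

        return self._result(out_data, (self,), backward)

    # -- nonlinearities & reductions -------------------------------------------
    def relu(self):
        mask = self.data > 0

        def backward(g, a=self, m=mask):
            if a.requires_grad:
                a._accum(g * m)

        return self._result(self.data * mask, (self,), backward)

    def abs(self):
        sign = np.sign(self.data)

        def backward(g, a=self, s=sign):
            if a.requires_grad:
                a._accum(g * s)

        return self._result(np.abs(self.data), (self,), backward)

    def sum(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(np.full_like(a.data, float(g)))

        return self._result(self.data.sum(), (self,), backward)

    def mean(self):
        n = self.data.size

        def backward(g, a=self, n=n):
            if a.requires_grad:
                a._accum(np.full_like(a.data, float(g) / n))

        return self._result(self.data.mean(), (self,), backward)

    def mean_spatial(self):
        """Mean over all but the batch axis: (N, ...) -> (N,)."""
        n = int(np.prod(self.data.shape[1:]))

        def backward(g, a=self, n=n):
            if a.requires_grad:
                shape = (a.data.shape[0],) + (1,) * (a.data.ndim - 1)
                a._accum(np.broadcast_to(g.reshape(shape) / n, a.data.shape).copy())

        return self._result(self.data.reshape(self.data.shape[0], -1).mean(axis=1), (self,), backward)

    # -- structured ops ---------------------------------------------------------
    def pixel_shuffle(self, r: int):
        """(N, C*r^2, H, W) -> (N, C, H*r, W*r), sub-pixel rearrangement."""
        n, c2, h, w = self.data.shape
        c = c2 // (r * r)
        out_data = (
            self.data.reshape(n, c, r, r, h, w)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(n, c, h * r, w * r)
        )

        def backward(g, a=self, n=n, c=c, r=r, h=h, w=w):
            if a.requires_grad:
                gg = (
                    g.reshape(n, c, h, r, w, r)
                    .transpose(0, 1, 3, 5, 2, 4)
                    .reshape(n, c * r * r, h, w)
                )
                a._accum(gg)

        return self._result(out_data, (self,), backward)

    def avg_pool2(self):
        """2x2 average pooling with stride 2 (even extents required)."""
        n, c, h, w = self.data.shape
        if h % 2 or w % 2:
            raise ValueError(f"avg_pool2 requires even spatial extents, got ({h}, {w})")
        out_data = self.data.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

        def backward(g, a=self, n=n, c=c, h=h, w=w):
            if a.requires_grad:
                gg = np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) * 0.25
                a._accum(gg)

        return self._result(out_data, (self,), backward)

    def upsample_nearest(self, r: int):
        """(N, C, H, W) -> (N, C, H*r, W*r) by pixel replication."""
        out_data = np.repeat(np.repeat(self.data, r, axis=2), r, axis=3)

        def backward(g, a=self, r=r):
            if a.requires_grad:
                n, c, hr, wr = g.shape
                gg = g.reshape(n, c, hr // r, r, wr // r, r).sum(axis=(3, 5))
                a._accum(gg)

        return self._result(out_data, (self,), backward)

    def crop2d(self, h: int, w: int):
        """Crop the spatial axes to the leading (h, w) region."""
        out_data = self.data[:, :, :h, :w]

        def backward(g, a=self, h=h, w=w):
            if a.requires_grad:
                gg = np.zeros_like(a.data)
                gg[:, :, :h, :w] = g
                a._accum(gg)

        return self._result(out_data.copy(), (self,), backward)

    def blur1d(self, kernel: np.ndarray, axis: int):
        """Valid-mode correlation with a 1-D kernel along a spatial axis (2 or 3)."""
        k = kernel.astype(np.float32)
        taps = k.size
        ext = self.data.shape[axis]
        out_ext = ext - taps + 1
        if out_ext <= 0:
            raise ValueError(f"kernel of {taps} taps too large for extent {ext}")

        def sl(i, length):
            idx = [slice(None)] * 4
            idx[axis] = slice(i, i + length)
            return tuple(idx)

        shape = list(self.data.shape)
        shape[axis] = out_ext
        out_data = np.zeros(shape, dtype=np.float32)
        for i in range(taps):
            out_data += k[i] * self.data[sl(i, out_ext)]

        def backward(g, a=self, k=k, taps=taps, out_ext=out_ext):
            if a.requires_grad:
                gg = np.zeros_like(a.data)
                for i in range(taps):
                    gg[sl(i, out_ext)] += k[i] * g
                a._accum(gg)

        return self._result(out_data, (self,), backward)

    # -- autodiff machinery -----------------------------------------------------
    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.asarray(g, dtype=np.float32)
        else:
            self.grad = self.grad + g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)
                # free intermediate grads/tape to bound memory
                if node is not self:
                    node._backward = None


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward(g, ts=tensors, offs=offsets, axis=axis):
        for t, lo, hi in zip(ts, offs[:-1], offs[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accum(g[tuple(idx)])

    return Tensor._result(np.concatenate(datas, axis=axis), tuple(tensors), backward)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, padding: int = 0) -> Tensor:
    """2-D convolution (cross-correlation) via im2col and GEMM.

    x: (N, Cin, H, W); w: (Cout, Cin, k, k); b: (Cout,) or None.
    """
    n, cin, h, ww = x.data.shape
    cout, cin_w, kh, kw = w.data.shape
    if cin != cin_w:
        raise ValueError(f"channel mismatch: input {cin} vs weight {cin_w}")
    xp = (
        np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        if padding
        else x.data
    )
    hp, wp = xp.shape[2], xp.shape[3]
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n * ho * wo, cin * kh * kw
    )
    wmat = w.data.reshape(cout, -1)
    out = cols @ wmat.T
    if b is not None:
        out += b.data
    out_data = out.reshape(n, ho, wo, cout).transpose(0, 3, 1, 2)

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        go = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(n * ho * wo, cout)
        if w.requires_grad:
            w._accum((go.T @ cols).reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accum(go.sum(axis=0))
        if x.requires_grad:
            gcols = (go @ wmat).reshape(n, ho, wo, cin, kh, kw)
            gxp = np.zeros((n, cin, hp, wp), dtype=np.float32)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i : i + ho * stride : stride, j : j + wo * stride : stride] += (
                        gcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                    )
            if padding:
                gxp = gxp[:, :, padding:-padding, padding:-padding]
            x._accum(gxp)

    return Tensor._result(out_data, parents, backward)
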