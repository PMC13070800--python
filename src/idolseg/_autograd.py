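"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operator set the 3D segmentation network and its
composite loss need: same-padding 3D convolution (im2col + BLAS matmul, with
a fast path for 1x1x1 kernels), ReLU, channel concatenation, max pooling and
nearest-neighbour upsampling with per-axis factors, dropout, channel-axis
softmax, and the scalar arithmetic to assemble losses.  Activations and
weights are float32; a single sample is processed at a time (batch size 1
throughout the package).

Convolution gradients recompute the im2col matrix in the backward pass from
the saved input instead of caching it, trading a little compute for a large
reduction in peak memory on full-resolution feature maps.
"""

from __future__ import annotations

from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

__all__ = ["Tensor", "Adam"]


class Tensor:
    """Array node in the computation tape."""

    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    def __init__(
        self,
        data: np.ndarray,
        parents: Tuple["Tensor", ...] = (),
        backward: Optional[Callable[[np.ndarray], None]] = None,
        requires_grad: bool = False,
    ):
        self.data = np.asarray(data)
        self.grad: Optional[np.ndarray] = None
        self._parents = parents
        self._backward = backward
        self.requires_grad = requires_grad

    # -- graph machinery ---------------------------------------------------

    def backward(self) -> None:
        """Reverse-accumulate gradients from this (scalar) tensor."""
        topo: List[Tensor] = []
        seen = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.ones_like(self.data, dtype=np.float32)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=np.float32)
        self.grad += g

    def item(self) -> float:
        return float(self.data)

    # -- scalar / elementwise arithmetic ------------------------------------

    def __add__(self, other: "Tensor | float") -> "Tensor":
        if not isinstance(other, Tensor):
            out = Tensor(self.data + other, (self,))
            out._backward = lambda g, a=self: a._accum(g)
            return out
        out = Tensor(self.data + other.data, (self, other))

        def bw(g, a=self, b=other):
            a._accum(g)
            b._accum(g)

        out._backward = bw
        return out

    def __mul__(self, c: float) -> "Tensor":
        out = Tensor(self.data * c, (self,))
        out._backward = lambda g, a=self, c=c: a._accum(g * c)
        return out

    __rmul__ = __mul__

    def mul_arr(self, arr: np.ndarray) -> "Tensor":
        """Elementwise product with a constant array (no grad to the array)."""
        out = Tensor(self.data * arr, (self,))
        out._backward = lambda g, a=self, arr=arr: a._accum(g * arr)
        return out

    def rsub(self, c: float = 1.0) -> "Tensor":
        """c - t, elementwise."""
        out = Tensor(c - self.data, (self,))
        out._backward = lambda g, a=self: a._accum(-g)
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), (self,))
        out._backward = lambda g, a=self: a._accum(g / a.data)
        return out

    def clamp(self, lo: float, hi: float) -> "Tensor":
        """Clip values; the gradient passes straight through.

        Pass-through (rather than zeroing outside the range) keeps a learning
        signal at confidently-wrong voxels, where a hard-gated clamp would
        silence the loss gradient exactly where correction is needed.
        """
        out = Tensor(np.clip(self.data, lo, hi), (self,))
        out._backward = lambda g, a=self: a._accum(g)
        return out

    def sum(self) -> "Tensor":
        out = Tensor(np.float32(self.data.sum()), (self,))
        out._backward = lambda g, a=self: a._accum(
            np.full_like(a.data, g, dtype=np.float32)
        )
        return out

    def div(self, other: "Tensor") -> "Tensor":
        """Scalar division self/other."""
        out = Tensor(self.data / other.data, (self, other))

        def bw(g, a=self, b=other):
            a._accum(g / b.data)
            b._accum(-g * a.data / (b.data * b.data))

        out._backward = bw
        return out

    # -- neural-network ops --------------------------------------------------

    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0), (self,))
        mask = (self.data > 0).astype(np.float32)
        out._backward = lambda g, a=self, m=mask: a._accum(g * m)
        return out

    def slice_channel(self, c: int) -> "Tensor":
        out = Tensor(self.data[c], (self,))

        def bw(g, a=self, c=c):
            full = np.zeros_like(a.data, dtype=np.float32)
            full[c] = g
            a._accum(full)

        out._backward = bw
        return out

    def softmax_channels(self) -> "Tensor":
        """Softmax over axis 0 (the class axis) of a (C, X, Y, Z) tensor."""
        z = self.data - self.data.max(axis=0, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=0, keepdims=True)
        out = Tensor(p.astype(np.float32), (self,))

        def bw(g, a=self, p=p):
            dot = (g * p).sum(axis=0, keepdims=True)
            a._accum((p * (g - dot)).astype(np.float32))

        out._backward = bw
        return out

    def log_softmax_channels(self) -> "Tensor":
        """Log-softmax over axis 0, numerically fused (bounded gradients)."""
        z = self.data - self.data.max(axis=0, keepdims=True)
        lse = np.log(np.exp(z).sum(axis=0, keepdims=True))
        lp = (z - lse).astype(np.float32)
        out = Tensor(lp, (self,))

        def bw(g, a=self, lp=lp):
            p = np.exp(lp)
            a._accum((g - p * g.sum(axis=0, keepdims=True)).astype(np.float32))

        out._backward = bw
        return out

    def exp(self) -> "Tensor":
        e = np.exp(self.data).astype(np.float32)
        out = Tensor(e, (self,))
        out._backward = lambda g, a=self, e=e: a._accum(g * e)
        return out

    def dropout(self, rate: float, rng: np.random.Generator) -> "Tensor":
        if rate <= 0:
            return self
        keep = (rng.random(self.data.shape) >= rate).astype(np.float32)
        scale = 1.0 / (1.0 - rate)
        out = Tensor(self.data * keep * scale, (self,))
        out._backward = lambda g, a=self, k=keep, s=scale: a._accum(g * k * s)
        return out

    def max_pool(self, factors: Tuple[int, int, int]) -> "Tensor":
        """Non-overlapping max pooling over the three spatial axes."""
        C, X, Y, Z = self.data.shape
        fx, fy, fz = factors
        if X % fx or Y % fy or Z % fz:
            raise ValueError(
                f"spatial shape {(X, Y, Z)} not divisible by pool factors {factors}"
            )
        Xo, Yo, Zo = X // fx, Y // fy, Z // fz
        win = (
            self.data.reshape(C, Xo, fx, Yo, fy, Zo, fz)
            .transpose(0, 1, 3, 5, 2, 4, 6)
            .reshape(C, Xo, Yo, Zo, fx * fy * fz)
        )
        idx = win.argmax(axis=-1)
        out_data = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
        out = Tensor(out_data, (self,))

        def bw(g, a=self, idx=idx):
            gw = np.zeros((C, Xo, Yo, Zo, fx * fy * fz), dtype=np.float32)
            np.put_along_axis(gw, idx[..., None], g[..., None], axis=-1)
            gx = (
                gw.reshape(C, Xo, Yo, Zo, fx, fy, fz)
                .transpose(0, 1, 4, 2, 5, 3, 6)
                .reshape(C, X, Y, Z)
            )
            a._accum(gx)

        out._backward = bw
        return out

    def upsample(self, factors: Tuple[int, int, int]) -> "Tensor":
        """Nearest-neighbour upsampling by integer per-axis factors."""
        fx, fy, fz = factors
        d = np.repeat(np.repeat(np.repeat(self.data, fx, 1), fy, 2), fz, 3)
        out = Tensor(d, (self,))
        C, X, Y, Z = self.data.shape

        def bw(g, a=self):
            gs = g.reshape(C, X, fx, Y, fy, Z, fz).sum(axis=(2, 4, 6))
            a._accum(gs.astype(np.float32))

        out._backward = bw
        return out


def concat(tensors: Sequence[Tensor]) -> Tensor:
    """Concatenate along the channel axis (0)."""
    out = Tensor(np.concatenate([t.data for t in tensors], axis=0), tuple(tensors))
    sizes = [t.data.shape[0] for t in tensors]

    def bw(g):
        off = 0
        for t, s in zip(tensors, sizes):
            t._accum(g[off : off + s])
            off += s

    out._backward = bw
    return out


def _xcorr3(xd: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Same-padded cross-correlation of (C, X, Y, Z) with (Cout, C, kx, ky, kz).

    One (Cout, C) GEMM per kernel offset plus a shifted accumulation into the
    output; avoids materializing an im2col matrix (which would inflate the
    activation k^3-fold and is memory-bandwidth bound at these sizes).
    """
    C, X, Y, Z = xd.shape
    Cout, _, k0, k1, k2 = w.shape
    p0, p1, p2 = k0 // 2, k1 // 2, k2 // 2
    xp = np.pad(xd, ((0, 0), (p0, p0), (p1, p1), (p2, p2)))
    Xp, Yp, Zp = xp.shape[1:]
    xf = xp.reshape(C, -1)
    y = np.zeros((Cout, X, Y, Z), dtype=np.float32)
    for i in range(k0):
        for j in range(k1):
            for l in range(k2):
                u = (w[:, :, i, j, l] @ xf).reshape(Cout, Xp, Yp, Zp)
                y += u[:, i : i + X, j : j + Y, l : l + Z]
    return y


def _xcorr3_w_grad(xd: np.ndarray, g: np.ndarray, kshape: Tuple[int, ...]) -> np.ndarray:
    """Weight gradient of :func:`_xcorr3`: dW[...,i,j,l] = g * shifted input."""
    C, X, Y, Z = xd.shape
    Cout = g.shape[0]
    k0, k1, k2 = kshape
    p0, p1, p2 = k0 // 2, k1 // 2, k2 // 2
    gp = np.pad(g, ((0, 0), (p0, p0), (p1, p1), (p2, p2)))
    xf = xd.reshape(C, -1).T  # (N, C), contiguous input
    dw = np.empty((Cout, C, k0, k1, k2), dtype=np.float32)
    for i in range(k0):
        for j in range(k1):
            for l in range(k2):
                gs = gp[
                    :, 2 * p0 - i : 2 * p0 - i + X,
                    2 * p1 - j : 2 * p1 - j + Y,
                    2 * p2 - l : 2 * p2 - l + Z,
                ].reshape(Cout, -1)
                dw[:, :, i, j, l] = gs @ xf
    return dw


def conv3d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Same-padding 3D convolution (cross-correlation) of a (C, X, Y, Z) map."""
    C, X, Y, Z = x.data.shape
    Cout, Cin, kx, ky, kz = w.data.shape
    if Cin != C:
        raise ValueError(f"conv3d channel mismatch: input {C}, weight expects {Cin}")
    if (kx, ky, kz) == (1, 1, 1):
        xm = x.data.reshape(C, -1)
        Wm = w.data.reshape(Cout, Cin)
        y = (Wm @ xm).reshape(Cout, X, Y, Z) + b.data[:, None, None, None]
        out = Tensor(y.astype(np.float32), (x, w, b))

        def bw1(g, x=x, w=w, b=b, Wm=Wm, xm=xm):
            gm = g.reshape(Cout, -1)
            w._accum((gm @ xm.T).reshape(w.data.shape).astype(np.float32))
            b._accum(gm.sum(axis=1).astype(np.float32))
            x._accum((Wm.T @ gm).reshape(x.data.shape).astype(np.float32))

        out._backward = bw1
        return out

    y = _xcorr3(x.data, w.data) + b.data[:, None, None, None]
    out = Tensor(y.astype(np.float32), (x, w, b))

    def bw(g, x=x, w=w, b=b):
        g = np.ascontiguousarray(g, dtype=np.float32)
        w._accum(_xcorr3_w_grad(x.data, g, (kx, ky, kz)))
        b._accum(g.sum(axis=(1, 2, 3)).astype(np.float32))
        # grad wrt input of a same-padded cross-correlation is the
        # same-padded cross-correlation of g with the spatially flipped
        # kernel, channel axes swapped
        w_flip = np.ascontiguousarray(
            w.data[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
        )
        x._accum(_xcorr3(g, w_flip))

    out._backward = bw
    return out


class Adam:
    """Adam optimizer with the standard moment defaults."""

    def __init__(
        self,
        params: Sequence[Tensor],
        lr: float = 1e-3,
        betas: Tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data, dtype=np.float32) for p in self.params]
        self.v = [np.zeros_like(p.data, dtype=np.float32) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
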