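"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the displacement-field predictor needs:
3D convolution (kernel 3, zero padding), 1x1x1 channel mixing, leaky ReLU,
2x average pooling, 2x nearest-neighbour upsampling, channel
concatenation, trilinear warping of a constant image by a predicted field,
mean-squared error and the forward-difference smoothness penalty.  All
arrays are float32 channel-first ``(C, D, H, W)``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam"]


class Tensor:
    __slots__ = ("data", "grad", "parents", "_backward", "requires_grad")

    def __init__(self, data, parents=(), backward=None, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.parents = tuple(parents)
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in self.parents)

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.asarray(g, dtype=np.float32).copy()
        else:
            self.grad += g

    def backward(self):
        if self.data.ndim != 0:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t.parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.asarray(1.0, dtype=np.float32)
        for t in reversed(topo):
            if t._backward is not None and t.requires_grad and t.grad is not None:
                t._backward(t.grad)

    # -- scalar arithmetic (for combining loss terms) --
    def __add__(self, other):
        if not isinstance(other, Tensor):
            other = Tensor(np.float32(other))

        def bw(g):
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(g)

        return Tensor(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __mul__(self, scalar: float):
        s = float(scalar)

        def bw(g):
            self._accum(g * s)

        return Tensor(self.data * s, (self,), bw)

    __rmul__ = __mul__


def parameter(data) -> Tensor:
    return Tensor(data, requires_grad=True)


def conv3(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """3x3x3 convolution with zero padding 1. x: (C,D,H,W), w: (O,C,3,3,3).

    Implemented as 27 shifted channel-mixing matmuls (one BLAS sgemm per
    kernel tap), which is far faster on a single core than materialising
    the im2col window matrix.
    """
    C, D, H, W = x.shape
    O = w.shape[0]
    xp = np.pad(x.data, ((0, 0), (1, 1), (1, 1), (1, 1)))
    y = np.zeros((O, D * H * W), dtype=np.float32)
    for i in range(3):
        for j in range(3):
            for k in range(3):
                sh = np.ascontiguousarray(xp[:, i : i + D, j : j + H, k : k + W]).reshape(C, -1)
                y += w.data[:, :, i, j, k] @ sh
    y = y.reshape(O, D, H, W) + b.data[:, None, None, None]

    def bw(g):
        g2 = np.ascontiguousarray(g).reshape(O, -1)
        if w.requires_grad:
            gw = np.empty((O, C, 3, 3, 3), dtype=np.float32)
            for i in range(3):
                for j in range(3):
                    for k in range(3):
                        sh = np.ascontiguousarray(
                            xp[:, i : i + D, j : j + H, k : k + W]
                        ).reshape(C, -1)
                        gw[:, :, i, j, k] = g2 @ sh.T
            w._accum(gw)
        if b.requires_grad:
            b._accum(g2.sum(axis=1))
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for i in range(3):
                for j in range(3):
                    for k in range(3):
                        gxp[:, i : i + D, j : j + H, k : k + W] += (
                            w.data[:, :, i, j, k].T @ g2
                        ).reshape(C, D, H, W)
            x._accum(gxp[:, 1:-1, 1:-1, 1:-1])

    return Tensor(y, (x, w, b), bw)


def conv1(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """1x1x1 channel-mixing convolution. w: (O,C)."""
    y = np.einsum("cdhw,oc->odhw", x.data, w.data, optimize=True)
    y += b.data[:, None, None, None]

    def bw(g):
        if w.requires_grad:
            w._accum(np.einsum("odhw,cdhw->oc", g, x.data, optimize=True))
        if b.requires_grad:
            b._accum(g.sum(axis=(1, 2, 3)))
        if x.requires_grad:
            x._accum(np.einsum("odhw,oc->cdhw", g, w.data, optimize=True))

    return Tensor(y, (x, w, b), bw)


def leaky_relu(x: Tensor, slope: float = 0.2) -> Tensor:
    pos = x.data > 0
    y = np.where(pos, x.data, slope * x.data)

    def bw(g):
        x._accum(np.where(pos, g, np.float32(slope) * g))

    return Tensor(y, (x,), bw)


def avgpool2(x: Tensor) -> Tensor:
    c, d, h, w = x.shape
    y = x.data.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2).mean(axis=(2, 4, 6))

    def bw(g):
        gx = np.broadcast_to(
            g[:, :, None, :, None, :, None] / 8.0,
            (c, d // 2, 2, h // 2, 2, w // 2, 2),
        ).reshape(c, d, h, w)
        x._accum(gx)

    return Tensor(y, (x,), bw)


def upsample2(x: Tensor) -> Tensor:
    y = x.data.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)

    def bw(g):
        c, d, h, w = x.shape
        x._accum(g.reshape(c, d, 2, h, 2, w, 2).sum(axis=(2, 4, 6)))

    return Tensor(y, (x,), bw)


def concat(a: Tensor, b: Tensor) -> Tensor:
    na = a.shape[0]

    def bw(g):
        if a.requires_grad:
            a._accum(g[:na])
        if b.requires_grad:
            b._accum(g[na:])

    return Tensor(np.concatenate([a.data, b.data], axis=0), (a, b), bw)


def _trilinear_gather(m: np.ndarray, coords: np.ndarray):
    """Sample ``m`` (D,H,W) at absolute positions ``coords`` (3,D,H,W),
    clamping to the edge.  Returns the sampled values and the partial
    derivatives of the sample w.r.t. each coordinate."""
    n = m.shape
    inside = np.ones(coords.shape[1:], dtype=np.float32)
    idx0, frac = [], []
    for a in range(3):
        c = np.clip(coords[a], 0.0, n[a] - 1)
        inside *= ((coords[a] > 0.0) & (coords[a] < n[a] - 1)).astype(np.float32)
        i0 = np.clip(np.floor(c).astype(np.int64), 0, n[a] - 2)
        idx0.append(i0)
        frac.append((c - i0).astype(np.float32))
    fx, fy, fz = frac
    i0, j0, k0 = idx0
    c000 = m[i0, j0, k0]
    c001 = m[i0, j0, k0 + 1]
    c010 = m[i0, j0 + 1, k0]
    c011 = m[i0, j0 + 1, k0 + 1]
    c100 = m[i0 + 1, j0, k0]
    c101 = m[i0 + 1, j0, k0 + 1]
    c110 = m[i0 + 1, j0 + 1, k0]
    c111 = m[i0 + 1, j0 + 1, k0 + 1]
    c00 = c000 + fz * (c001 - c000)
    c01 = c010 + fz * (c011 - c010)
    c10 = c100 + fz * (c101 - c100)
    c11 = c110 + fz * (c111 - c110)
    c0 = c00 + fy * (c01 - c00)
    c1 = c10 + fy * (c11 - c10)
    out = c0 + fx * (c1 - c0)
    dx = (c1 - c0) * inside
    d0 = c01 - c00
    d1 = c11 - c10
    dy = (d0 + fx * (d1 - d0)) * inside
    e00 = c001 - c000
    e01 = c011 - c010
    e10 = c101 - c100
    e11 = c111 - c110
    e0 = e00 + fy * (e01 - e00)
    e1 = e10 + fy * (e11 - e10)
    dz = (e0 + fx * (e1 - e0)) * inside
    return out, (dx, dy, dz)


def warp(moving: np.ndarray, phi: Tensor) -> Tensor:
    """Trilinear warp of a constant single-channel image by the field phi
    (3,D,H,W), pull convention with clamp-to-edge sampling; differentiable
    in phi."""
    m = np.asarray(moving, dtype=np.float32)
    shape = phi.shape[1:]
    base = np.indices(shape, dtype=np.float32)
    coords = base + phi.data
    out, (dx, dy, dz) = _trilinear_gather(m, coords)

    def bw(g):
        phi._accum(np.stack([g * dx, g * dy, g * dz]))

    return Tensor(out, (phi,), bw)


def mse(pred: Tensor, target: np.ndarray) -> Tensor:
    t = np.asarray(target, dtype=np.float32)
    diff = pred.data - t
    n = diff.size

    def bw(g):
        pred._accum((2.0 / n) * g * diff)

    return Tensor(np.float32((diff.astype(np.float64) ** 2).mean()), (pred,), bw)


def smoothness(phi: Tensor) -> Tensor:
    """(1/3) sum over axes of the per-voxel mean of squared forward
    differences, summed over the three displacement components; the
    forward difference off the last slice is taken as zero."""
    n = phi.data[0].size
    total = 0.0
    diffs = []
    for axis in (1, 2, 3):
        d = np.diff(phi.data, axis=axis)
        diffs.append((axis, d))
        total += (d.astype(np.float64) ** 2).sum() / n
    total /= 3.0

    def bw(g):
        grad = np.zeros_like(phi.data)
        for axis, d in diffs:
            gd = (2.0 / (3.0 * n)) * g * d
            lo = [slice(None)] * 4
            hi = [slice(None)] * 4
            lo[axis] = slice(None, -1)
            hi[axis] = slice(1, None)
            grad[tuple(lo)] -= gd
            grad[tuple(hi)] += gd
        phi._accum(grad)

    return Tensor(np.float32(total), (phi,), bw)


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params, lr=0.01, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
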