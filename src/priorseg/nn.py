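"""Minimal 3D conv-net building blocks on numpy with explicit backprop.

The networks in this package run on CPU via BLAS: convolutions are lowered
to im2col patch matrices and a single sgemm per layer, and every layer
implements ``forward(x, train)`` / ``backward(grad_out) -> grad_in`` with
parameter gradients accumulated in place. Tensors are single-sample,
channel-first ``(C, D, H, W)`` float32 — batch size 1 throughout, matching
the training protocol.

Design notes
------------
* Anisotropic strides ``(1, 2, 2)`` keep the slice axis untouched, so all
  down/upsampling acts in-plane only.
* Batch normalization with batch size 1 normalizes each channel over its
  spatial extent and keeps running moments for deterministic eval passes.
* Trilinear upsampling with scale ``(1, 2, 2)`` is separable linear
  interpolation along H and W (align_corners=False convention), applied as
  two small fixed matrices; its backward pass is the exact transpose.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "Param",
    "Conv3d",
    "BatchNorm3d",
    "ReLU",
    "LeakyReLU",
    "UpsampleInPlane2x",
    "ConvBlock",
    "ResBlock",
    "Adam",
    "sigmoid",
    "bce_with_logits",
    "l1_loss",
]

Stride = Tuple[int, int, int]


class Param:
    """A trainable tensor with an accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.ascontiguousarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Module:
    def params(self) -> List[Param]:
        return []

    def buffers(self) -> List[np.ndarray]:
        """Non-trainable state (e.g. normalization running moments)."""
        return []

    def zero_grad(self) -> None:
        for p in self.params():
            p.zero_grad()


class Conv3d(Module):
    """3D convolution, kernel 3x3x3 or 1x1x1, 'same' padding, optional stride.

    Lowered to a single GEMM against a ``(k^3 * c_in, N)`` patch buffer
    filled by strided slice copies (rows stay W-contiguous, so the gather is
    a sequence of memcpys rather than a scattered transpose); the backward
    pass reuses the cached buffer for the weight gradient and scatters the
    input gradient through k^3 strided slice-adds.
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int = 3,
        stride: Stride = (1, 1, 1),
        bias: bool = True,
        rng: Optional[np.random.Generator] = None,
    ):
        rng = rng or np.random.default_rng(0)
        self.c_in, self.c_out = c_in, c_out
        self.k = kernel
        self.stride = stride
        fan_in = c_in * kernel**3
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, kernel, kernel, kernel))
        self.weight = Param(w)
        self.bias = Param(np.zeros(c_out)) if bias else None
        self._cache = None
        # persistent scratch buffers: layer shapes are fixed across steps,
        # so reusing them avoids large-allocation churn on every call
        self._bufs: dict = {}

    def _scratch(self, key: str, shape: Tuple[int, ...]) -> np.ndarray:
        buf = self._bufs.get(key)
        if buf is None or buf.shape != shape:
            buf = np.empty(shape, dtype=np.float32)
            self._bufs[key] = buf
        return buf

    def params(self) -> List[Param]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def _wmat(self) -> np.ndarray:
        # rows of the patch buffer run (offset, channel), so weights are
        # reordered to (c_out, k^3 * c_in) with the offset index outermost
        return np.ascontiguousarray(
            self.weight.data.transpose(0, 2, 3, 4, 1).reshape(self.c_out, -1)
        )

    def _patch_buffer(self, xp: np.ndarray, out_shape: Tuple[int, int, int]) -> np.ndarray:
        k, (sd, sh, sw) = self.k, self.stride
        do, ho, wo = out_shape
        c = self.c_in
        buf = self._scratch("patch", (k**3 * c, do * ho * wo))
        bufv = buf.reshape(k**3, c, do, ho, wo)
        idx = 0
        for kd in range(k):
            for kh in range(k):
                for kw in range(k):
                    bufv[idx] = xp[
                        :,
                        kd : kd + sd * do : sd,
                        kh : kh + sh * ho : sh,
                        kw : kw + sw * wo : sw,
                    ]
                    idx += 1
        return buf

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        k, (sd, sh, sw) = self.k, self.stride
        pad = k // 2
        if pad:
            c, d, h, w = x.shape
            xp = self._scratch("xpad", (c, d + 2 * pad, h + 2 * pad, w + 2 * pad))
            xp[...] = 0.0
            xp[:, pad:-pad, pad:-pad, pad:-pad] = x
        else:
            xp = x
        _, dp, hp, wp = xp.shape
        do = (dp - k) // sd + 1
        ho = (hp - k) // sh + 1
        wo = (wp - k) // sw + 1
        if k == 1 and self.stride == (1, 1, 1):
            buf = np.ascontiguousarray(x).reshape(self.c_in, -1)
        else:
            buf = self._patch_buffer(xp, (do, ho, wo))
        out = self._scratch("out", (self.c_out, do * ho * wo))
        np.matmul(self._wmat(), buf, out=out)
        if self.bias is not None:
            out += self.bias.data[:, None]
        if train:
            self._cache = (buf, x.shape, (do, ho, wo))
        return out.reshape(self.c_out, do, ho, wo)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        buf, xshape, (do, ho, wo) = self._cache
        k, (sd, sh, sw) = self.k, self.stride
        pad = k // 2
        gmat = gout.reshape(self.c_out, -1)
        gw = gmat @ buf.T  # (c_out, k^3 * c_in)
        self.weight.grad += gw.reshape(self.c_out, k, k, k, self.c_in).transpose(0, 4, 1, 2, 3)
        if self.bias is not None:
            self.bias.grad += gout.sum(axis=(1, 2, 3))
        gbuf = self._scratch("gbuf", (k**3 * self.c_in, gmat.shape[1]))
        np.matmul(self._wmat().T, gmat, out=gbuf)
        if k == 1 and self.stride == (1, 1, 1):
            return gbuf.reshape(xshape).copy()
        cdim, d, h, w = xshape
        gxp = self._scratch("gxp", (cdim, d + 2 * pad, h + 2 * pad, w + 2 * pad))
        gxp[...] = 0.0
        gbufv = gbuf.reshape(k**3, cdim, do, ho, wo)
        idx = 0
        for kd in range(k):
            for kh in range(k):
                for kw in range(k):
                    gxp[
                        :,
                        kd : kd + sd * do : sd,
                        kh : kh + sh * ho : sh,
                        kw : kw + sw * wo : sw,
                    ] += gbufv[idx]
                    idx += 1
        if pad:
            return gxp[:, pad:-pad, pad:-pad, pad:-pad]
        return gxp


class BatchNorm3d(Module):
    """Per-channel normalization over the spatial extent (batch size 1)."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._cache = None

    def params(self) -> List[Param]:
        return [self.gamma, self.beta]

    def buffers(self) -> List[np.ndarray]:
        return [self.running_mean, self.running_var]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        c = x.shape[0]
        flat = x.reshape(c, -1)
        if train:
            mean = flat.mean(axis=1)
            var = flat.var(axis=1)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (flat - mean[:, None]) * invstd[:, None]
        out = self.gamma.data[:, None] * xhat + self.beta.data[:, None]
        self._cache = (xhat, invstd, x.shape, train)
        return out.reshape(x.shape).astype(np.float32)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        xhat, invstd, shape, train = self._cache
        c = shape[0]
        gy = gout.reshape(c, -1)
        self.gamma.grad += (gy * xhat).sum(axis=1)
        self.beta.grad += gy.sum(axis=1)
        gxhat = gy * self.gamma.data[:, None]
        if not train:
            return (gxhat * invstd[:, None]).reshape(shape).astype(np.float32)
        n = gy.shape[1]
        gx = (
            invstd[:, None]
            / n
            * (
                n * gxhat
                - gxhat.sum(axis=1, keepdims=True)
                - xhat * (gxhat * xhat).sum(axis=1, keepdims=True)
            )
        )
        return gx.reshape(shape).astype(np.float32)


class ReLU(Module):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, gout, 0.0).astype(np.float32)


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x).astype(np.float32)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, gout, self.slope * gout).astype(np.float32)


def _linear_upsample_matrix(n: int) -> np.ndarray:
    """(2n, n) linear-interpolation matrix, align_corners=False convention."""
    u = np.zeros((2 * n, n), dtype=np.float32)
    for i in range(2 * n):
        s = (i + 0.5) / 2.0 - 0.5
        i0 = int(np.floor(s))
        w1 = s - i0
        u[i, min(max(i0, 0), n - 1)] += 1.0 - w1
        u[i, min(max(i0 + 1, 0), n - 1)] += w1
    return u


class UpsampleInPlane2x(Module):
    """Trilinear upsampling with scale (1, 2, 2): linear in H and W, z kept."""

    def __init__(self):
        self._mats: dict[int, np.ndarray] = {}

    def _mat(self, n: int) -> np.ndarray:
        if n not in self._mats:
            self._mats[n] = _linear_upsample_matrix(n)
        return self._mats[n]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        _, _, h, w = x.shape
        uh, uw = self._mat(h), self._mat(w)
        self._hw = (h, w)
        y = np.einsum("hk,cdkw->cdhw", uh, x, optimize=True)
        y = np.einsum("wk,cdhk->cdhw", uw, y, optimize=True)
        return np.ascontiguousarray(y, dtype=np.float32)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        h, w = self._hw
        uh, uw = self._mat(h), self._mat(w)
        g = np.einsum("kw,cdhk->cdhw", uw, gout, optimize=True)
        g = np.einsum("kh,cdkw->cdhw", uh, g, optimize=True)
        return np.ascontiguousarray(g, dtype=np.float32)


class ConvBlock(Module):
    """Conv3D -> BatchNorm -> activation (the basic convolutional unit)."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        stride: Stride = (1, 1, 1),
        act: str = "relu",
        norm: bool = True,
        rng: Optional[np.random.Generator] = None,
    ):
        self.conv = Conv3d(c_in, c_out, kernel=3, stride=stride, bias=not norm, rng=rng)
        self.norm = BatchNorm3d(c_out) if norm else None
        if act == "relu":
            self.act: Optional[Module] = ReLU()
        elif act == "lrelu":
            self.act = LeakyReLU(0.2)
        elif act == "none":
            self.act = None
        else:
            raise ValueError(f"unknown activation {act!r}")

    def params(self) -> List[Param]:
        out = self.conv.params()
        if self.norm is not None:
            out += self.norm.params()
        return out

    def buffers(self) -> List[np.ndarray]:
        return self.norm.buffers() if self.norm is not None else []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        y = self.conv.forward(x, train)
        if self.norm is not None:
            y = self.norm.forward(y, train)
        if self.act is not None:
            y = self.act.forward(y, train)
        return y

    def backward(self, gout: np.ndarray) -> np.ndarray:
        g = gout
        if self.act is not None:
            g = self.act.backward(g)
        if self.norm is not None:
            g = self.norm.backward(g)
        return self.conv.backward(g)


class ResBlock(Module):
    """Two conv-norm-ReLU units with an identity (or 1x1x1-projected) shortcut."""

    def __init__(self, c_in: int, c_out: int, rng: Optional[np.random.Generator] = None):
        self.block1 = ConvBlock(c_in, c_out, rng=rng)
        self.conv2 = Conv3d(c_out, c_out, kernel=3, bias=False, rng=rng)
        self.norm2 = BatchNorm3d(c_out)
        self.proj = None
        if c_in != c_out:
            self.proj = Conv3d(c_in, c_out, kernel=1, bias=False, rng=rng)
        self.out_act = ReLU()

    def params(self) -> List[Param]:
        out = self.block1.params() + self.conv2.params() + self.norm2.params()
        if self.proj is not None:
            out += self.proj.params()
        return out

    def buffers(self) -> List[np.ndarray]:
        return self.block1.buffers() + self.norm2.buffers()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        y = self.block1.forward(x, train)
        y = self.norm2.forward(self.conv2.forward(y, train), train)
        short = x if self.proj is None else self.proj.forward(x, train)
        return self.out_act.forward(y + short, train)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        g = self.out_act.backward(gout)
        gshort = g if self.proj is None else self.proj.backward(g)
        gmain = self.block1.backward(self.conv2.backward(self.norm2.backward(g)))
        return gmain + gshort


class Adam:
    """Adam with bias correction; state per parameter."""

    def __init__(
        self,
        params: Sequence[Param],
        lr: float = 4e-4,
        betas: Tuple[float, float] = (0.5, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1.0 - self.b1) * (p.grad - m)
            v += (1.0 - self.b2) * (p.grad**2 - v)
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out.astype(np.float32)


def bce_with_logits(logits: np.ndarray, target: float | np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy with logits and its gradient w.r.t. logits."""
    t = np.broadcast_to(np.asarray(target, dtype=np.float64), logits.shape)
    x = logits.astype(np.float64)
    loss = np.maximum(x, 0.0) - x * t + np.log1p(np.exp(-np.abs(x)))
    grad = (sigmoid(logits).astype(np.float64) - t) / logits.size
    return float(loss.mean()), grad.astype(np.float32)


def l1_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean absolute error and its (sub)gradient w.r.t. ``pred``."""
    diff = pred.astype(np.float64) - target.astype(np.float64)
    grad = np.sign(diff) / pred.size
    return float(np.abs(diff).mean()), grad.astype(np.float32)
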