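"""Three-branch CNN + GRU emotion classifier.

Architecture: two identical 1D-CNN branches (respiration and heartbeat
series), one 2D-CNN branch applied per facial keyframe, parallel feature
fusion along the feature axis, a GRU with 64 hidden units over the fused
sequence, and a dense softmax over the four emotions.

Each CNN block is convolution -> max pooling -> batch normalization -> ELU.
The 1D branch blocks are conv(5,16,s1)+pool(4,s4), conv(5,32,s1)+pool(2,s2),
conv(5,32,s2)+pool(2,s2), conv(5,64,s2)+pool(2,s2); the 2D branch blocks are
conv(3x3,32,s1)+pool(2x2,s2), conv(3x3,64,s1)+pool(2x2,s2),
conv(3x3,96,s1)+pool(4x4,s4), conv(3x3,96,s1)+pool(4x4,s4), followed by a
global average over the spatial axes (one 96-vector per keyframe).

Convolutions use 'same' padding (output length ceil(L/stride)); pooling is
floor-mode (incomplete trailing windows dropped). For a 1200-sample series
the temporal axis shrinks 1200 -> 300 -> 150 -> 75 -> 37 -> 19 -> 9; a
227x227 image shrinks 227 -> 113 -> 56 -> 14 -> 3 spatially.

Everything (forward, backprop, Adam) is implemented on NumPy arrays; the
network is small enough that BLAS matmuls via im2col carry the load.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .synthgen import EMOTIONS

# float32 keeps the matmuls on the fast BLAS path; tests may flip to float64
# for tight numeric gradient checks.
DTYPE = np.float32

LABEL_TO_INDEX = {lab: i for i, lab in enumerate(EMOTIONS)}


# ---------------------------------------------------------------------------
# specs and containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConvBlockSpec:
    """(conv kernel, filters, conv stride, pool kernel, pool stride)."""

    kernel: int | tuple
    filters: int
    conv_stride: int
    pool_kernel: int
    pool_stride: int


@dataclass(frozen=True)
class BranchSpec:
    blocks: tuple


BRANCH_1D = BranchSpec(blocks=(
    ConvBlockSpec(5, 16, 1, 4, 4),
    ConvBlockSpec(5, 32, 1, 2, 2),
    ConvBlockSpec(5, 32, 2, 2, 2),
    ConvBlockSpec(5, 64, 2, 2, 2),
))

BRANCH_2D = BranchSpec(blocks=(
    ConvBlockSpec((3, 3), 32, 1, 2, 2),
    ConvBlockSpec((3, 3), 64, 1, 2, 2),
    ConvBlockSpec((3, 3), 96, 1, 4, 4),
    ConvBlockSpec((3, 3), 96, 1, 4, 4),
))

GRU_UNITS = 64
N_CLASSES = len(EMOTIONS)


@dataclass
class EmotionSample:
    """One classifier input: two vital-sign series, a keyframe stack, a label."""

    respiration: np.ndarray   # (L,)
    heartbeat: np.ndarray     # (L,)
    keyframes: np.ndarray     # (F, 227, 227, 3) uint8 or float
    label: str
    subject_id: int = 0
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.respiration = np.asarray(self.respiration, dtype=DTYPE)
        self.heartbeat = np.asarray(self.heartbeat, dtype=DTYPE)
        if self.respiration.shape != self.heartbeat.shape:
            raise ValueError("respiration and heartbeat must have the same length")
        kf = np.asarray(self.keyframes)
        if kf.ndim != 4 or kf.shape[1:] != (227, 227, 3):
            raise ValueError("keyframes must be (F, 227, 227, 3)")
        if self.label not in LABEL_TO_INDEX:
            raise ValueError(f"unknown label {self.label!r}")
        self.keyframes = kf


@dataclass
class TrainConfig:
    epochs: int = 30
    batch_size: int = 16
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    seed: int = 0
    val_fraction: float = 0.15

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("epochs, batch_size, learning_rate must be positive")
        if not (0.0 <= self.val_fraction < 1.0):
            raise ValueError("val_fraction must be in [0, 1)")


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(DTYPE)
        self.grad = np.zeros_like(self.value)


def _same_pad(length: int, kernel: int, stride: int) -> tuple[int, int, int]:
    out = -(-length // stride)  # ceil
    total = max((out - 1) * stride + kernel - length, 0)
    return out, total // 2, total - total // 2


class Layer:
    def params(self) -> list[Param]:
        return []


class Conv1D(Layer):
    """1-D convolution, channels-last (B, L, C), 'same' padding.

    Computed as a sum over kernel offsets of strided-slice matmuls, which
    keeps every memory access contiguous (no im2col gather).
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int,
                 rng: np.random.Generator):
        scale = np.sqrt(2.0 / (kernel * in_ch))
        self.w = Param(rng.normal(0, scale, size=(kernel, in_ch, out_ch)))
        self.b = Param(np.zeros(out_ch))
        self.kernel, self.stride = kernel, stride
        self.in_ch, self.out_ch = in_ch, out_ch

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        bsz, length, _ = x.shape
        out, pl, pr = _same_pad(length, self.kernel, self.stride)
        xp = np.zeros((bsz, pl + length + pr, self.in_ch), dtype=DTYPE)
        xp[:, pl:pl + length] = x
        s = self.stride
        # im2col: (B, out, k, C) filled by k strided-slice copies
        cols = np.empty((bsz, out, self.kernel, self.in_ch), dtype=DTYPE)
        for p in range(self.kernel):
            cols[:, :, p] = xp[:, p:p + (out - 1) * s + 1:s]
        cols = cols.reshape(bsz, out, self.kernel * self.in_ch)
        wmat = self.w.value.reshape(self.kernel * self.in_ch, self.out_ch)
        y = cols.reshape(bsz * out, -1) @ wmat + self.b.value
        self._cache = (cols, x.shape, pl, out)
        return y.reshape(bsz, out, self.out_ch)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, xshape, pl, out = self._cache
        bsz, length, _ = xshape
        self.b.grad += dy.sum(axis=(0, 1))
        dyf = dy.reshape(bsz * out, self.out_ch)
        colf = cols.reshape(bsz * out, -1)
        self.w.grad += (colf.T @ dyf).reshape(self.w.value.shape)
        wmat = self.w.value.reshape(self.kernel * self.in_ch, self.out_ch)
        dcols = (dyf @ wmat.T).reshape(bsz, out, self.kernel, self.in_ch)
        dxp = np.zeros((bsz, pl + length + max(
            0, (out - 1) * self.stride + self.kernel - pl - length),
            self.in_ch), dtype=DTYPE)
        s = self.stride
        for p in range(self.kernel):
            dxp[:, p:p + (out - 1) * s + 1:s] += dcols[:, :, p]
        return dxp[:, pl:pl + length]


class Conv2D(Layer):
    """2-D convolution, channels-last (B, H, W, C), 'same' padding, stride 1.

    Same shift-and-matmul strategy as Conv1D: one (B*H*W, Cin) @ (Cin, Cout)
    product per kernel offset.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: tuple[int, int],
                 rng: np.random.Generator):
        kh, kw = kernel
        scale = np.sqrt(2.0 / (kh * kw * in_ch))
        self.w = Param(rng.normal(0, scale, size=(kh, kw, in_ch, out_ch)))
        self.b = Param(np.zeros(out_ch))
        self.kh, self.kw = kh, kw
        self.in_ch, self.out_ch = in_ch, out_ch

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        bsz, h, w, _ = x.shape
        _, pt, pb = _same_pad(h, self.kh, 1)
        _, pleft, pright = _same_pad(w, self.kw, 1)
        xp = np.zeros((bsz, h + pt + pb, w + pleft + pright, self.in_ch),
                      dtype=DTYPE)
        xp[:, pt:pt + h, pleft:pleft + w] = x
        wk = self.w.value.reshape(self.kh * self.kw, self.in_ch, self.out_ch)
        y = np.tile(self.b.value, (bsz * h * w, 1))
        o = 0
        for p in range(self.kh):
            for q in range(self.kw):
                y += xp[:, p:p + h, q:q + w].reshape(-1, self.in_ch) @ wk[o]
                o += 1
        self._cache = (xp, x.shape, (pt, pleft))
        return y.reshape(bsz, h, w, self.out_ch)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp, xshape, (pt, pleft) = self._cache
        bsz, h, w, _ = xshape
        self.b.grad += dy.sum(axis=(0, 1, 2))
        dyf = dy.reshape(bsz * h * w, self.out_ch)
        wk = self.w.value.reshape(self.kh * self.kw, self.in_ch, self.out_ch)
        wg = self.w.grad.reshape(self.kh * self.kw, self.in_ch, self.out_ch)
        dxp = np.zeros_like(xp)
        o = 0
        for p in range(self.kh):
            for q in range(self.kw):
                xs = xp[:, p:p + h, q:q + w].reshape(-1, self.in_ch)
                wg[o] += xs.T @ dyf
                dxp[:, p:p + h, q:q + w] += (dyf @ wk[o].T).reshape(
                    bsz, h, w, self.in_ch)
                o += 1
        return dxp[:, pt:pt + h, pleft:pleft + w]


class MaxPool1D(Layer):
    """Floor-mode max pooling with stride == kernel (non-overlapping)."""

    def __init__(self, kernel: int, stride: int):
        if kernel != stride:
            raise ValueError("only non-overlapping pooling is supported")
        self.k = kernel

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        bsz, length, ch = x.shape
        out = length // self.k
        xr = x[:, :out * self.k].reshape(bsz, out, self.k, ch)
        idx = xr.argmax(axis=2)
        self._cache = (x.shape, idx, out)
        return np.take_along_axis(xr, idx[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xshape, idx, out = self._cache
        bsz, length, ch = xshape
        dxr = np.zeros((bsz, out, self.k, ch), dtype=DTYPE)
        np.put_along_axis(dxr, idx[:, :, None, :], dy[:, :, None, :], axis=2)
        dx = np.zeros(xshape, dtype=DTYPE)
        dx[:, :out * self.k] = dxr.reshape(bsz, out * self.k, ch)
        return dx


class MaxPool2D(Layer):
    """Floor-mode 2-D max pooling with stride == kernel (power of two).

    Implemented as repeated 2x2 halvings built from elementwise maxima, with
    boolean winner masks cached for backprop (ties route to the earliest
    window element, matching argmax conventions). A 4x4 pool is two halvings.
    """

    def __init__(self, kernel: int, stride: int):
        if kernel != stride:
            raise ValueError("only non-overlapping pooling is supported")
        if kernel < 2 or kernel & (kernel - 1):
            raise ValueError("pool kernel must be a power of two >= 2")
        self.k = kernel

    @staticmethod
    def _halve(x: np.ndarray):
        a = x[:, 0::2, 0::2]
        b = x[:, 0::2, 1::2]
        c = x[:, 1::2, 0::2]
        d = x[:, 1::2, 1::2]
        m_top = np.maximum(a, b)
        m_bot = np.maximum(c, d)
        y = np.maximum(m_top, m_bot)
        return y, (b > a, d > c, m_bot > m_top)

    @staticmethod
    def _unhalve(dy: np.ndarray, sel, shape) -> np.ndarray:
        right_top, right_bot, bottom = sel
        bsz, h, w, ch = shape
        oh, ow = dy.shape[1], dy.shape[2]
        top = np.where(bottom, 0, dy)
        bot = dy - top
        # interleave left/right along W, then even/odd rows along H, so every
        # write into dx is a full contiguous row
        dx = np.empty((bsz, oh, 2, ow, 2, ch), dtype=DTYPE)
        dx[:, :, 0, :, 0] = np.where(right_top, 0, top)
        dx[:, :, 0, :, 1] = np.where(right_top, top, 0)
        dx[:, :, 1, :, 0] = np.where(right_bot, 0, bot)
        dx[:, :, 1, :, 1] = np.where(right_bot, bot, 0)
        return dx.reshape(bsz, h, w, ch)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        k = self.k
        bsz, h, w, ch = x.shape
        oh, ow = h // k, w // k
        y = x[:, :oh * k, :ow * k]
        cropped_shape = y.shape
        sels = []
        for _ in range(k.bit_length() - 1):
            sels.append(y.shape)
            y, sel = self._halve(y)
            sels.append(sel)
        self._cache = (x.shape, cropped_shape, sels)
        return np.ascontiguousarray(y)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xshape, cropped_shape, sels = self._cache
        d = dy
        for i in range(len(sels) - 2, -1, -2):
            d = self._unhalve(d, sels[i + 1], sels[i])
        if cropped_shape == xshape:
            return d
        dx = np.zeros(xshape, dtype=DTYPE)
        dx[:, :cropped_shape[1], :cropped_shape[2]] = d
        return dx


class BatchNorm(Layer):
    """Per-channel normalization over all non-channel axes (channels last)."""

    def __init__(self, ch: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(ch))
        self.beta = Param(np.zeros(ch))
        self.running_mean = np.zeros(ch, dtype=DTYPE)
        self.running_var = np.ones(ch, dtype=DTYPE)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var)
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean) / std
        self._cache = (xhat, std, axes, x.shape, train)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, std, axes, xshape, train = self._cache
        self.gamma.grad += (dy * xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        dxhat = dy * self.gamma.value
        if not train:
            return dxhat / std
        m = np.prod([xshape[a] for a in axes])
        return (dxhat - dxhat.mean(axis=axes)
                - xhat * (dxhat * xhat).mean(axis=axes)) / std


class ELU(Layer):
    def __init__(self, alpha: float = 1.0):
        self.alpha = alpha

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        neg = x <= 0
        y = np.where(neg, self.alpha * np.expm1(np.minimum(x, 0.0)), x)
        self._cache = (neg, y)
        return y.astype(DTYPE)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        neg, y = self._cache
        return dy * np.where(neg, y + self.alpha, 1.0)


class GlobalAvgPool2D(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._cache = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        bsz, h, w, ch = self._cache
        return np.broadcast_to(dy[:, None, None, :] / (h * w),
                               (bsz, h, w, ch)).astype(DTYPE)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / d_in)
        self.w = Param(rng.normal(0, scale, size=(d_in, d_out)))
        self.b = Param(np.zeros(d_out))

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._cache = x
        return x @ self.w.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._cache
        self.w.grad += x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.w.value.T


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class GRU(Layer):
    """Gated recurrent unit over (B, T, D) -> final hidden state (B, H).

    Gate convention (single bias set, so parameters number 3*(D*H + H*H + H)):
      z_t = sigmoid(x_t Wz + h_{t-1} Uz + bz)
      r_t = sigmoid(x_t Wr + h_{t-1} Ur + br)
      n_t = tanh(x_t Wn + r_t * (h_{t-1} Un) + bn)
      h_t = (1 - z_t) * h_{t-1} + z_t * n_t
    """

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator):
        s_in = np.sqrt(1.0 / d_in)
        s_h = np.sqrt(1.0 / hidden)
        self.wz = Param(rng.normal(0, s_in, (d_in, hidden)))
        self.wr = Param(rng.normal(0, s_in, (d_in, hidden)))
        self.wn = Param(rng.normal(0, s_in, (d_in, hidden)))
        self.uz = Param(rng.normal(0, s_h, (hidden, hidden)))
        self.ur = Param(rng.normal(0, s_h, (hidden, hidden)))
        self.un = Param(rng.normal(0, s_h, (hidden, hidden)))
        self.bz = Param(np.zeros(hidden))
        self.br = Param(np.zeros(hidden))
        self.bn = Param(np.zeros(hidden))
        self.hidden = hidden

    def params(self):
        return [self.wz, self.wr, self.wn, self.uz, self.ur, self.un,
                self.bz, self.br, self.bn]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        bsz, T, _ = x.shape
        h = np.zeros((bsz, self.hidden), dtype=DTYPE)
        steps = []
        for t in range(T):
            xt = x[:, t]
            z = _sigmoid(xt @ self.wz.value + h @ self.uz.value + self.bz.value)
            r = _sigmoid(xt @ self.wr.value + h @ self.ur.value + self.br.value)
            hun = h @ self.un.value
            n = np.tanh(xt @ self.wn.value + r * hun + self.bn.value)
            h_new = (1 - z) * h + z * n
            steps.append((xt, h, z, r, n, hun))
            h = h_new.astype(DTYPE)
        self._cache = (steps, x.shape)
        return h

    def backward(self, dh: np.ndarray) -> np.ndarray:
        steps, xshape = self._cache
        dx = np.zeros(xshape, dtype=DTYPE)
        dh = dh.astype(DTYPE)
        for t in range(len(steps) - 1, -1, -1):
            xt, h_prev, z, r, n, hun = steps[t]
            dz = dh * (n - h_prev) * z * (1 - z)
            dn = dh * z * (1 - n * n)
            dr = dn * hun * r * (1 - r)
            self.wz.grad += xt.T @ dz
            self.wr.grad += xt.T @ dr
            self.wn.grad += xt.T @ dn
            self.uz.grad += h_prev.T @ dz
            self.ur.grad += h_prev.T @ dr
            self.un.grad += h_prev.T @ (dn * r)
            self.bz.grad += dz.sum(axis=0)
            self.br.grad += dr.sum(axis=0)
            self.bn.grad += dn.sum(axis=0)
            dx[:, t] = (dz @ self.wz.value.T + dr @ self.wr.value.T
                        + dn @ self.wn.value.T)
            dh = (dh * (1 - z) + (dn * r) @ self.un.value.T
                  + dz @ self.uz.value.T + dr @ self.ur.value.T)
        return dx


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for lay in self.layers for p in lay.params()]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for lay in self.layers:
            x = lay.forward(x, train=train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for lay in reversed(self.layers):
            dy = lay.backward(dy)
        return dy


# ---------------------------------------------------------------------------
# branch builders
# ---------------------------------------------------------------------------

def build_1d_branch(spec: BranchSpec = BRANCH_1D, in_ch: int = 1,
                    rng: np.random.Generator | None = None) -> Sequential:
    """Four conv blocks per the 1-D table; keeps a reduced temporal axis."""
    rng = rng if rng is not None else np.random.default_rng(0)
    layers: list[Layer] = []
    ch = in_ch
    for blk in spec.blocks:
        layers.append(Conv1D(ch, blk.filters, blk.kernel, blk.conv_stride, rng))
        layers.append(MaxPool1D(blk.pool_kernel, blk.pool_stride))
        layers.append(BatchNorm(blk.filters))
        layers.append(ELU())
        ch = blk.filters
    return Sequential(layers)


def build_2d_branch(spec: BranchSpec = BRANCH_2D, in_ch: int = 3,
                    rng: np.random.Generator | None = None) -> Sequential:
    """Four conv blocks per the 2-D table + global average pooling."""
    rng = rng if rng is not None else np.random.default_rng(0)
    layers: list[Layer] = []
    ch = in_ch
    for blk in spec.blocks:
        layers.append(Conv2D(ch, blk.filters, blk.kernel, rng))
        layers.append(MaxPool2D(blk.pool_kernel, blk.pool_stride))
        layers.append(BatchNorm(blk.filters))
        layers.append(ELU())
        ch = blk.filters
    layers.append(GlobalAvgPool2D())
    return Sequential(layers)


def branch_1d_output_length(length: int, spec: BranchSpec = BRANCH_1D) -> int:
    """Closed-form temporal length after the 1-D branch."""
    for blk in spec.blocks:
        length = -(-length // blk.conv_stride)       # same conv: ceil(L/s)
        length = length // blk.pool_kernel           # floor-mode pooling
    return length


def branch_2d_output_size(size: int, spec: BranchSpec = BRANCH_2D) -> int:
    for blk in spec.blocks:
        size = -(-size // blk.conv_stride)
        size = size // blk.pool_kernel
    return size


# ---------------------------------------------------------------------------
# fusion
# ---------------------------------------------------------------------------

def _face_resample_indices(n_frames: int, t_steps: int) -> np.ndarray:
    """Nearest-index mapping of F keyframe vectors onto T fused time steps."""
    return np.minimum((np.arange(t_steps) * n_frames) // t_steps, n_frames - 1)


def fuse_features(resp_feats: np.ndarray, heart_feats: np.ndarray,
                  face_feats: np.ndarray) -> np.ndarray:
    """Concatenate per-time-step features: [resp | heart | face].

    resp/heart: (B, T, C1); face: (B, F, C2), resampled to T by nearest
    index. Output (B, T, C1 + C1 + C2).
    """
    if resp_feats.shape[:2] != heart_feats.shape[:2]:
        raise ValueError("1-D branch outputs disagree in batch or temporal length")
    T = resp_feats.shape[1]
    idx = _face_resample_indices(face_feats.shape[1], T)
    face_seq = face_feats[:, idx]
    return np.concatenate([resp_feats, heart_feats, face_seq], axis=2)


# ---------------------------------------------------------------------------
# the full network
# ---------------------------------------------------------------------------

class EmotionNet:
    """Two 1D-CNN branches + per-keyframe 2D-CNN, fusion, GRU(64), softmax(4)."""

    def __init__(self, series_length: int = 1200, n_keyframes: int = 8,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        self.series_length = series_length
        self.n_keyframes = n_keyframes
        self.resp_branch = build_1d_branch(rng=rng)
        self.heart_branch = build_1d_branch(rng=rng)
        self.face_branch = build_2d_branch(rng=rng)
        self.t_steps = branch_1d_output_length(series_length)
        if self.t_steps < 1:
            raise ValueError(
                f"series_length={series_length} collapses to an empty "
                "temporal axis after the 1-D branch; need at least 88 samples")
        if n_keyframes < 1:
            raise ValueError("n_keyframes must be >= 1")
        fused = (BRANCH_1D.blocks[-1].filters * 2
                 + BRANCH_2D.blocks[-1].filters)
        self.fused_width = fused
        self.gru = GRU(fused, GRU_UNITS, rng)
        self.head = Dense(GRU_UNITS, N_CLASSES, rng)
        self.seed = seed

    # -- plumbing ----------------------------------------------------------
    def params(self) -> list[Param]:
        return (self.resp_branch.params() + self.heart_branch.params()
                + self.face_branch.params() + self.gru.params()
                + self.head.params())

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    # -- forward / backward -------------------------------------------------
    def forward(self, resp: np.ndarray, heart: np.ndarray, faces: np.ndarray,
                train: bool = True,
                zero_modalities: tuple = ()) -> np.ndarray:
        """Logits for a batch. resp/heart: (B, L); faces: (B, F, 227, 227, 3).

        ``zero_modalities`` (subset of {'respiration','heartbeat','face'})
        zeroes that branch's features before fusion — the modality-ablation
        probe.
        """
        bsz = resp.shape[0]
        rf = self.resp_branch.forward(resp[..., None].astype(DTYPE), train)
        hf = self.heart_branch.forward(heart[..., None].astype(DTYPE), train)
        F = faces.shape[1]
        flat = faces.reshape(bsz * F, *faces.shape[2:]).astype(DTYPE)
        ff = self.face_branch.forward(flat, train).reshape(bsz, F, -1)
        if "respiration" in zero_modalities:
            rf = np.zeros_like(rf)
        if "heartbeat" in zero_modalities:
            hf = np.zeros_like(hf)
        if "face" in zero_modalities:
            ff = np.zeros_like(ff)
        fused = fuse_features(rf, hf, ff)
        h = self.gru.forward(fused, train)
        logits = self.head.forward(h, train)
        self._cache = (rf.shape, hf.shape, ff.shape, F, bsz, zero_modalities)
        return logits

    def backward(self, dlogits: np.ndarray) -> None:
        rf_shape, hf_shape, ff_shape, F, bsz, zeroed = self._cache
        dh = self.head.backward(dlogits)
        dfused = self.gru.backward(dh)
        c1 = rf_shape[2]
        drf = dfused[:, :, :c1]
        dhf = dfused[:, :, c1:2 * c1]
        dface_seq = dfused[:, :, 2 * c1:]
        idx = _face_resample_indices(F, rf_shape[1])
        dff = np.zeros(ff_shape, dtype=DTYPE)
        np.add.at(dff, (slice(None), idx), dface_seq)
        if "respiration" not in zeroed:
            self.resp_branch.backward(drf)
        if "heartbeat" not in zeroed:
            self.heart_branch.backward(dhf)
        if "face" not in zeroed:
            self.face_branch.backward(dff.reshape(bsz * F, -1))

    # -- persistence ---------------------------------------------------------
    def state_dict(self) -> dict:
        state = {f"p{i}": p.value for i, p in enumerate(self.params())}
        bn_idx = 0
        for lay in (self.resp_branch.layers + self.heart_branch.layers
                    + self.face_branch.layers):
            if isinstance(lay, BatchNorm):
                state[f"bn{bn_idx}_mean"] = lay.running_mean
                state[f"bn{bn_idx}_var"] = lay.running_var
                bn_idx += 1
        return state

    def load_state_dict(self, state: dict) -> None:
        for i, p in enumerate(self.params()):
            p.value = np.asarray(state[f"p{i}"], dtype=DTYPE)
            p.grad = np.zeros_like(p.value)
        bn_idx = 0
        for lay in (self.resp_branch.layers + self.heart_branch.layers
                    + self.face_branch.layers):
            if isinstance(lay, BatchNorm):
                lay.running_mean = np.asarray(state[f"bn{bn_idx}_mean"],
                                              dtype=DTYPE)
                lay.running_var = np.asarray(state[f"bn{bn_idx}_var"],
                                             dtype=DTYPE)
                bn_idx += 1

    def save(self, path) -> None:
        path = Path(path)
        np.savez_compressed(path.with_suffix(".npz"), **self.state_dict())
        arch = dict(series_length=self.series_length,
                    n_keyframes=self.n_keyframes, seed=self.seed,
                    fused_width=self.fused_width, t_steps=self.t_steps,
                    gru_units=GRU_UNITS, n_classes=N_CLASSES)
        path.with_suffix(".json").write_text(json.dumps(arch, indent=2))

    @classmethod
    def load(cls, path) -> "EmotionNet":
        path = Path(path)
        arch = json.loads(path.with_suffix(".json").read_text())
        net = cls(series_length=arch["series_length"],
                  n_keyframes=arch["n_keyframes"], seed=arch["seed"])
        with np.load(path.with_suffix(".npz")) as fh:
            net.load_state_dict({k: fh[k] for k in fh.files})
        return net


# ---------------------------------------------------------------------------
# loss, optimizer, training
# ---------------------------------------------------------------------------

def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray
                  ) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    probs = softmax(logits)
    n = len(labels)
    loss = -np.log(np.maximum(probs[np.arange(n), labels], 1e-12)).mean()
    grad = probs.copy()
    grad[np.arange(n), labels] -= 1.0
    return float(loss), (grad / n).astype(DTYPE)


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * p.grad ** 2
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def samples_to_arrays(samples: list[EmotionSample]
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Stack samples into batch arrays with per-sample normalization.

    Series are z-scored per sample (the classifier should read waveform
    shape and rate, not absolute displacement amplitude, which depends on
    radar geometry); images are scaled to [-0.5, 0.5].
    """
    def norm(v):
        v = np.asarray(v, dtype=DTYPE)
        sd = v.std()
        return (v - v.mean()) / (sd if sd > 0 else 1.0)

    resp = np.stack([norm(s.respiration) for s in samples])
    heart = np.stack([norm(s.heartbeat) for s in samples])
    faces = np.stack([s.keyframes for s in samples]).astype(DTYPE)
    faces = faces / 255.0 - 0.5
    labels = np.asarray([LABEL_TO_INDEX[s.label] for s in samples])
    return resp, heart, faces, labels


@dataclass
class TrainHistory:
    epochs: list = field(default_factory=list)
    train_loss: list = field(default_factory=list)
    val_accuracy: list = field(default_factory=list)

    def to_csv(self, path) -> None:
        import pandas as pd
        pd.DataFrame(dict(epoch=self.epochs, loss=self.train_loss,
                          val_accuracy=self.val_accuracy)).to_csv(path,
                                                                  index=False)


def train(samples: list[EmotionSample], config: TrainConfig,
          val_samples: list[EmotionSample] | None = None,
          net: EmotionNet | None = None) -> tuple[EmotionNet, TrainHistory]:
    """Train with cross-entropy + Adam; returns the best-validation checkpoint.

    When ``val_samples`` is None a stratified fraction of ``samples`` is
    held out per ``config.val_fraction``. Deterministic for a fixed config
    (single-threaded BLAS assumed for bit-identity).
    """
    rng = np.random.default_rng(config.seed)
    if val_samples is None and config.val_fraction > 0:
        by_label: dict[str, list[int]] = {}
        for i, s in enumerate(samples):
            by_label.setdefault(s.label, []).append(i)
        val_idx: list[int] = []
        for lab in sorted(by_label):
            idx = np.array(by_label[lab])
            rng.shuffle(idx)
            n_val = max(1, int(round(len(idx) * config.val_fraction)))
            val_idx.extend(idx[:n_val].tolist())
        val_set = set(val_idx)
        val_samples = [samples[i] for i in sorted(val_set)]
        samples = [s for i, s in enumerate(samples) if i not in val_set]

    L = len(samples[0].respiration)
    F = samples[0].keyframes.shape[0]
    if net is None:
        net = EmotionNet(series_length=L, n_keyframes=F, seed=config.seed)
    if config.optimizer != "adam":
        raise ValueError("only the adaptive-moment optimizer is available")
    opt = Adam(net.params(), lr=config.learning_rate)

    resp, heart, faces, labels = samples_to_arrays(samples)
    history = TrainHistory()
    best_acc, best_state = -1.0, None
    order = np.arange(len(samples))
    for epoch in range(config.epochs):
        rng.shuffle(order)
        losses = []
        for lo in range(0, len(order), config.batch_size):
            sel = order[lo:lo + config.batch_size]
            net.zero_grad()
            logits = net.forward(resp[sel], heart[sel], faces[sel], train=True)
            loss, dlogits = cross_entropy(logits, labels[sel])
            net.backward(dlogits)
            opt.step()
            losses.append(loss)
        if val_samples:
            val_acc = evaluate_accuracy(net, val_samples)
        else:
            val_acc = float("nan")
        history.epochs.append(epoch)
        history.train_loss.append(float(np.mean(losses)))
        history.val_accuracy.append(val_acc)
        if not val_samples or np.isnan(val_acc):
            best_state = net.state_dict()
        elif val_acc >= best_acc:
            best_acc = val_acc
            best_state = copy.deepcopy(net.state_dict())
    if best_state is not None:
        net.load_state_dict(best_state)
    return net, history


def predict_proba(net: EmotionNet, samples: list[EmotionSample],
                  batch_size: int = 16,
                  zero_modalities: tuple = ()) -> np.ndarray:
    """Class probabilities (n, 4) in EMOTIONS order, eval mode."""
    resp, heart, faces, _ = samples_to_arrays(samples)
    out = []
    for lo in range(0, len(samples), batch_size):
        logits = net.forward(resp[lo:lo + batch_size], heart[lo:lo + batch_size],
                             faces[lo:lo + batch_size], train=False,
                             zero_modalities=zero_modalities)
        out.append(softmax(logits))
    return np.concatenate(out, axis=0)


def predict(net: EmotionNet, sample: EmotionSample) -> tuple[np.ndarray, str]:
    """Probabilities and argmax label for one sample."""
    probs = predict_proba(net, [sample])[0]
    return probs, EMOTIONS[int(np.argmax(probs))]


def evaluate_accuracy(net: EmotionNet, samples: list[EmotionSample],
                      zero_modalities: tuple = ()) -> float:
    probs = predict_proba(net, samples, zero_modalities=zero_modalities)
    pred = probs.argmax(axis=1)
    truth = np.asarray([LABEL_TO_INDEX[s.label] for s in samples])
    return float((pred == truth).mean())
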