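"""Compact CPU neural-network building blocks with explicit backpropagation.

All tensors are float32 numpy arrays in NCHW layout.  Each layer caches what
its backward pass needs during ``forward`` and releases it after ``backward``;
a layer instance therefore serves exactly one forward/backward pair at a time,
which is all the training loop requires.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


def _as_f32(x: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(x, dtype=DTYPE)


class Conv2d:
    """3x3 (or kxk) same-padding convolution, He-initialised."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3, *,
                 rng: np.random.Generator, name: str = "conv"):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        fan_in = in_ch * kernel * kernel
        self.W = _as_f32(rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                    size=(out_ch, in_ch, kernel, kernel)))
        self.b = np.zeros(out_ch, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.name = name
        self._cols: np.ndarray | None = None
        self._xshape: tuple | None = None

    @property
    def params(self):
        return [(f"{self.name}.W", self.W, self.dW),
                (f"{self.name}.b", self.b, self.db)]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        k, p = self.kernel, self.kernel // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        # (N, C, H, W, k, k) -> (N*H*W, C*k*k)
        v = sliding_window_view(xp, (k, k), axis=(2, 3))
        n, c, h, w = x.shape
        return np.ascontiguousarray(v.transpose(0, 2, 3, 1, 4, 5)).reshape(n * h * w, c * k * k)

    def forward(self, x: np.ndarray, *, need_grad: bool = True) -> np.ndarray:
        if x.shape[1] != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {x.shape[1]}")
        n, _, h, w = x.shape
        cols = self._im2col(_as_f32(x))
        out = cols @ self.W.reshape(self.out_ch, -1).T + self.b
        if need_grad:
            self._cols, self._xshape = cols, x.shape
        return out.reshape(n, h, w, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, c, h, w = self._xshape
        k, p = self.kernel, self.kernel // 2
        gmat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(n * h * w, self.out_ch)
        self.dW += (gmat.T @ self._cols).reshape(self.W.shape)
        self.db += gmat.sum(axis=0)
        dcols = (gmat @ self.W.reshape(self.out_ch, -1)).reshape(n, h, w, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=DTYPE)
        for di in range(k):
            for dj in range(k):
                dxp[:, :, di:di + h, dj:dj + w] += dcols[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
        self._cols = None
        return dxp[:, :, p:p + h, p:p + w]


class ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, *, need_grad: bool = True) -> np.ndarray:
        out = np.maximum(x, 0)
        if need_grad:
            self._mask = x > 0
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        out = g * self._mask
        self._mask = None
        return out


def maxpool2(x: np.ndarray) -> np.ndarray:
    """2x2 stride-2 max pool over the last two axes (must be even)."""
    *lead, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"spatial dims must be even for 2x2 maxpool, got {h}x{w}")
    v = x.reshape(*lead, h // 2, 2, w // 2, 2)
    return v.max(axis=(-3, -1))


class MaxPool2:
    """2x2 stride-2 max pool; gradient routes to the first maximum on ties."""

    def __init__(self):
        self._idx = None
        self._shape = None

    def forward(self, x: np.ndarray, *, need_grad: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"spatial dims must be even for 2x2 maxpool, got {h}x{w}")
        v = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        v = v.reshape(n, c, h // 2, w // 2, 4)
        if need_grad:
            self._idx = np.argmax(v, axis=-1)
            self._shape = (n, c, h, w)
        return v.max(axis=-1)

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        out = np.zeros((n, c, h // 2, w // 2, 4), dtype=DTYPE)
        np.put_along_axis(out, self._idx[..., None], g[..., None], axis=-1)
        out = out.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        self._idx = None
        return np.ascontiguousarray(out.reshape(n, c, h, w))


def upsample_matrix(n: int) -> np.ndarray:
    """Linear operator for 2x bilinear upsampling along one axis.

    Output sample i reads the source at (i + 0.5)/2 - 0.5 (edge-clamped), so
    upsampling a length-1 axis replicates its value; this is the convention
    under which up(down(constant)) returns the constant.
    """
    a = np.zeros((2 * n, n), dtype=np.float64)
    for i in range(2 * n):
        s = min(max((i + 0.5) / 2.0 - 0.5, 0.0), n - 1.0)
        i0 = int(np.floor(s))
        i1 = min(i0 + 1, n - 1)
        t = s - i0
        a[i, i0] += 1.0 - t
        a[i, i1] += t
    return a.astype(DTYPE)


_UP_CACHE: dict[int, np.ndarray] = {}


def _up(n: int) -> np.ndarray:
    if n not in _UP_CACHE:
        _UP_CACHE[n] = upsample_matrix(n)
    return _UP_CACHE[n]


def bilinear_up2(x: np.ndarray) -> np.ndarray:
    """2x bilinear upsampling of (..., H, W)."""
    *_, h, w = x.shape
    y = np.tensordot(x, _up(h), axes=([-2], [1]))   # (..., W, 2H)
    y = np.tensordot(y, _up(w), axes=([-2], [1]))   # (..., 2H, 2W)
    return np.ascontiguousarray(y, dtype=x.dtype)


class BilinearUp2:
    def __init__(self):
        self._hw = None

    def forward(self, x: np.ndarray, *, need_grad: bool = True) -> np.ndarray:
        if need_grad:
            self._hw = x.shape[-2:]
        return bilinear_up2(x)

    def backward(self, g: np.ndarray) -> np.ndarray:
        h, w = self._hw
        d = np.tensordot(g, _up(h), axes=([-2], [0]))
        d = np.tensordot(d, _up(w), axes=([-2], [0]))
        self._hw = None
        return np.ascontiguousarray(d, dtype=DTYPE)


class Dropout:
    """Inverted dropout; a no-op unless ``active``."""

    def __init__(self, p: float):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self._mask = None

    def forward(self, x: np.ndarray, *, rng: np.random.Generator | None,
                active: bool, need_grad: bool = True) -> np.ndarray:
        if not active or self.p == 0.0:
            self._mask = 1.0 if need_grad else None
            return x
        if rng is None:
            raise ValueError("active dropout requires an rng")
        mask = (rng.random(x.shape) >= self.p).astype(DTYPE) / DTYPE(1.0 - self.p)
        if need_grad:
            self._mask = mask
        return x * mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        out = g * self._mask
        self._mask = None
        return out


class Adam:
    """Adam over a list of (name, param, grad) triples (params updated in place)."""

    def __init__(self, params, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params = list(params)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for _, p, _ in self.params]
        self.v = [np.zeros_like(p) for _, p, _ in self.params]
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (_, p, g) in enumerate(self.params):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p -= (lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)

    def zero_grad(self) -> None:
        for _, _, g in self.params:
            g[...] = 0
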