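"""U-Net for binary GA segmentation with remainder skips and a bounded head.

The architecture follows an encoder/decoder U-Net with two departures from
the classic design:

* skip connections carry the *downsampling remainder* of each encoder level,
  ``rem(x) = x - upsample(downsample(x))`` with a 2x2 max-pool and 2x bilinear
  upsampling — the high-frequency content the pooling path discards — rather
  than the raw feature maps;
* the final activation is the algebraic sigmoid ``(x / sqrt(x^2 + 1) + 1) / 2``,
  which keeps every output strictly inside (0, 1).

Two variants exist: ``standard`` (a single p=0.2 dropout before the two head
convolutions, used only during training) and ``drop`` (additional p=0.5
dropout after the last three encoder blocks and the first two decoder blocks,
kept active at inference for Monte Carlo sampling).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from gaseg.nn import (
    DTYPE,
    Adam,
    BilinearUp2,
    Conv2d,
    Dropout,
    MaxPool2,
    ReLU,
    bilinear_up2,
    maxpool2,
)

__all__ = ["ModelConfig", "UNet", "final_activation", "remainder",
           "save_model", "load_model"]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``base_channels`` is the output width of the first encoder block; widths
    double at each of ``depth`` downsampling steps (32 -> 512 at defaults).
    """

    input_channels: int = 3
    base_channels: int = 32
    depth: int = 4
    final_hidden_channels: int = 8
    base_dropout_p: float = 0.2
    extra_dropout_p: float = 0.5
    variant: str = "standard"

    def __post_init__(self):
        if self.depth < 1 or self.base_channels < 1:
            raise ValueError("depth and base_channels must be >= 1")
        if self.variant not in ("standard", "drop"):
            raise ValueError(f"unknown variant {self.variant!r}")
        for p in (self.base_dropout_p, self.extra_dropout_p):
            if not 0.0 <= p < 1.0:
                raise ValueError("dropout probabilities must be in [0, 1)")

    @property
    def encoder_channels(self) -> list[int]:
        return [self.base_channels * 2 ** i for i in range(self.depth + 1)]


def final_activation(x):
    """Algebraic sigmoid ``(x / sqrt(x^2 + 1) + 1) / 2``.

    Strictly increasing, symmetric about (0, 0.5), with open range (0, 1).
    """
    x = np.asarray(x)
    if not np.all(np.isfinite(x)):
        raise ValueError("final_activation requires finite input")
    return 0.5 * (x / np.sqrt(x * x + 1.0) + 1.0)


def _final_activation_grad(x: np.ndarray) -> np.ndarray:
    return 0.5 * (x * x + 1.0) ** -1.5


def remainder(x: np.ndarray) -> np.ndarray:
    """High-frequency remainder ``x - upsample(downsample(x))``.

    ``downsample`` is a 2x2 stride-2 max pool and ``upsample`` is 2x bilinear
    interpolation, applied to the trailing two (spatial) axes.  A constant
    input maps to zeros.
    """
    x = np.asarray(x)
    h, w = x.shape[-2:]
    if h % 2 or w % 2:
        raise ValueError(f"spatial dims must be even, got {h}x{w}")
    return x - bilinear_up2(maxpool2(x))


class _Remainder:
    """Remainder as a differentiable layer (shared by every skip connection)."""

    def __init__(self):
        self.pool = MaxPool2()
        self.up = BilinearUp2()

    def forward(self, x, *, need_grad=True):
        return x - self.up.forward(self.pool.forward(x, need_grad=need_grad),
                                   need_grad=need_grad)

    def backward(self, g):
        return g - self.pool.backward(self.up.backward(g))


class _ConvBlock:
    """Two 3x3 convolutions, each followed by a rectified linear unit."""

    def __init__(self, in_ch, out_ch, *, rng, name):
        self.c1 = Conv2d(in_ch, out_ch, rng=rng, name=f"{name}.c1")
        self.r1 = ReLU()
        self.c2 = Conv2d(out_ch, out_ch, rng=rng, name=f"{name}.c2")
        self.r2 = ReLU()

    @property
    def params(self):
        return self.c1.params + self.c2.params

    def forward(self, x, *, need_grad=True):
        h = self.r1.forward(self.c1.forward(x, need_grad=need_grad), need_grad=need_grad)
        return self.r2.forward(self.c2.forward(h, need_grad=need_grad), need_grad=need_grad)

    def backward(self, g):
        g = self.c2.backward(self.r2.backward(g))
        return self.c1.backward(self.r1.backward(g))


class UNet:
    """Segmentation network; weights are deterministic in (config, seed)."""

    def __init__(self, config: ModelConfig, seed: int):
        self.config = config
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed)
        ch = config.encoder_channels
        d = config.depth

        self.enc = []
        in_ch = config.input_channels
        for i, c in enumerate(ch):
            self.enc.append(_ConvBlock(in_ch, c, rng=rng, name=f"enc{i}"))
            in_ch = c
        self.pools = [MaxPool2() for _ in range(d)]

        self.ups = [BilinearUp2() for _ in range(d)]
        self.rems = [_Remainder() for _ in range(d)]
        self.dec = []
        for j in range(d):
            lvl = d - 1 - j
            self.dec.append(_ConvBlock(ch[lvl + 1] + ch[lvl], ch[lvl],
                                       rng=rng, name=f"dec{j}"))

        self.head_drop = Dropout(config.base_dropout_p)
        self.pen = Conv2d(ch[0], config.final_hidden_channels, rng=rng, name="pen")
        self.pen_relu = ReLU()
        self.out = Conv2d(config.final_hidden_channels, 1, rng=rng, name="out")

        # drop variant: p=0.5 after the last 3 encoder blocks and first 2
        # decoder blocks (in forward order)
        self._extra_enc = set(range(max(0, d + 1 - 3), d + 1))
        self._extra_dec = set(range(min(2, d)))
        if config.variant == "drop":
            self.enc_drop = {i: Dropout(config.extra_dropout_p) for i in self._extra_enc}
            self.dec_drop = {j: Dropout(config.extra_dropout_p) for j in self._extra_dec}
        else:
            self.enc_drop, self.dec_drop = {}, {}

        self._pre_act: np.ndarray | None = None

    # ------------------------------------------------------------------ params
    @property
    def params(self):
        out = []
        for b in self.enc:
            out += b.params
        for b in self.dec:
            out += b.params
        out += self.pen.params + self.out.params
        return out

    def conv_kernels(self):
        """Convolution kernels only (no biases), for sparsity regularisation."""
        return [(name, p, g) for name, p, g in self.params if name.endswith(".W")]

    def n_params(self) -> int:
        return sum(p.size for _, p, _ in self.params)

    # ----------------------------------------------------------------- forward
    def _check_input(self, x: np.ndarray) -> None:
        if x.ndim != 4:
            raise ValueError("input must be (N, C, H, W)")
        if x.shape[1] != self.config.input_channels:
            raise ValueError(f"expected {self.config.input_channels} channels, "
                             f"got {x.shape[1]}")
        h, w = x.shape[2:]
        m = 2 ** self.config.depth
        if h % m or w % m:
            raise ValueError(f"spatial dims must be divisible by {m}, got {h}x{w}")

    def forward(self, x: np.ndarray, *, rng: np.random.Generator | None = None,
                dropout_active: bool = False, train: bool = False,
                need_grad: bool = False) -> np.ndarray:
        """One pass; returns per-pixel probabilities (N, 1, H, W) in (0, 1).

        During training every dropout layer of the variant is active; at
        inference they are active only when ``dropout_active`` is set.
        """
        self._check_input(x)
        x = np.ascontiguousarray(x, dtype=DTYPE)
        act = train or dropout_active
        d = self.config.depth

        feats = []
        h = x
        for i, block in enumerate(self.enc):
            h = block.forward(h, need_grad=need_grad)
            if i in self.enc_drop:
                h = self.enc_drop[i].forward(h, rng=rng, active=act, need_grad=need_grad)
            feats.append(h)
            if i < d:
                h = self.pools[i].forward(h, need_grad=need_grad)

        for j in range(d):
            lvl = d - 1 - j
            u = self.ups[j].forward(h, need_grad=need_grad)
            r = self.rems[j].forward(feats[lvl], need_grad=need_grad)
            h = np.concatenate([u, r], axis=1)
            h = self.dec[j].forward(h, need_grad=need_grad)
            if j in self.dec_drop:
                h = self.dec_drop[j].forward(h, rng=rng, active=act, need_grad=need_grad)

        h = self.head_drop.forward(h, rng=rng, active=act, need_grad=need_grad)
        h = self.pen_relu.forward(self.pen.forward(h, need_grad=need_grad),
                                  need_grad=need_grad)
        z = self.out.forward(h, need_grad=need_grad)
        if need_grad:
            self._pre_act = z
        return final_activation(z).astype(DTYPE)

    def backward(self, g_prob: np.ndarray) -> None:
        """Backpropagate a gradient w.r.t. the output probabilities."""
        g = (g_prob * _final_activation_grad(self._pre_act)).astype(DTYPE)
        self._pre_act = None
        g = self.pen.backward(self.pen_relu.backward(self.out.backward(g)))
        g = self.head_drop.backward(g)

        d = self.config.depth
        feat_grads = [None] * (d + 1)
        for j in reversed(range(d)):
            lvl = d - 1 - j
            if j in self.dec_drop:
                g = self.dec_drop[j].backward(g)
            g = self.dec[j].backward(g)
            c_up = self.config.encoder_channels[lvl + 1]
            gu, gr = g[:, :c_up], g[:, c_up:]
            feat_grads[lvl] = self.rems[j].backward(np.ascontiguousarray(gr))
            g = self.ups[j].backward(np.ascontiguousarray(gu))

        for i in reversed(range(d + 1)):
            if i < d:
                g = self.pools[i].backward(g)
                if feat_grads[i] is not None:
                    g = g + feat_grads[i]
            else:
                g = g + feat_grads[i] if feat_grads[i] is not None else g
            if i in self.enc_drop:
                g = self.enc_drop[i].backward(g)
            g = self.enc[i].backward(g)

    # ----------------------------------------------------------------- predict
    def predict(self, image: np.ndarray, *, dropout_active: bool = False,
                seed: int | None = None) -> np.ndarray:
        """Probability map (H, W) for a single (C, H, W) image.

        With ``dropout_active`` the pass is stochastic but fully determined
        by ``seed``.
        """
        if image.ndim != 3:
            raise ValueError("image must be (C, H, W)")
        rng = None
        if dropout_active:
            if seed is None:
                raise ValueError("dropout_active inference requires a seed")
            rng = np.random.default_rng(int(seed))
        out = self.forward(image[None], rng=rng, dropout_active=dropout_active)
        return out[0, 0]

    def make_optimizer(self) -> Adam:
        return Adam(self.params)

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.copy() for name, p, _ in self.params}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, p, _ in self.params:
            p[...] = state[name]


def save_model(model: UNet, path) -> None:
    """Serialise weights and config into a single .npz checkpoint."""
    meta = json.dumps({"config": asdict(model.config), "seed": model.seed})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **model.state_dict())


def load_model(path) -> UNet:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        model = UNet(ModelConfig(**meta["config"]), seed=meta["seed"])
        model.load_state_dict({k: z[k] for k in z.files if k != "__meta__"})
    return model
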