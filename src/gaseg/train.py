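"""Training: Dice loss with Hoyer-Square sparsity, Adam, folds, augmentation.

The per-step objective is ``dice_loss + hoyer_coefficient * hoyer_square``
over all convolution kernels (biases excluded).  The learning rate follows a
multiplicative schedule ``initial_lr * lr_decay_per_epoch ** epoch``.  An
ensemble is obtained by k-fold cross-validation: member j trains on every
fold except j, with its own weight-initialisation seed, so members differ in
both data and initialisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from gaseg.synthetic import SyntheticSample
from gaseg.unet import ModelConfig, UNet

__all__ = ["AugmentConfig", "TrainConfig", "FoldSplit", "dice_loss",
           "hoyer_square", "make_folds", "augment", "train_model",
           "train_ensemble"]


@dataclass(frozen=True)
class AugmentConfig:
    p_hflip: float = 0.5
    p_vflip: float = 0.5
    p_rot90: float = 0.5
    max_shift: int = 4          # pixels, uniform in [-max_shift, max_shift]
    p_jitter: float = 0.5
    jitter_gain_sd: float = 0.05
    jitter_offset_sd: float = 0.02

    @classmethod
    def identity(cls) -> "AugmentConfig":
        return cls(p_hflip=0, p_vflip=0, p_rot90=0, max_shift=0, p_jitter=0)


@dataclass(frozen=True)
class TrainConfig:
    initial_lr: float = 1e-4
    lr_decay_per_epoch: float = 0.999
    epochs: int = 50
    hoyer_coefficient: float = 1e-3
    batch_size: int = 8
    augmentation: AugmentConfig = field(default_factory=AugmentConfig)
    seed: int = 0

    def __post_init__(self):
        if self.initial_lr <= 0:
            raise ValueError("initial_lr must be positive")
        if not 0 < self.lr_decay_per_epoch <= 1:
            raise ValueError("lr_decay_per_epoch must be in (0, 1]")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")


@dataclass(frozen=True)
class FoldSplit:
    k: int
    assignments: dict[str, int]

    def fold_ids(self, fold: int) -> list[str]:
        return [sid for sid, f in self.assignments.items() if f == fold]


# --------------------------------------------------------------------- losses

def dice_loss(prob_map: np.ndarray, target: np.ndarray, eps: float = 1.0) -> float:
    """1 - Dice coefficient with additive smoothing ``eps``.

    ``1 - (2 * sum(p*t) + eps) / (sum(p) + sum(t) + eps)``; the smoothing
    keeps the loss defined (and its gradient bounded) on empty masks.
    """
    prob_map = np.asarray(prob_map, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if prob_map.shape != target.shape:
        raise ValueError(f"shape mismatch {prob_map.shape} vs {target.shape}")
    num = 2.0 * (prob_map * target).sum() + eps
    den = prob_map.sum() + target.sum() + eps
    return float(1.0 - num / den)


def _dice_loss_and_grad(probs: np.ndarray, targets: np.ndarray,
                        eps: float = 1.0) -> tuple[float, np.ndarray]:
    """Mean per-image Dice loss over a batch and its gradient w.r.t. probs."""
    n = probs.shape[0]
    p = probs.reshape(n, -1).astype(np.float64)
    t = targets.reshape(n, -1).astype(np.float64)
    num = 2.0 * (p * t).sum(axis=1) + eps
    den = p.sum(axis=1) + t.sum(axis=1) + eps
    loss = float(np.mean(1.0 - num / den))
    grad = -(2.0 * t * den[:, None] - num[:, None]) / den[:, None] ** 2
    return loss, (grad / n).reshape(probs.shape).astype(np.float32)


def hoyer_square(weights: np.ndarray) -> float:
    """Hoyer-Square sparsity measure ``(sum|w|)^2 / sum(w^2)``.

    Scale-invariant; 1 for a one-hot vector, n for a constant n-vector, and
    defined as 0 for an all-zero input.
    """
    w = np.asarray(weights, dtype=np.float64).ravel()
    peak = np.abs(w).max() if w.size else 0.0
    if peak == 0.0:
        return 0.0
    w = w / peak  # scale-invariant; guards against under/overflow in w^2
    s2 = float(np.dot(w, w))
    s1 = float(np.abs(w).sum())
    return s1 * s1 / s2


def _hoyer_square_grad(w: np.ndarray) -> tuple[float, np.ndarray]:
    w64 = w.astype(np.float64)
    s2 = float(np.sum(w64 * w64))
    if s2 == 0.0:
        return 0.0, np.zeros_like(w)
    s1 = float(np.abs(w64).sum())
    grad = 2.0 * s1 / s2 * np.sign(w64) - 2.0 * (s1 * s1) / (s2 * s2) * w64
    return s1 * s1 / s2, grad.astype(w.dtype)


# ---------------------------------------------------------------------- folds

def make_folds(dataset: list[SyntheticSample], k: int, seed: int) -> FoldSplit:
    """Seeded shuffle then round-robin assignment into k folds (sizes differ <=1)."""
    if len(dataset) < k:
        raise ValueError(f"need at least {k} samples, got {len(dataset)}")
    rng = np.random.default_rng(int(seed))
    order = rng.permutation(len(dataset))
    assignments = {dataset[idx].sample_id: pos % k
                   for pos, idx in enumerate(order)}
    return FoldSplit(k=k, assignments=assignments)


# --------------------------------------------------------------- augmentation

def augment(image: np.ndarray, masks: list[np.ndarray], config: AugmentConfig,
            seed: int) -> tuple[np.ndarray, list[np.ndarray]]:
    """One seeded augmentation draw.

    The same geometric transform (flips, 90-degree rotations, small integer
    translation) is applied to the image and every mask; photometric jitter
    (gain and offset) touches the image only.  Masks stay strictly binary.
    """
    rng = np.random.default_rng(int(seed))
    img = image.copy()
    ms = [m.copy() for m in masks]
    h, w = img.shape[-2:]

    if config.p_hflip > 0 and rng.random() < config.p_hflip:
        img = img[..., ::-1]
        ms = [m[..., ::-1] for m in ms]
    if config.p_vflip > 0 and rng.random() < config.p_vflip:
        img = img[..., ::-1, :]
        ms = [m[..., ::-1, :] for m in ms]
    if config.p_rot90 > 0 and h == w and rng.random() < config.p_rot90:
        k = int(rng.integers(1, 4))
        img = np.rot90(img, k, axes=(-2, -1))
        ms = [np.rot90(m, k, axes=(-2, -1)) for m in ms]
    if config.max_shift > 0:
        dy, dx = rng.integers(-config.max_shift, config.max_shift + 1, size=2)
        fill = float(np.median(img))
        img = _shift2d(img, int(dy), int(dx), fill)
        ms = [_shift2d(m, int(dy), int(dx), 0) for m in ms]
    if config.p_jitter > 0 and rng.random() < config.p_jitter:
        gain = 1.0 + rng.normal(0, config.jitter_gain_sd)
        offset = rng.normal(0, config.jitter_offset_sd)
        img = np.clip(img * gain + offset, 0.0, 1.0)
    return (np.ascontiguousarray(img, dtype=np.float32),
            [np.ascontiguousarray(m) for m in ms])


def _shift2d(a: np.ndarray, dy: int, dx: int, fill) -> np.ndarray:
    out = np.full_like(a, fill)
    h, w = a.shape[-2:]
    ys, yd = (slice(0, h - dy), slice(dy, h)) if dy >= 0 else (slice(-dy, h), slice(0, h + dy))
    xs, xd = (slice(0, w - dx), slice(dx, w)) if dx >= 0 else (slice(-dx, w), slice(0, w + dx))
    out[..., yd, xd] = a[..., ys, xs]
    return out


# ------------------------------------------------------------------- training

def _binary_dice(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = int(a.sum()), int(b.sum())
    if sa + sb == 0:
        return 1.0
    inter = int(np.logical_and(a, b).sum())
    return 2.0 * inter / (sa + sb)


def validation_dice(model: UNet, val_set: list[SyntheticSample],
                    threshold: float = 0.5) -> float:
    """Mean Dice of thresholded deterministic predictions vs truth."""
    scores = []
    for s in val_set:
        pred = model.predict(s.image) >= threshold
        scores.append(_binary_dice(pred, s.truth > 0))
    return float(np.mean(scores)) if scores else float("nan")


def train_model(model: UNet, train_set: list[SyntheticSample],
                val_set: list[SyntheticSample],
                config: TrainConfig) -> pd.DataFrame:
    """Train in place; returns a per-epoch log.

    Log columns: epoch (0-based), lr, dice_loss, hoyer, total_loss, val_dice,
    with ``total_loss = dice_loss + hoyer_coefficient * hoyer`` at every row
    and ``lr = initial_lr * lr_decay_per_epoch ** epoch``.
    """
    if not train_set:
        raise ValueError("training set is empty")
    rng = np.random.default_rng(int(config.seed))
    opt = model.make_optimizer()
    rows = []
    n = len(train_set)
    bs = max(1, min(config.batch_size, n))

    for epoch in range(config.epochs):
        lr = config.initial_lr * config.lr_decay_per_epoch ** epoch
        order = rng.permutation(n)
        dice_terms, hoyer_terms = [], []
        for start in range(0, n, bs):
            batch = [train_set[i] for i in order[start:start + bs]]
            imgs, tgts = [], []
            for s in batch:
                aug_seed = int(rng.integers(0, 2 ** 31))
                img, (tgt,) = augment(s.image, [s.truth], config.augmentation,
                                      aug_seed)
                imgs.append(img)
                tgts.append(tgt.astype(np.float32))
            x = np.stack(imgs)
            t = np.stack(tgts)[:, None]

            probs = model.forward(x, rng=rng, train=True, need_grad=True)
            d_loss, d_grad = _dice_loss_and_grad(probs, t)

            hs_total = 0.0
            opt.zero_grad()
            model.backward(d_grad)
            for _, wgt, grd in model.conv_kernels():
                hs, hs_grad = _hoyer_square_grad(wgt)
                hs_total += hs
                grd += config.hoyer_coefficient * hs_grad
            total = d_loss + config.hoyer_coefficient * hs_total
            if not np.isfinite(total):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: dice={d_loss} hoyer={hs_total}")
            opt.step(lr)
            dice_terms.append(d_loss)
            hoyer_terms.append(hs_total)

        mean_dice = float(np.mean(dice_terms))
        mean_hoyer = float(np.mean(hoyer_terms))
        rows.append({
            "epoch": epoch,
            "lr": lr,
            "dice_loss": mean_dice,
            "hoyer": mean_hoyer,
            "total_loss": mean_dice + config.hoyer_coefficient * mean_hoyer,
            "val_dice": validation_dice(model, val_set),
        })
    return pd.DataFrame(rows, columns=["epoch", "lr", "dice_loss", "hoyer",
                                       "total_loss", "val_dice"])


def _member_seed(base_seed: int, member: int) -> int:
    ss = np.random.SeedSequence([int(base_seed), 7, int(member)])
    return int(ss.generate_state(1)[0] % np.uint32(2 ** 31))


def train_ensemble(dataset: list[SyntheticSample], k: int,
                   model_config: ModelConfig,
                   config: TrainConfig) -> tuple[list[UNet], list[pd.DataFrame], FoldSplit]:
    """k-fold cross-validation ensemble; member j validates on fold j."""
    folds = make_folds(dataset, k, config.seed)
    models, logs = [], []
    for j in range(k):
        val = [s for s in dataset if folds.assignments[s.sample_id] == j]
        trn = [s for s in dataset if folds.assignments[s.sample_id] != j]
        seed_j = _member_seed(config.seed, j)
        model = UNet(model_config, seed=seed_j)
        cfg_j = TrainConfig(
            initial_lr=config.initial_lr,
            lr_decay_per_epoch=config.lr_decay_per_epoch,
            epochs=config.epochs,
            hoyer_coefficient=config.hoyer_coefficient,
            batch_size=config.batch_size,
            augmentation=config.augmentation,
            seed=seed_j,
        )
        logs.append(train_model(model, trn, val, cfg_j))
        models.append(model)
    return models, logs, folds
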