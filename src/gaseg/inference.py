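"""Approximate Bayesian inference: MC-dropout and ensemble probability maps.

Both techniques approximate the posterior predictive by averaging stochastic
model evaluations: Monte Carlo dropout re-runs one dropout-trained network T
times with dropout left on, while the ensemble averages the deterministic
outputs of K independently initialised and trained networks.  Per-pixel
uncertainty is then the Shannon entropy (base 2) of the averaged binary
predictive distribution — 0 bits at p in {0, 1}, 1 bit at p = 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from gaseg.unet import UNet

__all__ = ["ProbabilityMap", "EntropyMap", "predict", "mc_dropout_predict",
           "ensemble_predict", "entropy_map"]

_EPS = 1e-12  # log clamp; exact 0/1 handled by the 0*log0 == 0 convention


@dataclass
class ProbabilityMap:
    """Per-pixel GA probability in [0, 1] plus provenance of the estimate."""

    values: np.ndarray
    provenance: str = "single"       # "single" | "ensemble" | "mc_dropout"
    n_sources: int = 1               # K members or T dropout runs
    source_ids: tuple = ()

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.min() < 0 or v.max() > 1:
            raise ValueError("probabilities must lie in [0, 1]")
        self.values = v

    @property
    def shape(self):
        return self.values.shape


@dataclass
class EntropyMap:
    """Per-pixel Shannon entropy in bits; in [0, 1] for binary classes.

    Thresholds elsewhere are expressed as a fraction of the 1-bit maximum.
    """

    values: np.ndarray
    threshold_unit: str = "fraction of 1-bit maximum"

    @property
    def shape(self):
        return self.values.shape


def _stable_mean(stack: np.ndarray) -> np.ndarray:
    """Mean over axis 0, invariant to the order of the stacked maps.

    Sorting each pixel's samples before the (pairwise) summation makes the
    result bit-identical under any permutation of runs or members.
    """
    return np.sort(np.asarray(stack, dtype=np.float64), axis=0).mean(axis=0)


def predict(model: UNet, image: np.ndarray) -> ProbabilityMap:
    """Deterministic single-model probability map (dropout off)."""
    return ProbabilityMap(values=model.predict(image).astype(np.float64),
                          provenance="single", n_sources=1)


def _run_seed(seed: int, t: int) -> int:
    ss = np.random.SeedSequence([int(seed), int(t)])
    return int(ss.generate_state(1)[0] % np.uint32(2 ** 31))


def mc_dropout_predict(model: UNet, image: np.ndarray, T: int,
                       seed: int) -> ProbabilityMap:
    """Average of T dropout-active forward passes (UNet-DropT style).

    Each pass uses a distinct seed derived from ``seed``; the whole map is
    deterministic given (seed, T).
    """
    if model.config.variant != "drop":
        raise ValueError("mc_dropout_predict requires a drop-variant model")
    if T < 1:
        raise ValueError("T must be >= 1")
    runs = np.stack([
        model.predict(image, dropout_active=True, seed=_run_seed(seed, t))
        for t in range(T)
    ])
    return ProbabilityMap(values=_stable_mean(runs), provenance="mc_dropout",
                          n_sources=T)


def ensemble_predict(models: list[UNet], image: np.ndarray) -> ProbabilityMap:
    """Pixel-wise mean of deterministic forward passes of K models (UNet-Avg)."""
    if not models:
        raise ValueError("ensemble requires at least one model")
    specs = {(m.config.input_channels, m.config.depth) for m in models}
    if len(specs) > 1:
        raise ValueError("ensemble members disagree on input spec")
    outs = np.stack([m.predict(image) for m in models])
    return ProbabilityMap(values=_stable_mean(outs), provenance="ensemble",
                          n_sources=len(models))


def entropy_map(prob: ProbabilityMap | np.ndarray) -> EntropyMap:
    """Binary Shannon entropy ``-(p log2 p + (1-p) log2 (1-p))`` per pixel."""
    p = np.asarray(prob.values if isinstance(prob, ProbabilityMap) else prob,
                   dtype=np.float64)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    q = np.clip(p, _EPS, 1.0 - _EPS)
    # canonicalise on min(p, 1-p) so H(p) and H(1-p) share the same floats
    lo = np.minimum(q, 1.0 - q)
    h = -(lo * np.log2(lo) + (1.0 - lo) * np.log2(1.0 - lo))
    h[(p == 0.0) | (p == 1.0)] = 0.0
    return EntropyMap(values=h)
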