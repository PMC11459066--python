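"""Entropy-aware overlay rendering and summary figures.

The overlay uses a diverging colormap: saturated red where the model is
certain of GA, saturated blue where it is certain of no GA, fading to a
neutral white as per-pixel entropy approaches its 1-bit maximum.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from gaseg.inference import EntropyMap, ProbabilityMap

__all__ = ["render_overlay", "plot_dice_vs_threshold", "plot_tradeoff"]

_RED = np.array([1.0, 0.0, 0.0])
_BLUE = np.array([0.0, 0.0, 1.0])
_NEUTRAL = np.array([1.0, 1.0, 1.0])


def render_overlay(image: np.ndarray, prob, entropy) -> np.ndarray:
    """(H, W, 3) uint8: red = certain GA, blue = certain background.

    Saturation scales with certainty (1 - entropy); a fully uncertain pixel
    renders as the neutral midpoint color.
    """
    p = np.asarray(prob.values if isinstance(prob, ProbabilityMap) else prob,
                   dtype=np.float64)
    h = np.asarray(entropy.values if isinstance(entropy, EntropyMap) else entropy,
                   dtype=np.float64)
    if image.shape[-2:] != p.shape or p.shape != h.shape:
        raise ValueError("image, prob and entropy shapes do not match")
    endpoint = np.where((p >= 0.5)[..., None], _RED, _BLUE)
    certainty = np.clip(1.0 - h, 0.0, 1.0)[..., None]
    rgb = _NEUTRAL + certainty * (endpoint - _NEUTRAL)
    return np.round(np.clip(rgb, 0, 1) * 255).astype(np.uint8)


def plot_dice_vs_threshold(aggregated: pd.DataFrame, path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    for model_id, grp in aggregated.groupby("model_id"):
        grp = grp.sort_values("threshold")
        ax.plot(grp["threshold"] * 100, grp["dice_mean"], marker="o", label=model_id)
        ax.fill_between(grp["threshold"] * 100, grp["dice_ci_lo"],
                        grp["dice_ci_hi"], alpha=0.2)
    ax.set_xlabel("entropy threshold (% of 1-bit max)")
    ax.set_ylabel("mean Dice (two-grader average)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_tradeoff(aggregated: pd.DataFrame, path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    for model_id, grp in aggregated.groupby("model_id"):
        grp = grp.sort_values("threshold")
        sc = ax.scatter(grp["percent_removed"], grp["dice_mean"],
                        c=grp["threshold"], cmap="viridis", label=model_id)
        ax.plot(grp["percent_removed"], grp["dice_mean"], alpha=0.4)
    fig.colorbar(sc, ax=ax, label="entropy threshold")
    ax.set_xlabel("% of image removed")
    ax.set_ylabel("mean Dice")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
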