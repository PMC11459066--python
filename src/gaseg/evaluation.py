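"""Entropy-threshold sweep evaluation and paired statistics.

Selective prediction is evaluated by sweeping an entropy threshold over each
probability map: pixels whose entropy exceeds the threshold (a fraction of
the 1-bit binary maximum) are removed, the binarised prediction is scored
with the Dice coefficient against each of two graders on the retained pixels
only, the two scores are averaged per image, and per-image scores are then
averaged over the test set.  The companion quantity is the percentage of the
image removed at each threshold.

Statistics: two-sided Wilcoxon signed-rank tests between paired per-image
Dice scores (exact sign-flip enumeration for small n, normal approximation
otherwise) with Bonferroni adjustment, and Pearson correlation between mean
Dice and mean percent-removed across the threshold grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from gaseg.inference import EntropyMap, ProbabilityMap

__all__ = ["EntropyThresholdGrid", "retained_pixels", "percent_removed",
           "masked_dice", "threshold_sweep", "aggregate_sweep",
           "wilcoxon_paired", "pearson_tradeoff", "WilcoxonResult",
           "PearsonResult"]


def _default_grid() -> tuple[float, ...]:
    # "<1%" concretised as 0.01, then 10% steps up to 100% of the 1-bit max
    return (0.01,) + tuple(np.round(np.arange(0.1, 1.01, 0.1), 2))


@dataclass(frozen=True)
class EntropyThresholdGrid:
    thresholds: tuple[float, ...] = field(default_factory=_default_grid)

    def __post_init__(self):
        t = np.asarray(self.thresholds, dtype=float)
        if t.size == 0 or np.any(t <= 0) or np.any(t > 1):
            raise ValueError("thresholds must lie in (0, 1]")
        if np.any(np.diff(t) <= 0):
            raise ValueError("thresholds must be strictly increasing")


def _entropy_values(entropy) -> np.ndarray:
    return np.asarray(entropy.values if isinstance(entropy, EntropyMap) else entropy,
                      dtype=np.float64)


def _prob_values(prob) -> np.ndarray:
    return np.asarray(prob.values if isinstance(prob, ProbabilityMap) else prob,
                      dtype=np.float64)


def retained_pixels(entropy, threshold: float) -> np.ndarray:
    """Boolean mask of pixels at or below ``threshold`` (fraction of 1 bit)."""
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    return _entropy_values(entropy) <= threshold


def percent_removed(entropy, threshold: float) -> float:
    """Percentage of pixels whose entropy exceeds the threshold."""
    e = _entropy_values(entropy)
    if e.size == 0:
        raise ValueError("empty entropy map")
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    return float(100.0 * np.count_nonzero(e > threshold) / e.size)


def masked_dice(prob, grader: np.ndarray, retained: np.ndarray,
                binarize_at: float = 0.5) -> float:
    """Dice between the thresholded prediction and a grader on retained pixels.

    Returns 1.0 when prediction and grader are both empty on the retained
    set, and NaN (an undefined record) when no pixels are retained.
    """
    p = _prob_values(prob)
    g = np.asarray(grader)
    r = np.asarray(retained, dtype=bool)
    if p.shape != g.shape or p.shape != r.shape:
        raise ValueError("prob, grader and retained must share a shape")
    if not r.any():
        return float("nan")
    pred = p[r] >= binarize_at
    ref = g[r] > 0
    tot = int(pred.sum()) + int(ref.sum())
    if tot == 0:
        return 1.0
    return float(2.0 * np.logical_and(pred, ref).sum() / tot)


def threshold_sweep(prob_maps: dict, entropy_maps: dict, graders: dict,
                    grid: EntropyThresholdGrid | None = None,
                    binarize_at: float = 0.5) -> pd.DataFrame:
    """One record per (model, sample, threshold).

    ``prob_maps`` / ``entropy_maps``: model_id -> sample_id -> map;
    ``graders``: sample_id -> (grader1_mask, grader2_mask).
    Columns: model_id, sample_id, threshold, dice_vs_grader1, dice_vs_grader2,
    dice_mean, percent_removed, defined.
    """
    grid = grid or EntropyThresholdGrid()
    rows = []
    for model_id, per_sample in prob_maps.items():
        if model_id not in entropy_maps:
            raise ValueError(f"no entropy maps for model {model_id!r}")
        for sample_id, prob in per_sample.items():
            if sample_id not in entropy_maps[model_id]:
                raise ValueError(f"no entropy map for {model_id!r}/{sample_id!r}")
            if sample_id not in graders:
                raise ValueError(f"no grader masks for sample {sample_id!r}")
            ent = entropy_maps[model_id][sample_id]
            g1, g2 = graders[sample_id]
            for thr in grid.thresholds:
                keep = retained_pixels(ent, thr)
                d1 = masked_dice(prob, g1, keep, binarize_at)
                d2 = masked_dice(prob, g2, keep, binarize_at)
                defined = not (np.isnan(d1) or np.isnan(d2))
                rows.append({
                    "model_id": model_id,
                    "sample_id": sample_id,
                    "threshold": float(thr),
                    "dice_vs_grader1": d1,
                    "dice_vs_grader2": d2,
                    "dice_mean": (d1 + d2) / 2.0 if defined else float("nan"),
                    "percent_removed": percent_removed(ent, thr),
                    "defined": defined,
                })
    return pd.DataFrame(rows)


def _bootstrap_ci(values: np.ndarray, rng: np.random.Generator,
                  n_boot: int, level: float = 0.95) -> tuple[float, float]:
    if values.size == 0:
        return float("nan"), float("nan")
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    means = values[idx].mean(axis=1)
    lo, hi = np.percentile(means, [100 * (1 - level) / 2, 100 * (1 + level) / 2])
    return float(lo), float(hi)


def aggregate_sweep(sweep: pd.DataFrame, n_boot: int = 2000,
                    seed: int = 0) -> pd.DataFrame:
    """Mean Dice and percent-removed per (model, threshold) over samples.

    Samples with undefined Dice (empty retention) are excluded from the Dice
    average but counted in ``n_undefined``.  95% confidence intervals use a
    seeded percentile bootstrap over samples.
    """
    rng = np.random.default_rng(int(seed))
    rows = []
    for (model_id, thr), grp in sweep.groupby(["model_id", "threshold"], sort=True):
        dice = grp.loc[grp["defined"], "dice_mean"].to_numpy(dtype=float)
        prem = grp["percent_removed"].to_numpy(dtype=float)
        d_lo, d_hi = _bootstrap_ci(dice, rng, n_boot)
        p_lo, p_hi = _bootstrap_ci(prem, rng, n_boot)
        rows.append({
            "model_id": model_id,
            "threshold": float(thr),
            "dice_mean": float(dice.mean()) if dice.size else float("nan"),
            "dice_ci_lo": d_lo,
            "dice_ci_hi": d_hi,
            "percent_removed": float(prem.mean()),
            "percent_removed_ci_lo": p_lo,
            "percent_removed_ci_hi": p_hi,
            "n_samples": int(len(grp)),
            "n_undefined": int((~grp["defined"]).sum()),
        })
    return pd.DataFrame(rows)


# ------------------------------------------------------------------ statistics

@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float          # min(R+, R-) over nonzero differences
    p_value: float
    n_nonzero: int
    method: str               # "exact" (sign-flip enumeration) or "approx"
    significant_after_bonferroni: bool
    all_zero: bool = False


_EXACT_LIMIT = 16  # 2^16 sign patterns enumerate in milliseconds


def _signed_rank_min(d: np.ndarray) -> float:
    ranks = stats.rankdata(np.abs(d))  # midranks under ties
    r_pos = ranks[d > 0].sum()
    r_neg = ranks[d < 0].sum()
    return float(min(r_pos, r_neg))


def wilcoxon_paired(dice_a, dice_b, n_comparisons: int = 1,
                    alpha: float = 0.05) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired per-image scores.

    Zero differences are dropped.  For n <= 16 nonzero pairs the p-value is
    exact: every sign pattern of the (midrank-tied) ranks is enumerated and
    p = P0(min rank sum <= observed).  For 17 <= n <= 25 without ties the
    exact signed-rank null distribution is used; otherwise the normal
    approximation with continuity correction.  Significance is tested at
    ``alpha / n_comparisons`` (Bonferroni).
    """
    a = np.asarray(dice_a, dtype=float)
    b = np.asarray(dice_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("dice_a and dice_b must be equal-length 1-D arrays")
    if a.size < 5:
        raise ValueError("need at least 5 pairs")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n == 0:
        return WilcoxonResult(statistic=0.0, p_value=1.0, n_nonzero=0,
                              method="degenerate", all_zero=True,
                              significant_after_bonferroni=False)
    w_obs = _signed_rank_min(d)
    if n <= _EXACT_LIMIT:
        ranks = stats.rankdata(np.abs(d))
        total = ranks.sum()
        signs = ((np.arange(2 ** n)[:, None] >> np.arange(n)) & 1).astype(bool)
        r_pos = np.where(signs, ranks, 0.0).sum(axis=1)
        w_all = np.minimum(r_pos, total - r_pos)
        p = float(np.mean(w_all <= w_obs + 1e-9))
        method = "exact"
    elif n <= 25 and np.unique(np.abs(d)).size == n:
        res = stats.wilcoxon(d, zero_method="wilcox", method="exact")
        p = float(res.pvalue)
        method = "exact"
    else:
        res = stats.wilcoxon(d, zero_method="wilcox", correction=True,
                             method="approx")
        p = float(res.pvalue)
        method = "approx"
    return WilcoxonResult(statistic=w_obs, p_value=p, n_nonzero=n,
                          method=method,
                          significant_after_bonferroni=p < alpha / n_comparisons)


@dataclass(frozen=True)
class PearsonResult:
    rho: float
    p_value: float
    n: int
    defined: bool


def pearson_tradeoff(aggregated: pd.DataFrame, model_id: str,
                     dice_col: str = "dice_mean",
                     removed_col: str = "percent_removed") -> PearsonResult:
    """Pearson correlation of mean Dice vs mean percent removed across thresholds."""
    sub = aggregated[aggregated["model_id"] == model_id].dropna(subset=[dice_col])
    x = sub[removed_col].to_numpy(dtype=float)
    y = sub[dice_col].to_numpy(dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 thresholds with defined aggregates")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return PearsonResult(rho=float("nan"), p_value=float("nan"),
                             n=x.size, defined=False)
    r, p = stats.pearsonr(x, y)
    return PearsonResult(rho=float(r), p_value=float(p), n=x.size, defined=True)


def pairwise_wilcoxon(per_sample_dice: dict[str, np.ndarray],
                      alpha: float = 0.05) -> pd.DataFrame:
    """All pairwise model comparisons, Bonferroni-adjusted for their count."""
    names = sorted(per_sample_dice)
    pairs = list(combinations(names, 2))
    rows = []
    for a_name, b_name in pairs:
        res = wilcoxon_paired(per_sample_dice[a_name], per_sample_dice[b_name],
                              n_comparisons=len(pairs), alpha=alpha)
        rows.append({"model_a": a_name, "model_b": b_name,
                     "statistic": res.statistic, "p_value": res.p_value,
                     "n_nonzero": res.n_nonzero, "method": res.method,
                     "significant_after_bonferroni": res.significant_after_bonferroni})
    return pd.DataFrame(rows)
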