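#!/usr/bin/env python
"""Entropy-threshold sweep and statistics on the held-out test set.

Reads the inference maps, scores each model against both graders at
thresholds from 1% to 100% of the 1-bit entropy maximum, aggregates with
bootstrap confidence intervals, and runs the paired Wilcoxon and Pearson
trade-off analyses.  Tables go to results/eval/.
"""

import argparse
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from gaseg import io as gio
from gaseg.cli import _load_maps
from gaseg.evaluation import (EntropyThresholdGrid, aggregate_sweep,
                              pairwise_wilcoxon, pearson_tradeoff,
                              threshold_sweep)
from gaseg.pipeline import DESK, _sub_seed


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--data", default="results/data")
    ap.add_argument("--maps", default="results/maps")
    ap.add_argument("--out", default="results/eval")
    args = ap.parse_args()

    samples, _cfg = gio.read_dataset(args.data)
    test_set = samples[DESK.n_samples - DESK.n_test:]
    graders = {s.sample_id: (s.grader1, s.grader2) for s in test_set}
    prob_maps, ent_maps = _load_maps(Path(args.maps))
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    sweep = threshold_sweep(prob_maps, ent_maps, graders, EntropyThresholdGrid())
    sweep.to_csv(out / "sweep.csv", index=False)
    agg = aggregate_sweep(sweep, n_boot=DESK.bootstrap_resamples,
                          seed=_sub_seed(args.seed, 4))
    agg.to_csv(out / "aggregate.csv", index=False)

    print("mean Dice (two-grader average) at selected thresholds:")
    for m in sorted(prob_maps):
        row10 = agg[(agg.model_id == m) & np.isclose(agg.threshold, 0.10)].iloc[0]
        row100 = agg[(agg.model_id == m) & np.isclose(agg.threshold, 1.00)].iloc[0]
        print(f"  {m:>12}: {row10.dice_mean:.3f} at 10% "
              f"({row10.percent_removed:.1f}% removed) | "
              f"{row100.dice_mean:.3f} at 100%")

    at10 = sweep[np.isclose(sweep.threshold, 0.10)]
    per_sample = {m: at10[at10.model_id == m].sort_values("sample_id")
                  ["dice_mean"].to_numpy(dtype=float) for m in prob_maps}
    wtab = pairwise_wilcoxon(per_sample)
    wtab.to_csv(out / "wilcoxon.csv", index=False)
    print("\npairwise Wilcoxon signed-rank (Bonferroni-adjusted):")
    print(wtab.to_string(index=False))

    pearson = {m: asdict(pearson_tradeoff(agg, m)) for m in sorted(prob_maps)}
    (out / "pearson.json").write_text(json.dumps(pearson, indent=2, sort_keys=True))
    print("\nPearson rho (mean Dice vs % removed across thresholds):")
    for m, res in pearson.items():
        print(f"  {m:>12}: rho {res['rho']:+.3f} (p {res['p_value']:.3g})")


if __name__ == "__main__":
    main()
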