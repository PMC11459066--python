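#!/usr/bin/env python
"""Bayesian inference on the held-out test set.

For each test image writes three probability maps and their entropy maps:
the single baseline model (UNet-1), the ensemble average (UNet-Avg), and
Monte Carlo dropout averaged over T runs (UNet-DropT, T = 4 and 16).
Maps go to results/maps/ as 32-bit float TIFFs.
"""

import argparse
from pathlib import Path

from gaseg import io as gio
from gaseg.inference import (ensemble_predict, entropy_map,
                             mc_dropout_predict, predict)
from gaseg.pipeline import DESK, _sub_seed
from gaseg.unet import load_model


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--data", default="results/data")
    ap.add_argument("--models", default="results/models")
    ap.add_argument("--out", default="results/maps")
    args = ap.parse_args()

    samples, _cfg = gio.read_dataset(args.data)
    test_set = samples[DESK.n_samples - DESK.n_test:]
    models_dir = Path(args.models)
    members = [load_model(p) for p in sorted(models_dir.glob("unet[0-9]*.npz"))]
    drop = load_model(models_dir / "unetdrop.npz")
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    n_high = {m: 0.0 for m in ("UNet-1", "UNet-Avg", f"UNet-Drop{max(DESK.mc_T)}")}
    for i, s in enumerate(test_set):
        maps = {"UNet-1": predict(members[0], s.image),
                "UNet-Avg": ensemble_predict(members, s.image)}
        for T in DESK.mc_T:
            maps[f"UNet-Drop{T}"] = mc_dropout_predict(
                drop, s.image, T, seed=_sub_seed(args.seed, 100 + i))
        for model_id, pm in maps.items():
            ent = entropy_map(pm)
            gio.save_float_tiff(pm.values, out / f"prob_{model_id}_{s.sample_id}.tiff")
            gio.save_float_tiff(ent.values, out / f"ent_{model_id}_{s.sample_id}.tiff")
            if model_id in n_high:
                n_high[model_id] += (ent.values > 0.10).sum() / len(test_set)

    print(f"wrote maps for {len(test_set)} test samples to {out}")
    print("mean pixels with entropy > 10% of max per image:")
    for model_id, v in n_high.items():
        print(f"  {model_id:>12}: {v:8.1f}")


if __name__ == "__main__":
    main()
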