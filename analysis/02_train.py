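#!/usr/bin/env python
"""Train the cross-validation ensemble and the Monte Carlo dropout model.

Reads the cohort from results/data/, trains 3 standard-variant members by
3-fold cross-validation on the training pool plus one drop-variant model,
and writes checkpoints and per-epoch logs to results/models/.  The loss is
Dice loss + 0.001 * Hoyer-Square over convolution kernels, optimised with
Adam under a 0.999-per-epoch multiplicative learning-rate decay.
"""

import argparse
from pathlib import Path

from gaseg import io as gio
from gaseg.pipeline import DESK, _sub_seed
from gaseg.train import train_ensemble, train_model
from gaseg.unet import UNet, save_model


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--data", default="results/data")
    ap.add_argument("--out", default="results/models")
    args = ap.parse_args()

    samples, _cfg = gio.read_dataset(args.data)
    train_pool = samples[: DESK.n_samples - DESK.n_test]
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    tr_cfg = DESK.train_config(_sub_seed(args.seed, 1))
    members, logs, folds = train_ensemble(train_pool, DESK.ensemble_k,
                                          DESK.model_config("standard"), tr_cfg)
    for j, (m, log) in enumerate(zip(members, logs), start=1):
        save_model(m, out / f"unet{j}.npz")
        log.to_csv(out / f"training_log_unet{j}.csv", index=False)
        print(f"UNet-{j}: dice loss {log['dice_loss'].iloc[0]:.3f} -> "
              f"{log['dice_loss'].iloc[-1]:.3f}, "
              f"val Dice {log['val_dice'].iloc[-1]:.3f}")

    drop_train = [s for s in train_pool if folds.assignments[s.sample_id] != 0]
    drop_val = [s for s in train_pool if folds.assignments[s.sample_id] == 0]
    drop = UNet(DESK.model_config("drop"), seed=_sub_seed(args.seed, 2))
    drop_log = train_model(drop, drop_train, drop_val,
                           DESK.train_config(_sub_seed(args.seed, 3)))
    save_model(drop, out / "unetdrop.npz")
    drop_log.to_csv(out / "training_log_unetdrop.csv", index=False)
    print(f"UNet-Drop: dice loss {drop_log['dice_loss'].iloc[0]:.3f} -> "
          f"{drop_log['dice_loss'].iloc[-1]:.3f} "
          "(deterministic val Dice is not meaningful with dropout left on)")


if __name__ == "__main__":
    main()
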