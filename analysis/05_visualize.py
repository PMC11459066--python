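#!/usr/bin/env python
"""Figures: certainty overlays, Dice-vs-threshold curves, trade-off plot.

Overlays render certain-GA pixels in saturated red and certain-background
pixels in saturated blue, fading to white as entropy rises; the curve and
trade-off figures summarise the aggregate sweep.  Output: results/figures/.
"""

import argparse
from pathlib import Path

import pandas as pd
from PIL import Image

from gaseg import io as gio
from gaseg import viz
from gaseg.cli import _load_maps
from gaseg.pipeline import DESK


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", default="results/data")
    ap.add_argument("--maps", default="results/maps")
    ap.add_argument("--eval", dest="eval_dir", default="results/eval")
    ap.add_argument("--out", default="results/figures")
    args = ap.parse_args()

    samples, _cfg = gio.read_dataset(args.data)
    test_set = samples[DESK.n_samples - DESK.n_test:]
    prob_maps, ent_maps = _load_maps(Path(args.maps))
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    for model_id, per in prob_maps.items():
        for s in test_set[:3]:
            rgb = viz.render_overlay(s.image, per[s.sample_id],
                                     ent_maps[model_id][s.sample_id])
            Image.fromarray(rgb).save(out / f"overlay_{model_id}_{s.sample_id}.png")

    agg = pd.read_csv(Path(args.eval_dir) / "aggregate.csv")
    viz.plot_dice_vs_threshold(agg, out / "dice_vs_threshold.png")
    viz.plot_tradeoff(agg, out / "tradeoff.png")
    print(f"figures -> {out}")


if __name__ == "__main__":
    main()
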