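"""Raster and tabular I/O: PNG images, 0/255 PNG masks, float TIFF maps,
YAML configs and JSON run manifests."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import tifffile
import yaml
from PIL import Image

from gaseg.synthetic import SyntheticConfig, SyntheticSample

__all__ = ["save_image_png", "load_image_png", "save_mask_png", "load_mask_png",
           "save_float_tiff", "load_float_tiff", "save_config_yaml",
           "load_config_yaml", "write_manifest", "read_manifest",
           "write_dataset", "read_dataset"]


def save_image_png(image: np.ndarray, path) -> None:
    """(C, H, W) float [0,1] -> 8-bit PNG (grayscale or RGB)."""
    arr = np.clip(np.asarray(image), 0, 1)
    if arr.ndim != 3:
        raise ValueError("image must be (C, H, W)")
    u8 = np.round(arr * 255).astype(np.uint8)
    if u8.shape[0] == 1:
        Image.fromarray(u8[0], mode="L").save(path)
    elif u8.shape[0] == 3:
        Image.fromarray(u8.transpose(1, 2, 0), mode="RGB").save(path)
    else:
        raise ValueError("PNG export supports 1 or 3 channels")


def load_image_png(path) -> np.ndarray:
    arr = np.asarray(Image.open(path), dtype=np.float32) / 255.0
    if arr.ndim == 2:
        arr = arr[None]
    else:
        arr = arr.transpose(2, 0, 1)
    return arr


def save_mask_png(mask: np.ndarray, path) -> None:
    Image.fromarray((np.asarray(mask) > 0).astype(np.uint8) * 255, mode="L").save(path)


def load_mask_png(path) -> np.ndarray:
    return (np.asarray(Image.open(path)) > 127).astype(np.uint8)


def save_float_tiff(values: np.ndarray, path) -> None:
    tifffile.imwrite(path, np.asarray(values, dtype=np.float32))


def load_float_tiff(path) -> np.ndarray:
    return tifffile.imread(path)


def save_config_yaml(config: SyntheticConfig | dict, path) -> None:
    d = config.to_dict() if isinstance(config, SyntheticConfig) else dict(config)
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def load_config_yaml(path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def write_manifest(path, *, command: str, seed: int, config: dict,
                   outputs: dict) -> None:
    manifest = {"command": command, "seed": seed, "config": config,
                "config_hash": config_hash(config), "outputs": outputs}
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())


def write_dataset(samples: list[SyntheticSample], config: SyntheticConfig,
                  outdir) -> Path:
    """Write PNGs per sample plus a manifest CSV and YAML config; returns outdir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = ["sample_id,image,truth,grader1,grader2"]
    for s in samples:
        paths = {}
        for kind in ("image", "truth", "grader1", "grader2"):
            paths[kind] = f"{s.sample_id}_{kind}.png"
        save_image_png(s.image, outdir / paths["image"])
        for kind in ("truth", "grader1", "grader2"):
            save_mask_png(getattr(s, kind), outdir / paths[kind])
        rows.append(",".join([s.sample_id] + [paths[k] for k in
                                              ("image", "truth", "grader1", "grader2")]))
    (outdir / "manifest.csv").write_text("\n".join(rows) + "\n")
    save_config_yaml(config, outdir / "config.yaml")
    return outdir


def read_dataset(outdir) -> tuple[list[SyntheticSample], SyntheticConfig]:
    outdir = Path(outdir)
    config = SyntheticConfig.from_dict(load_config_yaml(outdir / "config.yaml"))
    lines = (outdir / "manifest.csv").read_text().strip().splitlines()[1:]
    samples = []
    for line in lines:
        sid, img, tru, g1, g2 = line.split(",")
        samples.append(SyntheticSample(
            image=load_image_png(outdir / img),
            truth=load_mask_png(outdir / tru),
            grader1=load_mask_png(outdir / g1),
            grader2=load_mask_png(outdir / g2),
            sample_id=sid,
        ))
    return samples, config
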