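"""Seeded synthetic en-face-like images with lesions and paired grader masks.

The generator emulates the statistical structure the analysis needs from
pseudo-color en face OCT imagery of geographic atrophy: one or more bright,
irregular lesion blobs (hypertransmission appears bright on sub-RPE slabs)
on a darker noisy background, a ground-truth binary mask, and two simulated
grader annotations that agree on lesion cores but disagree at boundaries and
on small satellite lesions.  It makes no attempt to model OCT physics or the
morphology statistics of real GA.

Lesions are ellipses whose radius is modulated by a smooth random Fourier
perturbation; graders are simulated by warping the truth boundary with a
smooth displacement field and randomly deleting/adding small satellites.
Everything is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage
from skimage.draw import disk as draw_disk
from skimage.draw import polygon as draw_polygon

__all__ = [
    "SyntheticConfig",
    "SyntheticSample",
    "generate_lesion_mask",
    "render_enface",
    "simulate_grader",
    "generate_dataset",
]

# stream separators so mask/image/grader draws never share an rng stream
_ROLE_MASK, _ROLE_RENDER, _ROLE_GRADER = 0, 1, 2


@dataclass(frozen=True)
class SyntheticConfig:
    image_height: int = 128
    image_width: int = 128
    n_channels: int = 3
    n_lesions_range: tuple[int, int] = (1, 3)
    lesion_radius_range: tuple[float, float] = (8.0, 24.0)
    boundary_roughness: float = 0.3
    background_intensity: float = 0.25
    lesion_intensity: float = 0.75
    noise_sd: float = 0.05
    grader_boundary_sd: float = 1.5
    grader_satellite_flip_prob: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.image_height % 16 or self.image_width % 16:
            raise ValueError("image dims must be divisible by 16 "
                             f"(got {self.image_height}x{self.image_width})")
        if not self.lesion_intensity > self.background_intensity:
            raise ValueError("lesion_intensity must exceed background_intensity")
        for name in ("background_intensity", "lesion_intensity", "noise_sd",
                     "grader_satellite_flip_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.boundary_roughness < 0 or self.grader_boundary_sd < 0:
            raise ValueError("roughness and grader_boundary_sd must be >= 0")
        lo, hi = self.n_lesions_range
        if lo < 0 or hi < lo:
            raise ValueError("invalid n_lesions_range")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["n_lesions_range"] = list(d["n_lesions_range"])
        d["lesion_radius_range"] = list(d["lesion_radius_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        d["n_lesions_range"] = tuple(d["n_lesions_range"])
        d["lesion_radius_range"] = tuple(d["lesion_radius_range"])
        return cls(**d)


@dataclass
class SyntheticSample:
    image: np.ndarray          # (C, H, W) float32 in [0, 1]
    truth: np.ndarray          # (H, W) uint8 {0, 1}
    grader1: np.ndarray
    grader2: np.ndarray
    sample_id: str = ""

    def __post_init__(self):
        hw = self.image.shape[1:]
        for name in ("truth", "grader1", "grader2"):
            m = getattr(self, name)
            if m.shape != hw:
                raise ValueError(f"{name} shape {m.shape} != image spatial {hw}")
            if not np.isin(m, (0, 1)).all():
                raise ValueError(f"{name} must be strictly binary")


def _rng(seed: int, role: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), role]))


def _rough_radius(rng: np.random.Generator, base: float, roughness: float,
                  phi: np.ndarray) -> np.ndarray:
    """Ellipse radius modulated by a smooth random Fourier series (rms ~= 1)."""
    aspect = rng.uniform(0.55, 1.0)
    theta0 = rng.uniform(0, 2 * np.pi)
    a, b = base, base * aspect
    ell = a * b / np.sqrt((b * np.cos(phi - theta0)) ** 2
                          + (a * np.sin(phi - theta0)) ** 2)
    noise = np.zeros_like(phi)
    for k in range(2, 6):
        noise += rng.normal(0, 1.0 / k) * np.cos(k * phi)
        noise += rng.normal(0, 1.0 / k) * np.sin(k * phi)
    rms = np.sqrt(np.mean(noise ** 2))
    if rms > 0:
        noise /= rms
    return np.maximum(ell * (1.0 + roughness * noise), 1.0)


def generate_lesion_mask(config: SyntheticConfig, sample_seed: int) -> np.ndarray:
    """Binary mask: union of 0+ irregular blobs; deterministic in the seed."""
    rng = _rng(sample_seed, _ROLE_MASK)
    h, w = config.image_height, config.image_width
    mask = np.zeros((h, w), dtype=np.uint8)
    lo, hi = config.n_lesions_range
    n = int(rng.integers(lo, hi + 1))
    phi = np.linspace(0, 2 * np.pi, 180, endpoint=False)
    rmin, rmax = config.lesion_radius_range
    for _ in range(n):
        base = rng.uniform(rmin, rmax)
        margin = min(base + 2.0, min(h, w) / 2.0 - 1.0)
        cy = rng.uniform(margin, h - margin)
        cx = rng.uniform(margin, w - margin)
        r = _rough_radius(rng, base, config.boundary_roughness, phi)
        rows = cy + r * np.sin(phi)
        cols = cx + r * np.cos(phi)
        rr, cc = draw_polygon(rows, cols, shape=(h, w))
        mask[rr, cc] = 1
    return mask


def render_enface(truth: np.ndarray, config: SyntheticConfig,
                  sample_seed: int) -> np.ndarray:
    """Render an n-channel image from a lesion mask.

    Pixel means are ``lesion_intensity`` inside lesions and
    ``background_intensity`` outside, plus iid Gaussian noise of sd
    ``noise_sd`` per channel, clipped to [0, 1].
    """
    if truth.shape != (config.image_height, config.image_width):
        raise ValueError(f"mask shape {truth.shape} does not match config "
                         f"{config.image_height}x{config.image_width}")
    rng = _rng(sample_seed, _ROLE_RENDER)
    base = np.where(truth > 0, config.lesion_intensity,
                    config.background_intensity).astype(np.float32)
    img = np.broadcast_to(base, (config.n_channels,) + base.shape).copy()
    if config.noise_sd > 0:
        img += rng.normal(0, config.noise_sd, size=img.shape).astype(np.float32)
    return np.clip(img, 0.0, 1.0)


def _smooth_displacement(rng: np.random.Generator, shape: tuple[int, int],
                         sd: float) -> np.ndarray:
    """(2, H, W) smooth field with per-component sd ``sd``, |v| clipped < 2 sd."""
    fields = rng.normal(0, 1.0, size=(2,) + shape)
    fields = ndimage.gaussian_filter(fields, sigma=(0, 6, 6))
    for c in range(2):
        s = fields[c].std()
        if s > 0:
            fields[c] *= sd / s
    norm = np.sqrt(fields[0] ** 2 + fields[1] ** 2)
    cap = 1.99 * sd
    scale = np.where(norm > cap, cap / (norm + 1e-12), 1.0)
    return fields * scale


def simulate_grader(truth: np.ndarray, config: SyntheticConfig,
                    grader_seed: int) -> np.ndarray:
    """Perturb a truth mask into a plausible human grading.

    The boundary is warped by a smooth random displacement field of sd
    ``grader_boundary_sd`` pixels (magnitude capped below 2 sd, so pixels at
    least 2 sd inside the lesion are always preserved), then small satellite
    components are deleted — and an extra one occasionally added — with
    probability ``grader_satellite_flip_prob``.
    """
    if not np.isin(truth, (0, 1)).all():
        raise ValueError("truth mask must be binary")
    rng = _rng(grader_seed, _ROLE_GRADER)
    h, w = truth.shape
    sd = config.grader_boundary_sd
    out = truth.astype(np.float64)
    if sd > 0:
        disp = _smooth_displacement(rng, (h, w), sd)
        rows, cols = np.mgrid[0:h, 0:w].astype(np.float64)
        out = ndimage.map_coordinates(out, [rows + disp[0], cols + disp[1]],
                                      order=1, mode="nearest")
    warped = (out > 0.5).astype(np.uint8)
    if sd > 0:
        # hard guarantee: lesion core (>= 2 sd inside the boundary) survives
        core = ndimage.distance_transform_edt(truth) >= 2.0 * sd
        warped[core] = 1

    p = config.grader_satellite_flip_prob
    if p > 0:
        labels, n = ndimage.label(warped)
        if n > 1:
            areas = ndimage.sum_labels(warped, labels, index=np.arange(1, n + 1))
            biggest = areas.max()
            for i, area in enumerate(areas, start=1):
                if area < 0.25 * biggest and rng.random() < p:
                    warped[labels == i] = 0
        if rng.random() < p:  # spurious small satellite seen by this grader only
            r = rng.uniform(2.0, 4.5)
            cy = rng.uniform(r + 1, h - r - 1)
            cx = rng.uniform(r + 1, w - r - 1)
            rr, cc = draw_disk((cy, cx), r, shape=(h, w))
            warped[rr, cc] = 1
    return warped


def sample_seed_for(config_seed: int, index: int, role: int) -> int:
    """Stable per-sample seed; adding samples never changes earlier ones."""
    ss = np.random.SeedSequence([int(config_seed), int(index), int(role)])
    return int(ss.generate_state(1)[0] % np.uint32(2 ** 31))


def generate_dataset(config: SyntheticConfig, n_samples: int) -> list[SyntheticSample]:
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    samples = []
    for i in range(n_samples):
        ms = sample_seed_for(config.seed, i, 0)
        truth = generate_lesion_mask(config, ms)
        image = render_enface(truth, config, sample_seed_for(config.seed, i, 1))
        g1 = simulate_grader(truth, config, sample_seed_for(config.seed, i, 2))
        g2 = simulate_grader(truth, config, sample_seed_for(config.seed, i, 3))
        samples.append(SyntheticSample(image=image, truth=truth, grader1=g1,
                                       grader2=g2, sample_id=f"s{i:04d}"))
    return samples
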