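"""Synthetic endoscopy-like fixtures: blob "polyps" on mucosa background.

Each image carries one or more smooth foreground regions (randomly
deformed ellipses, brighter and redder than the surrounding tissue) on a
textured pinkish background with optional vignetting and specular
highlights, loosely emulating colonoscopy frames.  The ground-truth mask
is the *exact* rasterised union of the analytic blob regions: a pixel is
foreground iff its centre lies inside a blob boundary, so tests can
verify masks by an independent point-in-region oracle.

Everything is deterministic under ``SyntheticConfig.seed``; per-image
randomness comes from ``SeedSequence([seed, image_index])``.
"""

from __future__ import annotations

import dataclasses
from typing import Any

import numpy as np
from skimage.filters import gaussian as _sk_gaussian

from .pairs import ImageMaskPair

_MAX_TRIES = 60


@dataclasses.dataclass
class SyntheticConfig:
    n_images: int = 16
    image_size: tuple[int, int] = (224, 224)
    n_polyps_range: tuple[int, int] = (1, 3)
    polyp_area_fraction_range: tuple[float, float] = (0.05, 0.30)
    texture_noise_sd: float = 0.04
    specular_prob: float = 0.5
    vignette_strength: float = 0.35
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.polyp_area_fraction_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError(
                f"polyp_area_fraction_range must lie inside (0,1), "
                f"got {self.polyp_area_fraction_range}")
        if self.n_polyps_range[0] < 1 or self.n_polyps_range[0] > self.n_polyps_range[1]:
            raise ValueError(f"invalid n_polyps_range {self.n_polyps_range}")
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")
        if min(self.image_size) < 16:
            raise ValueError("image_size must be at least 16x16")


@dataclasses.dataclass
class BlobParams:
    """An analytically-defined deformed ellipse.

    In local coordinates (rotate by -theta, divide x by aspect) the
    boundary is r(phi) = r0 * (1 + sum_k amp_k * cos(k*phi + phase_k)).
    """

    center: tuple[float, float]          # (row, col) in pixels
    r0: float                            # base radius, pixels
    aspect: float                        # x-axis stretch factor
    theta: float                         # rotation, radians
    harmonics: list[tuple[int, float, float]]  # (k, amp, phase)

    def to_json(self) -> dict[str, Any]:
        return {"center": list(self.center), "r0": self.r0,
                "aspect": self.aspect, "theta": self.theta,
                "harmonics": [list(h) for h in self.harmonics]}


def rasterize_blob(shape: tuple[int, int], blob: BlobParams) -> np.ndarray:
    """Exact point-in-region rasterisation of one blob -> bool mask."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    dy = yy - blob.center[0]
    dx = xx - blob.center[1]
    ct, st = np.cos(blob.theta), np.sin(blob.theta)
    lx = (ct * dx + st * dy) / blob.aspect
    ly = -st * dx + ct * dy
    r = np.hypot(lx, ly)
    phi = np.arctan2(ly, lx)
    boundary = np.full(shape, blob.r0)
    for k, amp, phase in blob.harmonics:
        boundary = boundary + blob.r0 * amp * np.cos(k * phi + phase)
    return r <= boundary


def _sample_blobs(rng: np.random.Generator, shape: tuple[int, int],
                  cfg: SyntheticConfig) -> tuple[np.ndarray, list[BlobParams]]:
    """Draw blobs until the union area fraction lands in the target range."""
    h, w = shape
    lo, hi = cfg.polyp_area_fraction_range
    n_lo, n_hi = cfg.n_polyps_range
    for _ in range(_MAX_TRIES):
        n = int(rng.integers(n_lo, n_hi + 1))
        target = rng.uniform(lo, hi)
        shares = rng.dirichlet(np.full(n, 4.0))
        shares = 0.5 / n + 0.5 * shares  # keep every blob non-degenerate
        blobs: list[BlobParams] = []
        centers: list[tuple[float, float]] = []
        for i in range(n):
            aspect = float(rng.uniform(0.65, 1.45))
            area = target * shares[i] * h * w
            r0 = float(np.sqrt(area / (np.pi * aspect)))
            cy = cx = None
            for _ in range(20):  # prefer well-separated centres
                cy = float(rng.uniform(0.15 * h, 0.85 * h))
                cx = float(rng.uniform(0.15 * w, 0.85 * w))
                if all(np.hypot(cy - oy, cx - ox) > 0.8 * (r0 + ob.r0)
                       for (oy, ox), ob in zip(centers, blobs)):
                    break
            harmonics = [(int(k), float(rng.uniform(0.0, 0.14)),
                          float(rng.uniform(0, 2 * np.pi)))
                         for k in rng.choice([2, 3, 4, 5], size=3, replace=False)]
            blob = BlobParams(center=(cy, cx), r0=r0, aspect=aspect,
                              theta=float(rng.uniform(0, np.pi)),
                              harmonics=harmonics)
            blobs.append(blob)
            centers.append((cy, cx))
        union = np.zeros(shape, dtype=bool)
        for b in blobs:
            union |= rasterize_blob(shape, b)
        frac = union.mean()
        if lo <= frac <= hi:
            return union, blobs
    raise RuntimeError(
        f"could not satisfy area fraction range {cfg.polyp_area_fraction_range} "
        f"after {_MAX_TRIES} attempts; constraints may be infeasible for "
        f"image size {shape}")


def _render_image(rng: np.random.Generator, mask: np.ndarray,
                  cfg: SyntheticConfig) -> np.ndarray:
    """Paint the mucosa background, polyp interiors and photometric effects."""
    h, w = mask.shape
    base = np.array([rng.uniform(160, 195), rng.uniform(90, 120),
                     rng.uniform(80, 110)])
    img = np.broadcast_to(base, (h, w, 3)).astype(np.float64).copy()

    # low-frequency multiplicative texture
    coarse = rng.normal(0.0, 1.0, (-(-h // 12), -(-w // 12)))
    field = _sk_gaussian(np.kron(coarse, np.ones((12, 12)))[:h, :w], sigma=6)
    img *= (1.0 + cfg.texture_noise_sd * 3.0 * field)[..., None]

    # polyp interior: brighter and redder, feathered edge for realism
    alpha = _sk_gaussian(mask.astype(np.float64), sigma=1.5)[..., None]
    polyp_color = base * np.array([1.28, 1.08, 1.02]) + np.array([12.0, 0.0, 0.0])
    img = (1 - alpha) * img + alpha * np.broadcast_to(polyp_color, (h, w, 3))

    # vignetting
    yy, xx = np.mgrid[0:h, 0:w]
    r2 = ((yy - h / 2) ** 2 + (xx - w / 2) ** 2) / ((h / 2) ** 2 + (w / 2) ** 2)
    img *= (1.0 - cfg.vignette_strength * r2)[..., None]

    # specular highlights (image-only distractors)
    if rng.random() < cfg.specular_prob:
        for _ in range(int(rng.integers(1, 4))):
            sy, sx = rng.uniform(0.1 * h, 0.9 * h), rng.uniform(0.1 * w, 0.9 * w)
            sr = rng.uniform(0.01, 0.03) * min(h, w)
            bump = np.exp(-(((yy - sy) ** 2 + (xx - sx) ** 2) / (2 * sr ** 2)))
            img += 220.0 * bump[..., None]

    img += rng.normal(0.0, cfg.texture_noise_sd * 40.0, (h, w, 3))
    return np.clip(img, 0, 255).round().astype(np.uint8)


def generate_synthetic_dataset(
        cfg: SyntheticConfig, return_manifest: bool = False
) -> list[ImageMaskPair] | tuple[list[ImageMaskPair], dict[str, Any]]:
    """Generate ``cfg.n_images`` image/mask pairs (optionally + manifest)."""
    pairs: list[ImageMaskPair] = []
    records = []
    for i in range(cfg.n_images):
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, i]))
        mask, blobs = _sample_blobs(rng, cfg.image_size, cfg)
        image = _render_image(rng, mask, cfg)
        pid = f"synthetic_{i:04d}"
        pairs.append(ImageMaskPair(image=image, mask=mask.astype(np.uint8), id=pid))
        records.append({"id": pid, "blobs": [b.to_json() for b in blobs]})
    if return_manifest:
        manifest = {"config": dataclasses.asdict(cfg), "images": records}
        return pairs, manifest
    return pairs
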