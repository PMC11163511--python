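"""Training-time augmentation: rotation, flips, Gaussian blur, resize.

The same geometric transform is applied to the image and its mask; the
mask is resampled nearest-neighbour so it stays binary, and photometric
blur touches the image only.  Each sample draws its randomness from a
dedicated stream derived from (global seed, sample id) so augmentation
is reproducible regardless of iteration order.
"""

from __future__ import annotations

import dataclasses
import zlib

import numpy as np
from skimage.filters import gaussian as _sk_gaussian
from skimage.transform import rotate as _sk_rotate

from .pairs import ImageMaskPair, resize_pair


@dataclasses.dataclass
class AugmentationConfig:
    """Rotation within +/-20 degrees, random flips and Gaussian blur,
    then resize to the network input size (224 x 224 by default)."""

    rotation_limit_deg: float = 20.0
    hflip_prob: float = 0.5
    vflip_prob: float = 0.5
    blur_prob: float = 0.5
    blur_sigma_range: tuple[float, float] = (0.1, 2.0)
    target_size: tuple[int, int] = (224, 224)
    seed: int = 0

    def __post_init__(self):
        for name in ("hflip_prob", "vflip_prob", "blur_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if min(self.target_size) <= 0:
            raise ValueError(f"target_size must be positive, got {self.target_size}")
        if self.rotation_limit_deg < 0:
            raise ValueError("rotation_limit_deg must be nonnegative")


def pair_rng(seed: int, pair_id: str, epoch: int = 0) -> np.random.Generator:
    """Per-sample random stream keyed by (seed, stable id hash, epoch)."""
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(pair_id.encode()), epoch]))


def augment_pair(pair: ImageMaskPair, cfg: AugmentationConfig,
                 rng: np.random.Generator) -> ImageMaskPair:
    """Apply one random augmentation draw, then resize to target size."""
    image, mask = pair.image, pair.mask

    if cfg.rotation_limit_deg > 0:
        angle = rng.uniform(-cfg.rotation_limit_deg, cfg.rotation_limit_deg)
        image = _sk_rotate(image, angle, order=1, mode="reflect",
                           preserve_range=True).round().astype(np.uint8)
        mask = _sk_rotate(mask, angle, order=0, mode="reflect",
                          preserve_range=True).astype(np.uint8)

    if cfg.hflip_prob > 0 and rng.random() < cfg.hflip_prob:
        image = image[:, ::-1]
        mask = mask[:, ::-1]
    if cfg.vflip_prob > 0 and rng.random() < cfg.vflip_prob:
        image = image[::-1]
        mask = mask[::-1]

    if cfg.blur_prob > 0 and rng.random() < cfg.blur_prob:
        sigma = rng.uniform(*cfg.blur_sigma_range)
        image = (_sk_gaussian(image.astype(np.float64) / 255.0, sigma=sigma,
                              channel_axis=-1) * 255.0).round().astype(np.uint8)

    out = ImageMaskPair(image=np.ascontiguousarray(image),
                        mask=np.ascontiguousarray(mask), id=pair.id)
    return resize_pair(out, cfg.target_size)
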