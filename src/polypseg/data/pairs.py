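"""Image/mask pair container, disk I/O, resizing and dataset splitting.

Datasets live on disk as ``<root>/images/*.{png,jpg,tif}`` and
``<root>/masks/*.png`` matched by filename stem.  Masks are stored as
8-bit PNG with values {0, 255} and binarised on load (pixel > 127 -> 1).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image
from skimage.transform import resize as _sk_resize

IMAGE_EXTENSIONS = (".png", ".jpg", ".jpeg", ".tif", ".tiff")


@dataclasses.dataclass
class ImageMaskPair:
    """One RGB endoscopy-style image with its aligned binary polyp mask."""

    image: np.ndarray  # H x W x 3 uint8
    mask: np.ndarray   # H x W uint8 in {0, 1}
    id: str

    def __post_init__(self):
        self.image = np.asarray(self.image)
        self.mask = np.asarray(self.mask)
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ValueError(f"pair '{self.id}': image must be HxWx3, "
                             f"got {self.image.shape}")
        if self.mask.ndim != 2:
            raise ValueError(f"pair '{self.id}': mask must be HxW, "
                             f"got {self.mask.shape}")
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError(
                f"pair '{self.id}': image {self.image.shape[:2]} and "
                f"mask {self.mask.shape} sizes differ")
        vals = np.unique(self.mask)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError(f"pair '{self.id}': mask values must be in "
                             f"{{0,1}}, found {vals[:5]}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


def binarize_mask(raw: np.ndarray, threshold: int = 127) -> np.ndarray:
    """8-bit mask -> {0,1}: pixel > threshold is foreground."""
    return (np.asarray(raw) > threshold).astype(np.uint8)


def _find_mask(mask_dir: Path, stem: str) -> Path | None:
    for ext in IMAGE_EXTENSIONS:
        cand = mask_dir / f"{stem}{ext}"
        if cand.exists():
            return cand
    return None


def load_dataset(image_dir: str | Path, mask_dir: str | Path) -> list[ImageMaskPair]:
    """Load all image/mask pairs, matched by stem and sorted by id."""
    image_dir, mask_dir = Path(image_dir), Path(mask_dir)
    for d in (image_dir, mask_dir):
        if not d.is_dir():
            raise FileNotFoundError(f"not a directory: {d}")
    pairs = []
    image_paths = sorted(p for p in image_dir.iterdir()
                         if p.suffix.lower() in IMAGE_EXTENSIONS)
    if not image_paths:
        raise FileNotFoundError(f"no images found in {image_dir}")
    for img_path in image_paths:
        mask_path = _find_mask(mask_dir, img_path.stem)
        if mask_path is None:
            raise FileNotFoundError(
                f"no mask found for image '{img_path.stem}' in {mask_dir}")
        image = np.asarray(Image.open(img_path).convert("RGB"))
        mask = binarize_mask(np.asarray(Image.open(mask_path).convert("L")))
        pairs.append(ImageMaskPair(image=image, mask=mask, id=img_path.stem))
    pairs.sort(key=lambda p: p.id)
    return pairs


def save_dataset(pairs: Sequence[ImageMaskPair], root: str | Path) -> None:
    """Write the on-disk layout: images/ and masks/ as PNG (mask {0,255})."""
    root = Path(root)
    (root / "images").mkdir(parents=True, exist_ok=True)
    (root / "masks").mkdir(parents=True, exist_ok=True)
    for p in pairs:
        Image.fromarray(p.image).save(root / "images" / f"{p.id}.png")
        Image.fromarray((p.mask * 255).astype(np.uint8)).save(
            root / "masks" / f"{p.id}.png")


def resize_pair(pair: ImageMaskPair, size: tuple[int, int]) -> ImageMaskPair:
    """Resize to (height, width): bilinear image, nearest-neighbour mask."""
    h, w = int(size[0]), int(size[1])
    if h <= 0 or w <= 0:
        raise ValueError(f"target size must be positive, got {size}")
    if (h, w) == pair.shape:
        return ImageMaskPair(pair.image.copy(), pair.mask.copy(), pair.id)
    image = _sk_resize(pair.image, (h, w), order=1, preserve_range=True,
                       anti_aliasing=False).round().astype(np.uint8)
    mask = _sk_resize(pair.mask, (h, w), order=0, preserve_range=True,
                      anti_aliasing=False).astype(np.uint8)
    return ImageMaskPair(image=image, mask=mask, id=pair.id)


def split_dataset(pairs: Sequence[ImageMaskPair], ratios: tuple[float, float],
                  seed: int) -> tuple[list[ImageMaskPair], list[ImageMaskPair]]:
    """Random disjoint train/test split; deterministic under ``seed``."""
    if not pairs:
        raise ValueError("cannot split an empty dataset")
    r_train, r_test = ratios
    if not np.isclose(r_train + r_test, 1.0):
        raise ValueError(f"split ratios must sum to 1, got {ratios}")
    if r_train < 0 or r_test < 0:
        raise ValueError(f"split ratios must be nonnegative, got {ratios}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    n_train = int(np.floor(r_train * len(pairs) + 0.5))
    train = [pairs[i] for i in sorted(order[:n_train])]
    test = [pairs[i] for i in sorted(order[n_train:])]
    return train, test
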