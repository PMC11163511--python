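"""Dataset I/O, augmentation, resizing, splitting, synthetic generation."""

import numpy as np
import pytest
from PIL import Image
from skimage.measure import label

from polypseg.data import (AugmentationConfig, ImageMaskPair, SyntheticConfig,
                           augment_pair, binarize_mask, generate_synthetic_dataset,
                           load_dataset, pair_rng, rasterize_blob, resize_pair,
                           save_dataset, split_dataset)
from polypseg.data.synthetic import BlobParams


def _toy_pairs(n=3, size=32, seed=0):
    rng = np.random.default_rng(seed)
    return [ImageMaskPair(
        image=rng.integers(0, 255, (size, size, 3), dtype=np.uint8),
        mask=(rng.random((size, size)) < 0.3).astype(np.uint8),
        id=f"pair_{i:02d}") for i in range(n)]


class TestLoadSave:
    def test_round_trip_preserves_pairs_sorted(self, tmp_path):
        pairs = _toy_pairs(3)
        save_dataset(pairs[::-1], tmp_path)  # write out of order
        loaded = load_dataset(tmp_path / "images", tmp_path / "masks")
        assert [p.id for p in loaded] == [p.id for p in pairs]
        for a, b in zip(pairs, loaded):
            np.testing.assert_array_equal(a.image, b.image)
            np.testing.assert_array_equal(a.mask, b.mask)

    def test_grayscale_mask_binarized(self, tmp_path):
        (tmp_path / "images").mkdir()
        (tmp_path / "masks").mkdir()
        img = np.zeros((8, 8, 3), np.uint8)
        mask255 = np.zeros((8, 8), np.uint8)
        mask255[:4] = 255
        Image.fromarray(img).save(tmp_path / "images" / "a.png")
        Image.fromarray(mask255).save(tmp_path / "masks" / "a.png")
        (loaded,) = load_dataset(tmp_path / "images", tmp_path / "masks")
        assert set(np.unique(loaded.mask)) == {0, 1}
        assert loaded.mask[:4].all() and not loaded.mask[4:].any()

    def test_missing_mask_names_orphan(self, tmp_path):
        (tmp_path / "images").mkdir()
        (tmp_path / "masks").mkdir()
        Image.fromarray(np.zeros((8, 8, 3), np.uint8)).save(
            tmp_path / "images" / "orphan.png")
        with pytest.raises(FileNotFoundError, match="orphan"):
            load_dataset(tmp_path / "images", tmp_path / "masks")

    def test_size_mismatch_reports_both_shapes(self):
        with pytest.raises(ValueError, match=r"(100, 80).*(80, 100)"):
            ImageMaskPair(image=np.zeros((100, 80, 3), np.uint8),
                          mask=np.zeros((80, 100), np.uint8), id="bad")

    def test_binarize_threshold(self):
        raw = np.array([[0, 127, 128, 255]], np.uint8)
        np.testing.assert_array_equal(binarize_mask(raw), [[0, 0, 1, 1]])


class TestAugment:
    def test_all_off_is_identity_up_to_resize(self):
        pair = _toy_pairs(1)[0]
        cfg = AugmentationConfig(rotation_limit_deg=0, hflip_prob=0,
                                 vflip_prob=0, blur_prob=0,
                                 target_size=pair.shape)
        out = augment_pair(pair, cfg, np.random.default_rng(0))
        np.testing.assert_array_equal(out.image, pair.image)
        np.testing.assert_array_equal(out.mask, pair.mask)

    def test_same_rng_is_bit_identical(self):
        pair = _toy_pairs(1)[0]
        cfg = AugmentationConfig(target_size=(32, 32), seed=7)
        a = augment_pair(pair, cfg, pair_rng(7, pair.id))
        b = augment_pair(pair, cfg, pair_rng(7, pair.id))
        np.testing.assert_array_equal(a.image, b.image)
        np.testing.assert_array_equal(a.mask, b.mask)

    def test_hflip_matches_array_flip_oracle(self):
        pair = _toy_pairs(1)[0]
        cfg = AugmentationConfig(rotation_limit_deg=0, hflip_prob=1.0,
                                 vflip_prob=0, blur_prob=0,
                                 target_size=pair.shape)
        out = augment_pair(pair, cfg, np.random.default_rng(3))
        np.testing.assert_array_equal(out.image, pair.image[:, ::-1])
        np.testing.assert_array_equal(out.mask, pair.mask[:, ::-1])

    def test_geometry_shared_blur_image_only(self):
        pair = _toy_pairs(1, size=48)[0]
        cfg = AugmentationConfig(rotation_limit_deg=20, hflip_prob=0.5,
                                 vflip_prob=0.5, blur_prob=1.0,
                                 target_size=(48, 48))
        out = augment_pair(pair, cfg, np.random.default_rng(5))
        assert set(np.unique(out.mask)) <= {0, 1}  # mask stays binary
        assert out.image.shape == (48, 48, 3)


class TestResize:
    def test_downscale_to_224(self):
        pair = _toy_pairs(1, size=448)[0]
        out = resize_pair(pair, (224, 224))
        assert out.image.shape == (224, 224, 3)
        assert out.mask.shape == (224, 224)
        assert set(np.unique(out.mask)) <= {0, 1}

    def test_identity_size_is_pixel_identical(self):
        pair = _toy_pairs(1)[0]
        out = resize_pair(pair, pair.shape)
        np.testing.assert_array_equal(out.image, pair.image)

    def test_nearest_corner_convention_on_2x2(self):
        # nearest-neighbour 2x2 -> 1x1 picks the lower-right sample under
        # skimage's half-pixel mapping; frozen here as the contract
        pair = ImageMaskPair(image=np.zeros((2, 2, 3), np.uint8),
                             mask=np.array([[1, 0], [0, 0]], np.uint8), id="t")
        out = resize_pair(pair, (1, 1))
        assert out.mask.shape == (1, 1)
        assert out.mask[0, 0] == 0

    def test_nonpositive_size_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            resize_pair(_toy_pairs(1)[0], (0, 10))


class TestSplit:
    def test_90_10_partition(self):
        pairs = _toy_pairs(100, size=16)
        train, test = split_dataset(pairs, (0.9, 0.1), seed=1)
        assert len(train) == 90 and len(test) == 10
        ids = {p.id for p in train} | {p.id for p in test}
        assert len(ids) == 100  # disjoint and exhaustive

    def test_same_seed_same_membership(self):
        pairs = _toy_pairs(20, size=16)
        a = split_dataset(pairs, (0.7, 0.3), seed=5)
        b = split_dataset(pairs, (0.7, 0.3), seed=5)
        assert [p.id for p in a[0]] == [p.id for p in b[0]]

    def test_all_train(self):
        pairs = _toy_pairs(5, size=16)
        train, test = split_dataset(pairs, (1.0, 0.0), seed=0)
        assert len(train) == 5 and not test

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            split_dataset([], (0.9, 0.1), seed=0)

    def test_bad_ratios_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            split_dataset(_toy_pairs(4, size=16), (0.5, 0.4), seed=0)


class TestSynthetic:
    def test_deterministic_regeneration(self):
        cfg = SyntheticConfig(n_images=10, image_size=(64, 64), seed=42)
        a = generate_synthetic_dataset(cfg)
        b = generate_synthetic_dataset(cfg)
        assert len(a) == 10
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.image, pb.image)
            np.testing.assert_array_equal(pa.mask, pb.mask)

    def test_area_fraction_within_range(self):
        cfg = SyntheticConfig(n_images=12, image_size=(64, 64),
                              polyp_area_fraction_range=(0.05, 0.2), seed=3)
        for p in generate_synthetic_dataset(cfg):
            assert 0.05 <= p.mask.mean() <= 0.2

    def test_two_seeded_components_per_image(self):
        cfg = SyntheticConfig(n_images=6, image_size=(96, 96),
                              n_polyps_range=(2, 2), seed=11)
        pairs, manifest = generate_synthetic_dataset(cfg, return_manifest=True)
        for pair, rec in zip(pairs, manifest["images"]):
            assert len(rec["blobs"]) == 2
            assert label(pair.mask).max() >= 1
            for blob_json in rec["blobs"]:  # each seeded blob is nonempty
                blob = BlobParams(center=tuple(blob_json["center"]),
                                  r0=blob_json["r0"], aspect=blob_json["aspect"],
                                  theta=blob_json["theta"],
                                  harmonics=[tuple(h) for h in blob_json["harmonics"]])
                assert rasterize_blob(pair.shape, blob).any()

    def test_mask_equals_point_in_region_oracle(self):
        """Independent per-pixel polar test reproduces the rasterised blob."""
        blob = BlobParams(center=(15.0, 18.0), r0=8.0, aspect=1.2, theta=0.4,
                          harmonics=[(2, 0.1, 1.0), (3, 0.05, 0.3)])
        mask = rasterize_blob((32, 32), blob)
        ct, st = np.cos(blob.theta), np.sin(blob.theta)
        for yy in range(32):
            for xx in range(32):
                dy, dx = yy - blob.center[0], xx - blob.center[1]
                lx = (ct * dx + st * dy) / blob.aspect
                ly = -st * dx + ct * dy
                r = np.hypot(lx, ly)
                phi = np.arctan2(ly, lx)
                boundary = blob.r0 * (1 + sum(a * np.cos(k * phi + ph)
                                              for k, a, ph in blob.harmonics))
                assert mask[yy, xx] == (r <= boundary)

    def test_mask_is_union_of_manifest_blobs(self):
        cfg = SyntheticConfig(n_images=3, image_size=(64, 64), seed=9)
        pairs, manifest = generate_synthetic_dataset(cfg, return_manifest=True)
        for pair, rec in zip(pairs, manifest["images"]):
            union = np.zeros(pair.shape, bool)
            for bj in rec["blobs"]:
                union |= rasterize_blob(pair.shape, BlobParams(
                    center=tuple(bj["center"]), r0=bj["r0"], aspect=bj["aspect"],
                    theta=bj["theta"], harmonics=[tuple(h) for h in bj["harmonics"]]))
            np.testing.assert_array_equal(pair.mask.astype(bool), union)

    def test_infeasible_area_range_raises(self):
        cfg = SyntheticConfig(n_images=1, image_size=(64, 64),
                              n_polyps_range=(8, 8),
                              polyp_area_fraction_range=(0.9, 0.905), seed=0)
        with pytest.raises(RuntimeError, match="area fraction"):
            generate_synthetic_dataset(cfg)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(polyp_area_fraction_range=(0.0, 0.5))
        with pytest.raises(ValueError):
            SyntheticConfig(n_polyps_range=(0, 2))
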