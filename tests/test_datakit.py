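import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from svimon.datakit import (
    DEFAULT_COLORMAP,
    AugmentationOp,
    ColorMap,
    SplitSpec,
    apply_augmentation,
    augment_dataset,
    decode_color_to_mask,
    encode_mask_to_color,
    resize_pair,
    split_dataset,
)
from svimon.errors import MaskCodecError, ParameterError
from svimon.scenegen import ScenePair


class TestColorCodec:
    def test_vegetation_color_decodes_to_class_1(self):
        img = np.full((2, 2, 3), (107, 142, 35), dtype=np.uint8)
        mask = decode_color_to_mask(img)
        assert (mask == 1).all()

    def test_strict_unknown_color_raises_with_rgb(self):
        img = np.full((2, 2, 3), (255, 0, 0), dtype=np.uint8)
        with pytest.raises(MaskCodecError, match=r"\(255, 0, 0\)"):
            decode_color_to_mask(img, strict=True)

    def test_lenient_assigns_nearest(self):
        img = np.full((1, 1, 3), (100, 140, 40), dtype=np.uint8)  # near vegetation
        assert decode_color_to_mask(img, strict=False)[0, 0] == 1

    def test_encode_all_vegetation(self):
        img = encode_mask_to_color(np.ones((2, 2), dtype=np.uint8))
        assert (img == np.array([107, 142, 35])).all()

    def test_encode_all_other_is_black(self):
        img = encode_mask_to_color(np.zeros((3, 3), dtype=np.uint8))
        assert (img == 0).all()

    def test_encode_unknown_id(self):
        with pytest.raises(MaskCodecError):
            encode_mask_to_color(np.full((2, 2), 9, dtype=np.uint8))

    def test_duplicate_colors_rejected(self):
        with pytest.raises(ParameterError):
            ColorMap({0: (0, 0, 0), 1: (0, 0, 0)})

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_round_trip_identity(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.integers(0, 3, size=(9, 13)).astype(np.uint8)
        assert np.array_equal(decode_color_to_mask(encode_mask_to_color(mask)), mask)

    def test_colormap_invertible(self):
        inv = DEFAULT_COLORMAP.inverse
        assert inv[(107, 142, 35)] == 1
        assert len(inv) == len(DEFAULT_COLORMAP.colors)


class TestResizePair:
    def test_downscale_shape(self, rng):
        pair = ScenePair(
            image=rng.integers(0, 255, (768, 1024, 3)).astype(np.uint8),
            mask=rng.integers(0, 3, (768, 1024)).astype(np.uint8),
        )
        out = resize_pair(pair, 256)
        assert out.image.shape == (256, 256, 3)
        assert out.mask.shape == (256, 256)

    def test_mask_ids_subset(self, small_scene):
        out = resize_pair(small_scene, 16)
        assert set(np.unique(out.mask)) <= set(np.unique(small_scene.mask))

    def test_identity_resize(self, small_scene):
        out = resize_pair(small_scene, 64)
        assert np.array_equal(out.mask, small_scene.mask)
        assert np.array_equal(out.image, small_scene.image)

    def test_too_small_side(self, small_scene):
        with pytest.raises(ParameterError):
            resize_pair(small_scene, 8)


class TestSplitDataset:
    def test_3500_gives_175_test(self):
        tr, va, te = split_dataset(3500, SplitSpec(seed=0))
        assert (len(tr), len(va), len(te)) == (2800, 525, 175)

    def test_floor_remainder_to_train(self):
        tr, va, te = split_dataset(20, SplitSpec(seed=1))
        assert (len(tr), len(va), len(te)) == (16, 3, 1)

    def test_deterministic(self):
        a = split_dataset(100, SplitSpec(seed=7))
        b = split_dataset(100, SplitSpec(seed=7))
        assert a == b

    def test_partition_exhaustive_disjoint(self):
        tr, va, te = split_dataset(53, SplitSpec(seed=3))
        all_idx = tr + va + te
        assert sorted(all_idx) == list(range(53))
        assert len(set(all_idx)) == 53

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ParameterError):
            SplitSpec(train_frac=0.5, val_frac=0.2, test_frac=0.2)

    def test_too_few_items(self):
        with pytest.raises(ParameterError):
            split_dataset(2)

    @settings(max_examples=30, deadline=None)
    @given(n=st.integers(3, 5000), seed=st.integers(0, 1000))
    def test_sizes_property(self, n, seed):
        tr, va, te = split_dataset(n, SplitSpec(seed=seed))
        assert len(va) == int(np.floor(0.15 * n))
        assert len(te) == int(np.floor(0.05 * n))
        assert len(tr) == n - len(va) - len(te)


class TestAugmentation:
    def test_hflip_involution(self, small_scene):
        op = AugmentationOp("hflip")
        twice = apply_augmentation(apply_augmentation(small_scene, op), op)
        assert np.array_equal(twice.image, small_scene.image)
        assert np.array_equal(twice.mask, small_scene.mask)

    def test_rot90_four_times_identity(self, small_scene):
        op = AugmentationOp("rot90")
        out = small_scene
        for _ in range(4):
            out = apply_augmentation(out, op)
        assert np.array_equal(out.mask, small_scene.mask)
        assert np.array_equal(out.image, small_scene.image)

    @pytest.mark.parametrize("kind", ["hflip", "vflip", "rot90", "rot180"])
    def test_flip_rotation_conserve_class_counts(self, small_scene, kind):
        out = apply_augmentation(small_scene, AugmentationOp(kind))
        for cid in (0, 1, 2):
            assert np.sum(out.mask == cid) == np.sum(small_scene.mask == cid)

    @pytest.mark.parametrize("kind", ["gaussian_noise", "blur"])
    def test_photometric_leaves_mask(self, small_scene, kind):
        out = apply_augmentation(small_scene, AugmentationOp(kind, seed=5))
        assert np.array_equal(out.mask, small_scene.mask)
        assert not np.array_equal(out.image, small_scene.image)

    def test_translate_fills_with_other(self, small_scene):
        out = apply_augmentation(small_scene, AugmentationOp("translate", translate_px=(5, 3)))
        assert (out.mask[:3, :] == 0).all()
        assert (out.mask[:, :5] == 0).all()

    def test_zoom_preserves_shape(self, small_scene):
        out = apply_augmentation(small_scene, AugmentationOp("zoom", zoom_factor=0.8))
        assert out.mask.shape == small_scene.mask.shape

    def test_unknown_kind(self):
        with pytest.raises(ParameterError):
            AugmentationOp("shear")

    def test_noise_deterministic(self, small_scene):
        op = AugmentationOp("gaussian_noise", seed=9)
        a = apply_augmentation(small_scene, op)
        b = apply_augmentation(small_scene, op)
        assert np.array_equal(a.image, b.image)


class TestAugmentDataset:
    def test_multiplier_arithmetic(self, small_album):
        pairs = small_album[:10]
        pool = [AugmentationOp("hflip"), AugmentationOp("gaussian_noise")]
        out = augment_dataset(pairs, multiplier=3, op_pool=pool, seed=0)
        assert len(out) == 30

    def test_multiplier_one_identity(self, small_album):
        pairs = small_album[:5]
        assert augment_dataset(pairs, 1) == pairs

    def test_empty_pool_rejected(self, small_album):
        with pytest.raises(ParameterError):
            augment_dataset(small_album[:2], 2, op_pool=[])

    def test_deterministic(self, small_album):
        pairs = small_album[:4]
        pool = [AugmentationOp(k) for k in ("hflip", "vflip", "blur")]
        a = augment_dataset(pairs, 2, pool, seed=3)
        b = augment_dataset(pairs, 2, pool, seed=3)
        assert all(np.array_equal(x.image, y.image) for x, y in zip(a, b))
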