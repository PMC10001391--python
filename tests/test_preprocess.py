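"""Slice extraction, cropping, normalisation, channel assembly and augmentation."""

import numpy as np
import pytest

from brainseg import preprocess as pre
from brainseg.metrics import region_masks


def _volume(depth=155, fill=None):
    vox = np.zeros((16, 16, depth))
    if fill is not None:
        vox[:] = fill
    else:
        vox += np.arange(depth)[None, None, :]  # plane k holds value k
    return pre.ModalityVolume(vox, "t1")


class TestExtractSlice:
    def test_default_index_is_90_for_155_slices(self):
        assert np.all(pre.extract_slice(_volume(155)) == 90)

    def test_default_index_is_middle_otherwise(self):
        assert np.all(pre.extract_slice(_volume(31)) == 15)

    def test_single_slice_volume(self):
        assert np.all(pre.extract_slice(_volume(1)) == 0)

    def test_requested_plane_returned(self):
        assert np.all(pre.extract_slice(_volume(155), 42) == 42)

    def test_out_of_range_names_depth(self):
        with pytest.raises(IndexError, match="155"):
            pre.extract_slice(_volume(155), 155)


class TestCropCenter:
    def test_240_to_224(self):
        ramp = np.arange(240 * 240, dtype=float).reshape(240, 240)
        out = pre.crop_center(ramp, 224)
        assert out.shape == (224, 224)
        assert np.array_equal(out, ramp[8:232, 8:232])

    def test_identity_crop(self):
        img = np.random.default_rng(0).normal(size=(224, 224))
        assert np.array_equal(pre.crop_center(img, 224), img)

    def test_odd_margin_goes_to_trailing_side(self):
        img = np.arange(7 * 7, dtype=float).reshape(7, 7)
        assert np.array_equal(pre.crop_center(img, 4), img[1:5, 1:5])

    def test_oversized_target_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            pre.crop_center(np.zeros((10, 10)), 11)


class TestZScore:
    def test_hand_example(self):
        out = pre.zscore_normalize(np.array([[1.0, 2.0, 3.0]]))
        assert np.allclose(out, [[-1.2247, 0.0, 1.2247]], atol=1e-4)

    def test_mean_zero_std_one(self, rng):
        out = pre.zscore_normalize(rng.uniform(0, 100, (64, 64)))
        assert abs(out.mean()) < 1e-9 and abs(out.std() - 1) < 1e-9

    def test_idempotent_within_tolerance(self, rng):
        img = rng.normal(3.0, 7.0, (32, 32))
        once = pre.zscore_normalize(img)
        assert np.allclose(pre.zscore_normalize(once), once, atol=1e-5)

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pre.zscore_normalize(np.full((8, 8), 5.0))


class TestGaussianDenoise:
    def test_sigma_zero_identity(self, rng):
        img = rng.normal(size=(16, 16))
        assert np.array_equal(pre.gaussian_denoise(img, 0.0), img)

    def test_constant_preserved(self):
        assert np.allclose(pre.gaussian_denoise(np.full((16, 16), 3.0), 2.0), 3.0)

    def test_impulse_matches_explicit_kernel(self):
        img = np.zeros((21, 21))
        img[10, 10] = 1.0
        out = pre.gaussian_denoise(img, 1.0)
        # brute-force normalised 2D Gaussian kernel on the same truncated support
        r = np.arange(-4, 5)  # scipy default truncation: 4 sigma
        k1 = np.exp(-r**2 / 2.0)
        k1 /= k1.sum()
        kernel = np.outer(k1, k1)
        assert abs(out.sum() - 1.0) < 1e-12
        assert abs(out[10, 10] - kernel[4, 4]) < 1e-12

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError, match="sigma"):
            pre.gaussian_denoise(np.zeros((4, 4)), -1.0)


class TestAssembleInput:
    def test_channel_order_contract(self):
        a, b, c = (np.full((4, 4), v) for v in (1.0, 2.0, 3.0))
        mm = pre.assemble_input(a, b, c)
        assert np.all(mm.pixels[..., 0] == 1) and np.all(mm.pixels[..., 2] == 3)
        assert mm.channel_order == ("t1", "t1ce", "t2")

    def test_wrong_modality_tag_rejected(self):
        arr = np.zeros((4, 4))
        with pytest.raises(pre.AlignmentError, match="flair"):
            pre.assemble_input(("flair", arr), arr, arr)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(pre.AlignmentError):
            pre.assemble_input(np.zeros((4, 4)), np.zeros((5, 5)), np.zeros((4, 4)))

    def test_file_round_trip_preserves_channels(self, tmp_path, rng):
        mm = pre.assemble_input(*(rng.normal(size=(8, 8)) for _ in range(3)))
        mask = pre.SegLabelMap(rng.integers(0, 4, (8, 8)))
        path = str(tmp_path / "pair.npz")
        pre.save_pair(path, mm, mask)
        mm2, mask2 = pre.load_pair(path)
        assert np.array_equal(mm.pixels, mm2.pixels)
        assert np.array_equal(mask.labels, mask2.labels)


class TestLabelRemap:
    def test_file_to_internal_and_back(self):
        file_labels = np.array([[0, 1], [2, 4]])
        internal = pre.remap_labels_from_file(file_labels)
        assert np.array_equal(internal, [[0, 1], [2, 3]])
        assert np.array_equal(pre.remap_labels_to_file(internal), file_labels)

    def test_unexpected_value_rejected(self):
        with pytest.raises(ValueError):
            pre.remap_labels_from_file(np.array([[3]]))


class TestAugment:
    def _pair(self, rng, size=16):
        mm = pre.MultiModalSlice(rng.normal(size=(size, size, 3)), normalized=True)
        mask = pre.SegLabelMap(rng.integers(0, 4, (size, size)))
        return mm, mask

    def test_flip_is_involution(self, rng):
        mm, mask = self._pair(rng)
        out = pre.augment(mm, mask, seed=0)
        hflip = out[1][0].pixels
        assert np.array_equal(hflip[:, ::-1], mm.pixels)

    def test_label_histogram_invariant_under_flips_and_rotations(self, rng):
        mm, mask = self._pair(rng)
        hist = np.bincount(mask.labels.ravel(), minlength=4)
        for _, m in pre.augment(mm, mask, seed=0)[:6]:  # orig + flips + rotations
            assert np.array_equal(np.bincount(m.labels.ravel(), minlength=4), hist)

    def test_deterministic_under_seed(self, rng):
        mm, mask = self._pair(rng)
        a = pre.augment(mm, mask, seed=3)
        b = pre.augment(mm, mask, seed=3)
        for (ia, ma), (ib, mb) in zip(a, b):
            assert np.array_equal(ia.pixels, ib.pixels)
            assert np.array_equal(ma.labels, mb.labels)

    def test_geometric_transforms_commute_with_region_extraction(self, rng):
        _, mask = self._pair(rng)
        base = region_masks(mask.labels)
        transforms = [
            lambda a: a[:, ::-1], lambda a: a[::-1, :],
            lambda a: np.rot90(a, 1), lambda a: np.rot90(a, 2), lambda a: np.rot90(a, 3),
        ]
        for tf in transforms:
            transformed = region_masks(tf(mask.labels))
            for region in ("WT", "TC", "EnT"):
                assert np.array_equal(transformed[region], tf(base[region]))

    def test_emitted_pairs_aligned(self, tiny_pairs):
        mm, mask = tiny_pairs[0]
        for i, m in pre.augment(mm, mask, seed=0):
            assert i.pixels.shape[:2] == m.labels.shape


def test_preprocess_case_emits_network_contract(default_case):
    volumes, labels = default_case
    mm, seg = pre.preprocess_case(volumes, labels, target=64)
    assert mm.pixels.shape == (64, 64, 3)
    assert seg.labels.shape == (64, 64)
    assert set(np.unique(seg.labels)) <= {0, 1, 2, 3}
    for ch in range(3):
        channel = mm.pixels[..., ch]
        assert abs(channel.mean()) < 1e-6
        assert abs(channel.std() - 1) < 1e-4
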