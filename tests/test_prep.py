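"""Preprocessing: I/O validation, normalisation, patching, augmentation."""

import nibabel as nib
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from voxsegan.phantom import MODALITIES, MultimodalCase, generate_cohort
from voxsegan.prep import (
    SegmentationPatch,
    augment_patch,
    extract_patches,
    flip_patch,
    normalize_intensity,
    one_hot,
    read_case,
    sample_tumour_patches,
)


def _write_niftis(tmp_path, shape=(16, 16, 16), label_value=1):
    affine = np.eye(4)
    paths = {}
    for m in MODALITIES:
        p = tmp_path / f"x_{m}.nii.gz"
        nib.save(nib.Nifti1Image(np.ones(shape, dtype=np.float32), affine), p)
        paths[m] = p
    seg = tmp_path / "x_seg.nii.gz"
    nib.save(nib.Nifti1Image(
        np.full(shape, label_value, dtype=np.int16), affine), seg)
    return paths, seg


def test_read_case_rejects_out_of_range_labels(tmp_path):
    paths, seg = _write_niftis(tmp_path, label_value=4)
    with pytest.raises(ValueError, match="label values outside"):
        read_case(paths, seg)


def test_read_case_rejects_grid_mismatch(tmp_path):
    paths, seg = _write_niftis(tmp_path)
    nib.save(nib.Nifti1Image(np.ones((8, 8, 8), dtype=np.float32), np.eye(4)),
             paths["t2"])
    with pytest.raises(ValueError, match="grid mismatch"):
        read_case(paths, seg)


def test_round_trip_through_cohort(small_config, tmp_path):
    rows = generate_cohort(small_config, tmp_path)
    case = read_case({m: rows[1][f"{m}_path"] for m in MODALITIES},
                     rows[1]["seg_path"])
    assert case.image.shape == (32, 32, 32, 4)
    assert case.labels.dtype == np.int16


class TestNormalize:
    def test_two_value_channel_maps_to_plus_minus_one(self):
        img = np.zeros((2, 2, 2, 4), dtype=np.float32)
        img[0, 0, 0, 0] = 2.0
        img[0, 0, 1, 0] = 4.0
        case = MultimodalCase("t", img, np.zeros((2, 2, 2), dtype=np.int16))
        out = normalize_intensity(case)
        # brain (nonzero) voxels {2, 4}: mean 3, population std 1
        assert out.image[0, 0, 0, 0] == pytest.approx(-1.0)
        assert out.image[0, 0, 1, 0] == pytest.approx(1.0)

    def test_constant_channel_maps_to_zeros(self):
        img = np.full((4, 4, 4, 4), 7.0, dtype=np.float32)
        case = MultimodalCase("t", img, np.zeros((4, 4, 4), dtype=np.int16))
        out = normalize_intensity(case)
        assert np.all(out.image == 0.0)

    def test_statistics_and_idempotence(self, small_case):
        out = normalize_intensity(small_case)
        for m in range(4):
            chan = out.image[..., m].astype(np.float64)
            brain = chan[chan != 0]
            assert abs(brain.mean()) < 1e-4
            assert abs(brain.std() - 1) < 1e-4
        again = normalize_intensity(out)
        # z-scoring its own output changes almost nothing (the nonzero mask
        # is identical up to exact zeros, which are measure-zero under noise)
        assert np.allclose(again.image, out.image, atol=1e-3)

    def test_minmax_range(self, small_case):
        out = normalize_intensity(small_case, method="minmax")
        assert out.image.min() >= 0.0 and out.image.max() <= 1.0

    def test_unknown_method_rejected(self, small_case):
        with pytest.raises(ValueError, match="unknown normalisation"):
            normalize_intensity(small_case, method="rank")


class TestPatches:
    def test_volume_equal_to_patch_gives_single_patch(self, small_case):
        patches = extract_patches(small_case, 32)
        assert len(patches) == 1
        assert patches[0].origin == (0, 0, 0)
        assert np.array_equal(patches[0].image, small_case.image)

    def test_corner_enumeration_64_32_32(self, small_config):
        from dataclasses import replace
        from voxsegan.phantom import generate_phantom
        cfg = replace(small_config, grid_size=64, tumour_radius_range=(5, 12))
        case = generate_phantom(cfg, 0)
        patches = extract_patches(case, 32, 32)
        assert len(patches) == 8

    def test_overlapping_stride_covers_every_voxel(self, small_case):
        patches = extract_patches(small_case, 16, 12)
        covered = np.zeros(small_case.labels.shape, dtype=bool)
        for p in patches:
            ox, oy, oz = p.origin
            covered[ox:ox + 16, oy:oy + 16, oz:oz + 16] = True
        assert covered.all()

    def test_volume_smaller_than_patch_errors(self, small_case):
        with pytest.raises(ValueError, match="pad"):
            extract_patches(small_case, 48)

    def test_one_hot_argmax_round_trip(self, small_case):
        oh = one_hot(small_case.labels)
        assert np.all(oh.sum(axis=-1) == 1.0)
        assert np.array_equal(np.argmax(oh, axis=-1), small_case.labels)

    def test_patch_side_must_be_divisible_by_16(self, small_case):
        with pytest.raises(ValueError, match="divisible"):
            SegmentationPatch(np.zeros((8, 8, 8, 4), dtype=np.float32),
                              one_hot(np.zeros((8, 8, 8), dtype=np.int16)),
                              (0, 0, 0))

    def test_tumour_centred_sampling_contains_tumour(self, small_case):
        rng = np.random.default_rng(0)
        for p in sample_tumour_patches(small_case, 16, 5, rng):
            assert p.labels_onehot[..., 1:].any()


class TestAugment:
    def test_identity_draw_leaves_patch_unchanged(self, small_case):
        patch = extract_patches(small_case, 32)[0]
        out = augment_patch(patch, np.random.default_rng(40))  # identity draw
        assert np.array_equal(out.image, patch.image)
        assert np.array_equal(out.labels_onehot, patch.labels_onehot)

    @pytest.mark.parametrize("axis", [0, 1, 2])
    def test_flip_is_an_involution(self, small_case, axis):
        patch = extract_patches(small_case, 32)[0]
        twice = flip_patch(flip_patch(patch, axis), axis)
        assert np.array_equal(twice.image, patch.image)
        assert np.array_equal(twice.labels_onehot, patch.labels_onehot)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_class_counts_invariant_under_augmentation(self, seed):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 4, size=(16, 16, 16)).astype(np.int16)
        patch = SegmentationPatch(
            rng.normal(size=(16, 16, 16, 4)).astype(np.float32),
            one_hot(labels), (0, 0, 0))
        out = augment_patch(patch, rng)
        assert np.array_equal(out.labels_onehot.sum(axis=(0, 1, 2)),
                              patch.labels_onehot.sum(axis=(0, 1, 2)))
        # image/label correspondence preserved voxel-wise
        src = patch.image[patch.labels_onehot[..., 2] == 1][:, 0]
        dst = out.image[out.labels_onehot[..., 2] == 1][:, 0]
        assert np.array_equal(np.sort(src), np.sort(dst))
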