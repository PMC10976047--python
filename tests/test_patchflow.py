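"""Tests for bounding boxes, patch grids, filtering, batching, reconstruction."""

import numpy as np
import pytest

from lesionloss.patchflow import (BoundingBox, bounding_box, extract_patch,
                                  extract_patches, filter_lesion_patches,
                                  make_batches, patch_grid, read_nifti,
                                  reconstruct, write_nifti_like)


def _box(extent):
    return BoundingBox(lo=(0, 0, 0), hi=(extent,) * 3)


class TestBoundingBox:
    def test_single_voxel(self):
        m = np.zeros((8, 8, 8), int)
        m[3, 4, 5] = 1
        bb = bounding_box(m)
        assert bb.lo == (3, 4, 5) and bb.hi == (4, 5, 6)

    def test_full_mask(self):
        bb = bounding_box(np.ones((64, 64, 64), int))
        assert bb.lo == (0, 0, 0) and bb.hi == (64, 64, 64)

    def test_matches_exhaustive_scan(self, rng):
        m = (rng.random((20, 20, 20)) < 0.01).astype(int)
        if m.sum() == 0:
            m[5, 5, 5] = 1
        bb = bounding_box(m)
        coords = np.argwhere(m)
        assert bb.lo == tuple(coords.min(axis=0))
        assert bb.hi == tuple(coords.max(axis=0) + 1)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            bounding_box(np.zeros((4, 4, 4), int))


class TestPatchGrid:
    def test_extent_64_gives_27_patches(self):
        g = patch_grid(_box(64), size=32, stride=16)
        per_axis = {0, 16, 32}
        assert len(g) == 27
        assert set(o[0] for o in g.origins) == per_axis

    def test_extent_32_single_patch(self):
        g = patch_grid(_box(32))
        assert g.origins == ((0, 0, 0),)

    def test_extent_40_clamps_final_origin(self):
        g = patch_grid(_box(40))
        assert set(o[0] for o in g.origins) == {0, 8}
        assert len(g) == 8

    @pytest.mark.parametrize("extent", [32, 33, 47, 48, 63, 64, 79, 100])
    def test_union_of_windows_covers_box_exactly(self, extent):
        g = patch_grid(_box(extent))
        covered = np.zeros((extent,) * 3, bool)
        for o in g.origins:
            covered[o[0]:o[0] + 32, o[1]:o[1] + 32, o[2]:o[2] + 32] = True
        assert covered.all()
        assert all(0 <= o[0] and o[0] + 32 <= extent for o in g.origins)

    def test_offset_box(self):
        bb = BoundingBox(lo=(10, 10, 10), hi=(42, 42, 42))
        g = patch_grid(bb)
        assert g.origins == ((10, 10, 10),)

    def test_sub_patch_box_is_centred(self):
        bb = BoundingBox(lo=(4, 4, 4), hi=(24, 24, 24))  # extent 20 < 32
        g = patch_grid(bb)
        assert len(g) == 1
        assert g.origins[0] == (-2, -2, -2)


class TestLesionFilter:
    def test_lesion_free_mask_empty_grid(self):
        g = patch_grid(_box(64))
        kept = filter_lesion_patches(g, np.zeros((64, 64, 64), int))
        assert len(kept) == 0

    def test_single_lesion_voxel(self):
        mask = np.zeros((32, 32, 32), int)
        mask[5, 5, 5] = 1
        g = patch_grid(_box(32))
        kept = filter_lesion_patches(g, mask)
        assert kept.origins == g.origins

    def test_matches_per_window_tally(self, rng):
        mask = (rng.random((64, 64, 64)) < 0.001).astype(int)
        g = patch_grid(_box(64))
        kept = filter_lesion_patches(g, mask)
        oracle = tuple(
            o for o in g.origins
            if mask[o[0]:o[0] + 32, o[1]:o[1] + 32, o[2]:o[2] + 32].sum() > 0
        )
        assert kept.origins == oracle

    def test_subset_and_monotone_in_mask(self, rng):
        mask = (rng.random((64, 64, 64)) < 0.0005).astype(int)
        g = patch_grid(_box(64))
        kept = filter_lesion_patches(g, mask)
        assert set(kept.origins) <= set(g.origins)
        mask2 = mask.copy()
        mask2[0, 0, 0] = 1
        kept2 = filter_lesion_patches(g, mask2)
        assert set(kept.origins) <= set(kept2.origins)


class TestBatches:
    def test_even_split(self):
        groups = make_batches(list(range(32)), 16, seed=0)
        assert [len(g) for g in groups] == [16, 16]

    def test_remainder_group(self):
        groups = make_batches(list(range(35)), 16, seed=0)
        assert [len(g) for g in groups] == [16, 16, 3]

    def test_same_seed_same_order(self):
        a = make_batches(list(range(40)), 16, seed=7)
        b = make_batches(list(range(40)), 16, seed=7)
        assert a == b

    def test_different_seed_usually_differs(self):
        a = make_batches(list(range(40)), 16, seed=7)
        b = make_batches(list(range(40)), 16, seed=8)
        assert a != b


class TestReconstruct:
    def test_constant_patches_give_constant_volume(self):
        g = patch_grid(_box(64))
        preds = [(o, np.full((32, 32, 32), 0.7)) for o in g.origins]
        vol = reconstruct(preds, (64, 64, 64))
        assert np.allclose(vol, 0.7)

    def test_two_way_overlap_average(self):
        preds = [((0, 0, 0), np.zeros((32, 32, 32))),
                 ((16, 0, 0), np.ones((32, 32, 32)))]
        vol = reconstruct(preds, (48, 32, 32))
        assert np.allclose(vol[:16], 0.0)
        assert np.allclose(vol[16:32], 0.5)
        assert np.allclose(vol[32:], 1.0)

    def test_matches_count_map_oracle(self, rng):
        shape = (40, 40, 40)
        g = patch_grid(BoundingBox((0, 0, 0), shape), size=32, stride=16)
        preds = [(o, rng.random((32, 32, 32))) for o in g.origins]
        vol = reconstruct(preds, shape)
        acc = np.zeros(shape)
        cnt = np.zeros(shape)
        for o, p in preds:
            acc[o[0]:o[0] + 32, o[1]:o[1] + 32, o[2]:o[2] + 32] += p
            cnt[o[0]:o[0] + 32, o[1]:o[1] + 32, o[2]:o[2] + 32] += 1
        oracle = np.where(cnt > 0, acc / np.maximum(cnt, 1), 0.0)
        assert np.abs(vol - oracle).max() < 1e-12

    def test_extract_then_reconstruct_is_identity(self, rng):
        """An identity 'model' on every window reproduces the volume over the
        covered region."""
        vol = rng.random((70, 54, 41))
        mask = np.ones_like(vol, dtype=int)
        g = patch_grid(bounding_box(mask))
        preds = [(o, extract_patch(vol, o)) for o in g.origins]
        recon = reconstruct(preds, vol.shape)
        assert np.abs(recon - vol).max() < 1e-12

    def test_uncovered_voxels_are_zero(self):
        preds = [((0, 0, 0), np.ones((32, 32, 32)))]
        vol = reconstruct(preds, (64, 64, 64))
        assert vol[40, 40, 40] == 0.0


class TestNiftiRoundTrip:
    def test_affine_propagated(self, tmp_path, rng):
        import nibabel as nib
        affine = np.diag([0.96, 0.95, 3.0, 1.0])
        data = rng.random((10, 10, 6))
        src = tmp_path / "src.nii.gz"
        nib.save(nib.Nifti1Image(data, affine), str(src))
        loaded, img = read_nifti(src)
        assert np.allclose(loaded, data, atol=1e-6)
        out = tmp_path / "out.nii.gz"
        write_nifti_like(loaded * 2, img, out)
        back, img2 = read_nifti(out)
        assert np.allclose(img2.affine, affine)
        assert np.allclose(back, data * 2, atol=1e-6)


def test_extract_patches_channel_stack(rng):
    vol = rng.random((2, 40, 40, 40)).astype(np.float32)
    out = extract_patches(vol, [(0, 0, 0), (8, 8, 8)], size=32)
    assert out.shape == (2, 2, 32, 32, 32)
    assert np.array_equal(out[1, 0], vol[0, 8:40, 8:40, 8:40])
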