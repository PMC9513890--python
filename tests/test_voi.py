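"""Centroid, cube cropping with padding, VOI proposal, and paste-back."""

import numpy as np
import pytest

from aneuseg.imaging import BinaryMask, VolumeImage
from aneuseg.voi import crop_cube, label_centroid, paste_back, propose_vois


def mask_from_points(points, shape=(20, 20, 20)):
    data = np.zeros(shape, dtype=np.uint8)
    for p in points:
        data[p] = 1
    return BinaryMask(data=data, spacing=(1, 1, 1))


class TestCentroid:
    def test_singleton(self):
        assert label_centroid(mask_from_points([(10, 12, 14)])) == (10, 12, 14)

    def test_mean_of_indices(self):
        assert label_centroid(mask_from_points([(0, 0, 0), (2, 0, 0)])) == (1, 0, 0)

    def test_half_up_rounding(self):
        # mean x = 0.5 rounds up to 1
        assert label_centroid(mask_from_points([(0, 0, 0), (1, 0, 0)])) == (1, 0, 0)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="empty"):
            label_centroid(mask_from_points([]))


class TestCropCube:
    def test_interior_crop_has_no_padding(self, rng):
        vol = VolumeImage(data=rng.normal(size=(128, 128, 128)), spacing=(0.5,) * 3)
        arr, box = crop_cube(vol, (64, 64, 64), 64)
        assert arr.shape == (64, 64, 64)
        assert box.lo == (32, 32, 32) and box.hi == (96, 96, 96)
        assert box.pad_before == (0, 0, 0) and box.pad_after == (0, 0, 0)
        assert np.array_equal(arr, vol.data[32:96, 32:96, 32:96])

    def test_corner_crop_pads_with_zeros(self, rng):
        vol = VolumeImage(data=rng.normal(size=(64, 64, 64)) + 10, spacing=(1,) * 3)
        arr, box = crop_cube(vol, (0, 0, 0), 64)
        assert box.pad_before == (32, 32, 32)
        assert arr.shape == (64, 64, 64)
        assert np.all(arr[:32] == 0) and np.all(arr[:, :32] == 0) and np.all(arr[:, :, :32] == 0)
        assert np.array_equal(arr[32:, 32:, 32:], vol.data[:32, :32, :32])

    def test_side_one_returns_center_voxel(self, rng):
        vol = VolumeImage(data=rng.normal(size=(8, 8, 8)), spacing=(1,) * 3)
        arr, _ = crop_cube(vol, (3, 4, 5), 1)
        assert arr.shape == (1, 1, 1)
        assert arr[0, 0, 0] == vol.data[3, 4, 5]

    def test_center_outside_volume_raises(self):
        vol = VolumeImage(data=np.zeros((8, 8, 8)), spacing=(1,) * 3)
        with pytest.raises(ValueError, match="outside"):
            crop_cube(vol, (8, 0, 0), 4)

    def test_same_box_aligns_channels(self, rng):
        a = VolumeImage(data=rng.normal(size=(40, 40, 40)), spacing=(1,) * 3)
        b = a.with_data(a.data * 2)
        arr_a, _ = crop_cube(a, (5, 20, 35), 16)
        arr_b, _ = crop_cube(b, (5, 20, 35), 16)
        assert np.array_equal(arr_b, arr_a * 2)


class TestProposeVois:
    def test_two_distant_blobs_two_boxes(self):
        data = np.zeros((160, 160, 160), dtype=np.uint8)
        data[20:24, 20:24, 20:24] = 1
        data[124:128, 20:24, 20:24] = 1
        boxes = propose_vois(BinaryMask(data=data, spacing=(1,) * 3), side=64)
        assert len(boxes) == 2

    def test_near_blobs_merge_into_one_box(self):
        data = np.zeros((160, 160, 160), dtype=np.uint8)
        data[50, 50, 50] = 1
        data[60, 50, 50] = 1  # centroids 10 < 64/2 apart
        boxes = propose_vois(BinaryMask(data=data, spacing=(1,) * 3), side=64)
        assert len(boxes) == 1
        assert boxes[0].center[0] == 55

    def test_empty_mask_empty_list(self):
        assert propose_vois(BinaryMask(data=np.zeros((40, 40, 40)), spacing=(1,) * 3), 16) == []

    def test_box_invariants_hold(self, rng):
        data = (rng.random((48, 48, 48)) < 0.001).astype(np.uint8)
        mask = BinaryMask(data=data, spacing=(1,) * 3)
        from scipy import ndimage
        n_comp = ndimage.label(data, structure=np.ones((3, 3, 3)))[1]
        boxes = propose_vois(mask, side=16)
        assert len(boxes) <= n_comp
        for b in boxes:
            span = np.subtract(b.hi, b.lo) + np.add(b.pad_before, b.pad_after)
            assert np.all(span == b.side)
            assert all(l >= 0 for l in b.lo) and all(h <= 48 for h in b.hi)


class TestPasteBack:
    def test_crop_then_paste_is_identity_on_box(self):
        data = np.zeros((40, 40, 40), dtype=np.uint8)
        data[18:22, 18:22, 18:22] = 1
        mask = BinaryMask(data=data, spacing=(1,) * 3)
        arr, box = crop_cube(mask, (20, 20, 20), 16)
        out = paste_back([(arr, box)], (40, 40, 40))
        assert np.array_equal(out.data, data)

    def test_overlapping_vois_combine_by_or(self):
        m = BinaryMask(data=np.zeros((40, 40, 40), dtype=np.uint8), spacing=(1,) * 3)
        a, box_a = crop_cube(m, (16, 16, 16), 8)
        b, box_b = crop_cube(m, (18, 16, 16), 8)
        a[4, 4, 4] = 1  # voxel (16,16,16) predicted 1 in box a, 0 in box b
        out = paste_back([(a, box_a), (b, box_b)], (40, 40, 40))
        assert out.data[16, 16, 16] == 1

    def test_empty_list_gives_zero_mask(self):
        out = paste_back([], (10, 10, 10))
        assert out.data.sum() == 0 and out.shape == (10, 10, 10)

    def test_padding_is_discarded(self):
        m = BinaryMask(data=np.zeros((20, 20, 20), dtype=np.uint8), spacing=(1,) * 3)
        arr, box = crop_cube(m, (0, 0, 0), 16)
        arr[:] = 1  # includes padded region
        out = paste_back([(arr, box)], (20, 20, 20))
        assert out.data[:8, :8, :8].all()
        assert out.data.sum() == 8 ** 3

    def test_inconsistent_box_raises(self):
        m = BinaryMask(data=np.zeros((40, 40, 40), dtype=np.uint8), spacing=(1,) * 3)
        arr, box = crop_cube(m, (20, 20, 20), 16)
        with pytest.raises(ValueError):
            paste_back([(arr, box)], (20, 20, 20))
        with pytest.raises(ValueError):
            paste_back([(arr[:8, :8, :8], box)], (40, 40, 40))
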