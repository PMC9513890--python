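"""Z-score, Sobel contour, adaptive label dilation, eightfold augmentation."""

import numpy as np
import pytest
from scipy import ndimage

from aneuseg.imaging import BinaryMask, VolumeBundle, VolumeImage
from aneuseg.preprocess import (
    AugmentPolicy,
    adaptive_dilate_label,
    augment_eightfold,
    component_dilation_radius,
    flip_z,
    sobel_contour,
    zscore,
)


def vol(data, spacing=(1, 1, 1)):
    return VolumeImage(data=np.asarray(data, dtype=np.float32), spacing=spacing)


class TestZscore:
    def test_two_value_closed_form(self):
        data = np.zeros((4, 4, 4)); data[:2] = 0; data[2:] = 2
        out = zscore(vol(data))
        assert set(np.unique(out.data)) == {-1.0, 1.0}

    def test_output_moments(self, small_volume):
        out = zscore(small_volume)
        assert abs(out.data.mean()) < 1e-6
        assert abs(out.data.std() - 1) < 1e-6
        assert out.shape == small_volume.shape

    def test_idempotent_within_tolerance(self, small_volume):
        once = zscore(small_volume)
        twice = zscore(once)
        assert np.abs(twice.data - once.data).max() < 1e-5

    def test_constant_volume_raises(self):
        with pytest.raises(ValueError, match="constant"):
            zscore(vol(np.full((4, 4, 4), 7.0)))


def brute_force_sobel(x):
    """Direct 3x3x3 separable convolution: derivative x smoothing x smoothing."""
    deriv = np.array([1.0, 0.0, -1.0])
    smooth = np.array([1.0, 2.0, 1.0])
    mag_sq = np.zeros_like(x, dtype=np.float64)
    for axis in range(3):
        kernels = [smooth] * 3
        kernels[axis] = deriv
        kern = (
            kernels[0][:, None, None] * kernels[1][None, :, None] * kernels[2][None, None, :]
        )
        g = ndimage.correlate(x.astype(np.float64), kern, mode="nearest")
        mag_sq += g * g
    mag = np.sqrt(mag_sq)
    return mag / mag.max() if mag.max() > 0 else mag


class TestSobelContour:
    def test_constant_volume_zero_contour(self):
        out = sobel_contour(vol(np.full((8, 8, 8), 3.0)))
        assert np.all(out.data == 0)

    def test_matches_brute_force_convolution(self, rng):
        x = rng.normal(size=(16, 16, 16)).astype(np.float32)
        out = sobel_contour(vol(x))
        ref = brute_force_sobel(x)
        # scipy's sobel may flip the derivative sign; magnitudes must agree
        assert np.abs(out.data - ref).max() < 1e-6

    def test_cube_contour_lies_on_surface(self):
        x = np.zeros((32, 32, 32)); x[11:21, 11:21, 11:21] = 1.0
        out = sobel_contour(vol(x)).data
        strong = np.argwhere(out > 0.5)
        # Chebyshev distance to the cube surface: inside [10..21] band per axis
        for p in strong:
            assert all(10 <= c <= 21 for c in p)
            assert any(c in (10, 11, 20, 21) for c in p)

    def test_ramp_has_constant_interior_response(self):
        x = np.broadcast_to(np.arange(16, dtype=np.float32)[:, None, None], (16, 16, 16))
        out = sobel_contour(vol(np.array(x))).data
        interior = out[2:-2, 2:-2, 2:-2]
        assert np.allclose(interior, interior[0, 0, 0], atol=1e-6)

    def test_range_is_unit_interval(self, small_volume):
        out = sobel_contour(small_volume).data
        assert out.min() >= 0 and out.max() == pytest.approx(1.0)


class TestAdaptiveDilation:
    def test_single_voxel_gets_unit_ball(self):
        data = np.zeros((9, 9, 9), dtype=np.uint8); data[4, 4, 4] = 1
        out = adaptive_dilate_label(BinaryMask(data=data, spacing=(1, 1, 1)))
        # brute force: 6-neighbourhood ball of radius 1
        expected = np.zeros_like(data)
        for d in [(0, 0, 0), (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]:
            expected[4 + d[0], 4 + d[1], 4 + d[2]] = 1
        assert np.array_equal(out.data, expected)

    def test_output_contains_input(self, rng):
        data = (rng.random((12, 12, 12)) < 0.05).astype(np.uint8)
        if not data.any():
            data[0, 0, 0] = 1
        mask = BinaryMask(data=data, spacing=(0.5, 0.5, 0.5))
        out = adaptive_dilate_label(mask)
        assert np.all(out.data >= data)

    def test_larger_component_gets_larger_radius(self):
        sp = (0.5, 0.5, 0.5)
        r_small = component_dilation_radius(1, sp)
        r_big = component_dilation_radius(4000, sp)
        assert r_big > r_small
        data = np.zeros((40, 40, 40), dtype=np.uint8)
        data[3, 3, 3] = 1                      # singleton
        data[15:31, 15:31, 15:31] = 1          # 16^3 block
        out = adaptive_dilate_label(BinaryMask(data=data, spacing=sp))
        grow_small = out.data[:8, :8, :8].sum() - 1
        # the big block must have grown by r_big along each face
        assert out.data[15 - r_big, 20, 20] == 1
        assert grow_small == 6 * r_small

    def test_empty_label_raises(self):
        with pytest.raises(ValueError, match="empty"):
            adaptive_dilate_label(BinaryMask(data=np.zeros((5, 5, 5)), spacing=(1, 1, 1)))


def make_bundle(rng, with_contour=True):
    v = VolumeImage(data=rng.normal(size=(12, 12, 12)).astype(np.float32), spacing=(1, 1, 1))
    lab = BinaryMask(data=(rng.random((12, 12, 12)) < 0.1).astype(np.uint8), spacing=(1, 1, 1))
    contour = sobel_contour(v) if with_contour else None
    return VolumeBundle(vessel=v, label=lab, contour=contour)


class TestAugmentation:
    def test_cardinality_is_eight_n(self, rng):
        samples = [make_bundle(rng) for _ in range(3)]
        out = augment_eightfold(samples)
        assert len(out) == 24

    def test_flip_is_involution(self, rng):
        b = make_bundle(rng)
        back = flip_z(flip_z(b))
        assert np.array_equal(back.vessel.data, b.vessel.data)
        assert np.array_equal(back.label.data, b.label.data)

    def test_flip_preserves_label_count(self, rng):
        b = make_bundle(rng)
        assert flip_z(b).label.data.sum() == b.label.data.sum()

    def test_intensity_transforms_keep_labels(self, rng):
        samples = [make_bundle(rng) for _ in range(2)]
        out = augment_eightfold(samples)
        n = len(samples)
        # layout: [orig(N) | flip(N) | gauss(2N) | histeq(4N)]
        for i in range(n):
            assert np.array_equal(out[2 * n + i].label.data, out[i].label.data)
            assert np.array_equal(out[4 * n + i].label.data, out[i].label.data)

    def test_contours_rederived_from_transformed_vessel(self, rng):
        samples = [make_bundle(rng)]
        out = augment_eightfold(samples)
        gauss = out[2]  # gaussian-filtered copy of the original
        expected = sobel_contour(gauss.vessel)
        assert np.allclose(gauss.contour.data, expected.data)
        assert not np.allclose(gauss.vessel.data, samples[0].vessel.data)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            augment_eightfold([])

    def test_policy_validation(self):
        with pytest.raises(ValueError):
            AugmentPolicy(gaussian_sigma_mm=0)
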