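"""Preprocessing chain for vessel volumes.

The chain applied to every vessel image is Z-score intensity normalization
followed by Sobel gradient-magnitude contour extraction (the contour becomes
the second input channel of the fine network).  Coarse-stage training labels
are additionally dilated with a radius that adapts to each aneurysm's size,
so small lesions still present a learnable target at full-volume scale.

Training cohorts are augmented eightfold: the originals are z-flipped (2N),
those 2N are Gaussian filtered (4N), and those 4N histogram-equalized (8N).
Labels only ever undergo the geometric flip; contour channels are re-derived
from each transformed vessel image rather than transformed themselves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import exposure

from .imaging import BinaryMask, VolumeBundle, VolumeImage
from .voi import CONNECTIVITY_26

__all__ = [
    "AugmentPolicy",
    "zscore",
    "sobel_contour",
    "adaptive_dilate_label",
    "flip_z",
    "gaussian_filter_volume",
    "hist_equalize",
    "augment_eightfold",
]

#: Dilation radius is ``max(1, round(DILATION_COEFF * d_eq / mean_spacing))``
#: voxels for a component of equivalent-sphere diameter ``d_eq`` (mm).
DILATION_COEFF = 0.25


@dataclass
class AugmentPolicy:
    """The three augmentation transform families.

    flip_axis:
        Axis flipped for the geometric augmentation (2 = z).
    gaussian_sigma_mm:
        Standard deviation of the Gaussian filter in mm, converted to voxels
        through the volume spacing.
    hist_eq_bins:
        Number of bins for histogram equalization.
    """

    flip_axis: int = 2
    gaussian_sigma_mm: float = 0.5
    hist_eq_bins: int = 256

    def __post_init__(self):
        if self.gaussian_sigma_mm <= 0:
            raise ValueError("gaussian_sigma_mm must be > 0")


def zscore(vol: VolumeImage) -> VolumeImage:
    """Standardize intensities to zero mean, unit variance over the volume.

    Raises ``ValueError`` for a constant volume (zero variance).
    """
    x = np.asarray(vol.data, dtype=np.float64)
    mu = x.mean()
    sd = x.std()
    if sd == 0:
        raise ValueError("cannot z-score a constant volume")
    return vol.with_data(((x - mu) / sd).astype(np.float32))


def sobel_contour(vessel: VolumeImage) -> VolumeImage:
    """Sobel gradient-magnitude contour image, rescaled to [0, 1].

    Applies the 3D Sobel operator along each axis, takes the Euclidean
    magnitude and divides by its maximum (uniform input yields all zeros).
    Responses concentrate at intensity boundaries, i.e. the vessel wall.
    """
    x = np.asarray(vessel.data, dtype=np.float64)
    mag_sq = np.zeros_like(x)
    for axis in range(3):
        g = ndimage.sobel(x, axis=axis, mode="nearest")
        mag_sq += g * g
    mag = np.sqrt(mag_sq)
    peak = mag.max()
    if peak > 0:
        mag /= peak
    return vessel.with_data(mag.astype(np.float32))


def adaptive_dilate_label(label: BinaryMask, spacing=None) -> BinaryMask:
    """Dilate each aneurysm component by a radius that scales with its size.

    Per 26-connected component the equivalent-sphere diameter ``d_eq`` (mm)
    is computed from its voxel volume, and the component is dilated with a
    ball of radius ``max(1, round(0.25 * d_eq / mean_spacing))`` voxels.
    The output always contains the input. Raises on an empty label.
    """
    if spacing is None:
        spacing = label.spacing
    spacing = np.asarray(spacing, dtype=float)
    data = label.data > 0
    if not data.any():
        raise ValueError("cannot dilate an empty label")
    mean_sp = float(spacing.mean())
    voxel_vol = float(np.prod(spacing))
    labels, n = ndimage.label(data, structure=CONNECTIVITY_26)
    out = np.zeros_like(data)
    for comp in range(1, n + 1):
        comp_mask = labels == comp
        d_eq = 2.0 * (3.0 * comp_mask.sum() * voxel_vol / (4.0 * np.pi)) ** (1.0 / 3.0)
        r = max(1, int(np.floor(DILATION_COEFF * d_eq / mean_sp + 0.5)))
        out |= ndimage.binary_dilation(comp_mask, structure=_ball(r))
    return label.with_data(out.astype(np.uint8))


def _ball(radius: int) -> np.ndarray:
    """Euclidean ball structuring element of the given voxel radius."""
    grid = np.mgrid[-radius:radius + 1, -radius:radius + 1, -radius:radius + 1]
    return (grid ** 2).sum(axis=0) <= radius ** 2


def component_dilation_radius(n_voxels: int, spacing) -> int:
    """Radius (voxels) the adaptive rule assigns to a component of given size."""
    spacing = np.asarray(spacing, dtype=float)
    d_eq = 2.0 * (3.0 * n_voxels * float(np.prod(spacing)) / (4.0 * np.pi)) ** (1.0 / 3.0)
    return max(1, int(np.floor(DILATION_COEFF * d_eq / float(spacing.mean()) + 0.5)))


def flip_z(bundle: VolumeBundle, axis: int = 2) -> VolumeBundle:
    """Flip vessel, label (and contour if present) along the given axis."""
    vessel = bundle.vessel.with_data(np.flip(bundle.vessel.data, axis=axis).copy())
    label = bundle.label.with_data(np.flip(bundle.label.data, axis=axis).copy())
    contour = None
    if bundle.contour is not None:
        contour = bundle.contour.with_data(np.flip(bundle.contour.data, axis=axis).copy())
    return VolumeBundle(vessel=vessel, label=label, contour=contour)


def gaussian_filter_volume(vol: VolumeImage, sigma_mm: float) -> VolumeImage:
    """Gaussian filter with physical-scale sigma (mm converted to voxels)."""
    sigma_vox = sigma_mm / np.asarray(vol.spacing, dtype=float)
    return vol.with_data(
        ndimage.gaussian_filter(vol.data.astype(np.float64), sigma=sigma_vox).astype(np.float32)
    )


def hist_equalize(vol: VolumeImage, nbins: int = 256) -> VolumeImage:
    """Histogram equalization over the volume's intensity range."""
    eq = exposure.equalize_hist(np.asarray(vol.data, dtype=np.float64), nbins=nbins)
    return vol.with_data(eq.astype(np.float32))


def _intensity_bundle(bundle: VolumeBundle, fn) -> VolumeBundle:
    """Apply an intensity-only transform: label untouched, contour re-derived."""
    vessel = fn(bundle.vessel)
    contour = sobel_contour(vessel) if bundle.contour is not None else None
    return VolumeBundle(vessel=vessel, label=bundle.label, contour=contour)


def augment_eightfold(samples: list, policy: AugmentPolicy = AugmentPolicy()) -> list:
    """Eightfold cumulative augmentation of a list of bundles.

    Originals (N) plus z-flips make 2N; Gaussian-filtered copies of those 2N
    make 4N; histogram-equalized copies of those 4N make 8N. Intensity
    transforms never touch labels; contours are recomputed from transformed
    vessels whenever a sample carries a contour channel.
    """
    if not samples:
        raise ValueError("augment_eightfold requires a nonempty sample list")
    flipped = [flip_z(b, policy.flip_axis) for b in samples]
    stage2 = list(samples) + flipped
    stage4 = stage2 + [
        _intensity_bundle(b, lambda v: gaussian_filter_volume(v, policy.gaussian_sigma_mm))
        for b in stage2
    ]
    stage8 = stage4 + [
        _intensity_bundle(b, lambda v: hist_equalize(v, policy.hist_eq_bins))
        for b in stage4
    ]
    return stage8
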