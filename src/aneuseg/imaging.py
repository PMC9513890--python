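"""Volumetric data model and NIfTI I/O.

All volumes in the package are plain 3D numpy arrays in ``(x, y, z)`` index
order together with a voxel spacing in millimetres and an origin.  Geometry
handling is deliberately minimal — spacing and origin only, direction cosines
assumed identity — because phantoms control their own geometry and nothing in
the pipeline resamples between differently oriented scans.

Conventions
-----------
* Voxel coordinates are 0-based integer indices.
* Boxes and crops use half-open bounds ``[lo, hi)``.
* Geometry equality means exact shape match and spacing agreement within
  ``SPACING_ATOL`` (1e-6 mm).
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "SPACING_ATOL",
    "VolumeImage",
    "BinaryMask",
    "VolumeBundle",
    "GeometryError",
    "read_volume",
    "read_mask",
    "write_volume",
]

#: Tolerance (mm) for spacing agreement in geometry checks.
SPACING_ATOL = 1e-6


class GeometryError(ValueError):
    """Shape/spacing mismatch between volumes that must share geometry."""


def _as_vec3(v, name: str) -> np.ndarray:
    arr = np.asarray(v, dtype=float).reshape(-1)
    if arr.size != 3:
        raise ValueError(f"{name} must have 3 components, got {arr.size}")
    return arr


@dataclass
class VolumeImage:
    """3D scalar volume with voxel spacing (mm) and origin (mm).

    Parameters
    ----------
    data:
        3D array of intensities (arbitrary units); stored as float32.
    spacing:
        Voxel edge lengths in mm, strictly positive and finite.
    origin:
        Position of voxel (0, 0, 0) in mm. Defaults to the zero vector.
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got {self.data.ndim} axes")
        if min(self.data.shape) < 1:
            raise ValueError("every axis must have length >= 1")
        self.spacing = _as_vec3(self.spacing, "spacing")
        if not np.all(np.isfinite(self.spacing)) or np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be finite and > 0, got {self.spacing}")
        self.origin = _as_vec3(self.origin, "origin")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def same_geometry(self, other) -> bool:
        return self.shape == other.shape and bool(
            np.allclose(self.spacing, other.spacing, atol=SPACING_ATOL, rtol=0.0)
        )

    def require_same_geometry(self, other) -> None:
        if not self.same_geometry(other):
            raise GeometryError(
                f"geometry mismatch: shape {self.shape} / spacing {self.spacing} vs "
                f"shape {other.shape} / spacing {other.spacing}"
            )

    def with_data(self, data: np.ndarray) -> "VolumeImage":
        """New volume sharing this geometry."""
        return dataclasses.replace(self, data=np.asarray(data))


@dataclass
class BinaryMask(VolumeImage):
    """3D binary mask sharing the :class:`VolumeImage` geometry.

    Values are exactly 0 or 1, stored as uint8.
    """

    def __post_init__(self):
        arr = np.asarray(self.data)
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(f"mask values must be in {{0, 1}}, got {uniq[:10]}")
        self.data = arr.astype(np.uint8)
        if self.data.ndim != 3:
            raise ValueError(f"mask must be 3D, got {self.data.ndim} axes")
        self.spacing = _as_vec3(self.spacing, "spacing")
        if not np.all(np.isfinite(self.spacing)) or np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be finite and > 0, got {self.spacing}")
        self.origin = _as_vec3(self.origin, "origin")

    def with_data(self, data: np.ndarray) -> "BinaryMask":
        return dataclasses.replace(self, data=np.asarray(data))

    @property
    def foreground_count(self) -> int:
        return int(self.data.sum())


@dataclass
class VolumeBundle:
    """A vessel volume, its contour channel, and the aneurysm label.

    All three share shape and spacing exactly; the contour may be ``None``
    until the preprocessing stage derives it from the vessel image.
    """

    vessel: VolumeImage
    label: BinaryMask
    contour: VolumeImage | None = None

    def __post_init__(self):
        self.vessel.require_same_geometry(self.label)
        if self.contour is not None:
            self.vessel.require_same_geometry(self.contour)


def _load_nifti(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D NIfTI image, got {data.ndim} dimensions")
    spacing = np.asarray(img.header.get_zooms()[:3], dtype=float)
    origin = np.asarray(img.affine[:3, 3], dtype=float)
    return data, spacing, origin


def read_volume(path) -> VolumeImage:
    """Read a 3D NIfTI file as a :class:`VolumeImage`.

    Data axis order follows the header's (x, y, z); spacing comes from the
    header zooms, origin from the affine translation.
    """
    data, spacing, origin = _load_nifti(path)
    return VolumeImage(data=data, spacing=spacing, origin=origin)


def read_mask(path) -> BinaryMask:
    """Read a 3D NIfTI label file as a :class:`BinaryMask` (values {0, 1})."""
    data, spacing, origin = _load_nifti(path)
    return BinaryMask(data=data, spacing=spacing, origin=origin)


def write_volume(vol: VolumeImage, path) -> None:
    """Write a volume or mask to NIfTI-1 (.nii / .nii.gz).

    Masks are written as unsigned 8-bit, volumes as float32. The affine is
    diagonal spacing plus origin translation (identity direction).
    """
    parent = os.path.dirname(os.path.abspath(str(path)))
    if not os.path.isdir(parent):
        raise FileNotFoundError(f"parent directory does not exist: {parent}")
    affine = np.eye(4)
    affine[0, 0], affine[1, 1], affine[2, 2] = vol.spacing
    affine[:3, 3] = vol.origin
    if isinstance(vol, BinaryMask):
        data = vol.data.astype(np.uint8)
    else:
        data = vol.data.astype(np.float32)
    nib.save(nib.Nifti1Image(data, affine), str(path))
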