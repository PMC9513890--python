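"""Volume-of-interest (VOI) geometry.

Training crops are cubes centred on the label centroid; at inference, VOIs
are proposed from the connected components of the coarse segmentation and the
fine results are pasted back into a full-size mask.  Cubes that straddle the
volume border are zero-padded to the requested side, and the padding is
recorded so paste-back can discard it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .imaging import BinaryMask, VolumeImage

__all__ = [
    "VOIBox",
    "label_centroid",
    "crop_cube",
    "propose_vois",
    "paste_back",
    "CONNECTIVITY_26",
]

#: 3x3x3 structuring element giving 26-connectivity for 3D components.
CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class VOIBox:
    """Axis-aligned cube in voxel index space with half-open clipped bounds.

    ``(hi - lo) + pad_before + pad_after == (side, side, side)`` always holds;
    ``lo``/``hi`` are clipped to the volume so the cube's out-of-bounds part
    appears only in the pad fields.
    """

    center: tuple
    side: int
    lo: tuple
    hi: tuple
    pad_before: tuple
    pad_after: tuple

    def __post_init__(self):
        span = np.subtract(self.hi, self.lo) + np.add(self.pad_before, self.pad_after)
        if not np.all(span == self.side):
            raise ValueError(f"inconsistent VOI box: span {span} != side {self.side}")
        if np.any(np.asarray(self.lo) < 0):
            raise ValueError(f"negative lower bound {self.lo}")

    def to_dict(self) -> dict:
        return asdict(self)


def _make_box(center, side: int, shape) -> VOIBox:
    center = np.asarray(center, dtype=int)
    half = side // 2
    want_lo = center - half
    want_hi = want_lo + side
    lo = np.clip(want_lo, 0, shape)
    hi = np.clip(want_hi, 0, shape)
    return VOIBox(
        center=tuple(int(c) for c in center),
        side=int(side),
        lo=tuple(int(v) for v in lo),
        hi=tuple(int(v) for v in hi),
        pad_before=tuple(int(v) for v in lo - want_lo),
        pad_after=tuple(int(v) for v in want_hi - hi),
    )


def label_centroid(mask: BinaryMask) -> tuple:
    """Centroid of the foreground, rounded half-up per axis.

    Raises ``ValueError`` on an empty mask.
    """
    idx = np.argwhere(mask.data > 0)
    if idx.size == 0:
        raise ValueError("cannot take the centroid of an empty mask")
    mean = idx.mean(axis=0)
    return tuple(int(np.floor(m + 0.5)) for m in mean)


def crop_cube(vol: VolumeImage, center, side: int):
    """Extract a zero-padded cube of shape ``(side,)*3`` centred at ``center``.

    Returns ``(array, VOIBox)``. The box records the clipped in-volume bounds
    and the zero padding applied on each face.  Cropping a vessel volume and
    its contour with the same box yields spatially aligned channels.
    """
    if side < 1:
        raise ValueError(f"side must be >= 1, got {side}")
    shape = np.asarray(vol.shape)
    center = np.asarray(center, dtype=int)
    if np.any(center < 0) or np.any(center >= shape):
        raise ValueError(f"center {tuple(center)} outside volume of shape {tuple(shape)}")
    box = _make_box(center, side, shape)
    src = vol.data[box.lo[0]:box.hi[0], box.lo[1]:box.hi[1], box.lo[2]:box.hi[2]]
    out = np.zeros((side, side, side), dtype=vol.data.dtype)
    sl = tuple(
        slice(pb, pb + (h - l))
        for pb, l, h in zip(box.pad_before, box.lo, box.hi)
    )
    out[sl] = src
    return out, box


def propose_vois(coarse_mask: BinaryMask, side: int = 64) -> list:
    """Propose one VOI per 26-connected component of the coarse mask.

    Boxes whose centres lie within ``side/2`` voxels of one another
    (Chebyshev distance) are merged into a single box at the count-weighted
    mean centroid, so one aneurysm split across touching blobs triggers a
    single fine pass.  An empty mask yields an empty list.
    """
    labels, n = ndimage.label(coarse_mask.data > 0, structure=CONNECTIVITY_26)
    if n == 0:
        return []
    centroids = np.asarray(ndimage.center_of_mass(coarse_mask.data > 0, labels, range(1, n + 1)))
    counts = np.asarray(ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1)))

    # Greedy agglomerative merge on the Chebyshev-near centroids.
    cents = [c for c in centroids]
    wts = [w for w in counts]
    merged = True
    while merged and len(cents) > 1:
        merged = False
        for i in range(len(cents)):
            for j in range(i + 1, len(cents)):
                if np.max(np.abs(cents[i] - cents[j])) < side / 2:
                    w = wts[i] + wts[j]
                    cents[i] = (cents[i] * wts[i] + cents[j] * wts[j]) / w
                    wts[i] = w
                    del cents[j], wts[j]
                    merged = True
                    break
            if merged:
                break

    shape = np.asarray(coarse_mask.shape)
    boxes = []
    for c in cents:
        center = np.clip(np.floor(c + 0.5).astype(int), 0, shape - 1)
        boxes.append(_make_box(center, side, shape))
    return boxes


def paste_back(voi_masks: list, shape, spacing=(1.0, 1.0, 1.0)) -> BinaryMask:
    """Restore VOI-level binary predictions into a full-size mask.

    Padded regions of each VOI are discarded; overlapping VOIs combine by
    logical OR; voxels outside every VOI are 0.
    """
    shape = tuple(int(s) for s in shape)
    full = np.zeros(shape, dtype=np.uint8)
    for arr, box in voi_masks:
        arr = np.asarray(arr)
        if arr.shape != (box.side,) * 3:
            raise ValueError(f"VOI mask shape {arr.shape} != side {box.side}")
        if any(h > s for h, s in zip(box.hi, shape)):
            raise ValueError(f"box bounds {box.hi} exceed volume shape {shape}")
        sl_src = tuple(
            slice(pb, pb + (h - l))
            for pb, l, h in zip(box.pad_before, box.lo, box.hi)
        )
        sl_dst = tuple(slice(l, h) for l, h in zip(box.lo, box.hi))
        full[sl_dst] |= (arr[sl_src] > 0).astype(np.uint8)
    return BinaryMask(data=full, spacing=spacing)
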