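"""Evaluation metrics for binary segmentations: DSC, Hausdorff distance, VS.

All three compare a predicted mask against ground truth:

* DSC — dice similarity coefficient ``2|GT ∩ Pred| / (|GT| + |Pred|)``;
* HD — symmetric Hausdorff distance between foreground voxel-centre point
  sets, in physical millimetres using the voxel spacing (the full maximum,
  not a percentile variant);
* VS — volumetric similarity ``1 - ||GT| - |Pred|| / (|GT| + |Pred|)``.

The Hausdorff distance is undefined when either mask is empty; those cases
return ``nan`` as a sentinel and cohort summaries exclude them from the HD
mean while counting how often they occurred.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import directed_hausdorff

__all__ = [
    "SegScores",
    "dice_coefficient",
    "hausdorff_mm",
    "volumetric_similarity",
    "score_pair",
]


@dataclass
class SegScores:
    """Per-case metric triple; ``hd_mm`` is ``nan`` when undefined."""

    dsc: float
    hd_mm: float
    vs: float

    @property
    def hd_defined(self) -> bool:
        return not math.isnan(self.hd_mm)


def _data(x):
    return np.asarray(getattr(x, "data", x))


def _check_shapes(gt, pred):
    g, p = _data(gt), _data(pred)
    if g.shape != p.shape:
        raise ValueError(f"shape mismatch: gt {g.shape} vs pred {p.shape}")
    return g > 0, p > 0


def dice_coefficient(gt, pred) -> float:
    """``2|GT ∩ Pred| / (|GT| + |Pred|)``; 1 when both masks are empty."""
    g, p = _check_shapes(gt, pred)
    denom = int(g.sum()) + int(p.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.logical_and(g, p).sum()) / denom


def volumetric_similarity(gt, pred) -> float:
    """``1 - ||GT| - |Pred|| / (|GT| + |Pred|)``; 1 when both are empty."""
    g, p = _check_shapes(gt, pred)
    ng, np_ = int(g.sum()), int(p.sum())
    if ng + np_ == 0:
        return 1.0
    return 1.0 - abs(ng - np_) / (ng + np_)


def hausdorff_mm(gt, pred, spacing=None) -> float:
    """Symmetric Hausdorff distance between foreground point sets, in mm.

    ``max(h(GT, Pred), h(Pred, GT))`` over voxel centres scaled by the voxel
    spacing. Returns ``nan`` (undefined) if either mask is empty.
    """
    g, p = _check_shapes(gt, pred)
    if spacing is None:
        spacing = getattr(gt, "spacing", None)
        if spacing is None:
            spacing = (1.0, 1.0, 1.0)
    spacing = np.asarray(spacing, dtype=float)
    if not g.any() or not p.any():
        return float("nan")
    pts_g = np.argwhere(g) * spacing
    pts_p = np.argwhere(p) * spacing
    return max(
        directed_hausdorff(pts_g, pts_p)[0],
        directed_hausdorff(pts_p, pts_g)[0],
    )


def score_pair(gt, pred, spacing=None) -> SegScores:
    """All three metrics for one GT/prediction pair."""
    return SegScores(
        dsc=dice_coefficient(gt, pred),
        hd_mm=hausdorff_mm(gt, pred, spacing),
        vs=volumetric_similarity(gt, pred),
    )
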