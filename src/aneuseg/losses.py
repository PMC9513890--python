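"""Soft dice and the (1 - DSC)^beta weighted dice loss.

The training objective for the fine network is a soft dice loss scaled by a
focal-style weight ``(1 - D)^beta`` where ``D`` is the current soft dice:
poorly overlapping predictions incur a relatively larger loss, steering the
optimiser toward voxels that are hard to segment.  ``beta`` lives in [0, 1];
``beta = 0`` recovers the plain negative soft dice.

Both functions are generic over numpy arrays and :mod:`aneuseg.nn` tensors —
the arithmetic is written with operators both support, so the very same code
path that is unit-tested against scalar oracles is the one differentiated
during training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LossConfig", "soft_dice", "weighted_dice_loss"]


@dataclass
class LossConfig:
    """Configuration of the weighted dice loss.

    beta:
        Focal exponent in [0, 1]; 0 disables the weighting.
    smooth:
        Smoothing constant S > 0 added to numerator (S/2) and denominator (S)
        so the empty-vs-empty case evaluates to 1. Default 1e-4.
    detach_weight:
        When true (default) the ``(1 - D)^beta`` factor is treated as a
        constant during differentiation and contributes no gradient.
    """

    beta: float = 0.1
    smooth: float = 1e-4
    detach_weight: bool = True

    def __post_init__(self):
        if not (0.0 <= self.beta <= 1.0):
            raise ValueError(f"beta must be in [0, 1], got {self.beta}")
        if not self.smooth > 0:
            raise ValueError(f"smooth must be > 0, got {self.smooth}")


def _fg(x):
    """Data array of a mask/volume wrapper; arrays and tensors pass through."""
    if isinstance(x, np.ndarray) or hasattr(x, "backward"):
        return x
    return np.asarray(getattr(x, "data", x))


def soft_dice(pred_prob, gt, smooth: float = 1e-4):
    """Soft dice overlap ``2 (sum g*p + S/2) / (sum g + sum p + S)``.

    ``pred_prob`` holds per-voxel foreground probabilities in [0, 1]; ``gt``
    is a binary mask. Sums run over all voxels. Accepts numpy arrays or
    autodiff tensors for ``pred_prob``.
    """
    p = _fg(pred_prob)
    g = np.asarray(_fg(gt), dtype=np.float32)
    p_shape = tuple(p.shape)
    if p_shape != tuple(g.shape):
        raise ValueError(f"shape mismatch: pred {p_shape} vs gt {g.shape}")
    inter = (p * g).sum()
    return (2.0 * inter + smooth) / (g.sum() + p.sum() + smooth)


def weighted_dice_loss(pred_prob, gt, cfg: LossConfig = LossConfig()):
    """Weighted dice loss ``-(1 - D)^beta * D`` with ``D`` the soft dice.

    Lies in [-1, 0]; at perfect overlap the weight vanishes and the loss is
    ~0; at ``beta = 0`` it equals the plain negative soft dice exactly.
    With ``cfg.detach_weight`` the weight factor is a constant w.r.t. the
    prediction, so the gradient is ``(1 - D)^beta`` times the plain soft-dice
    gradient.
    """
    d = soft_dice(pred_prob, gt, cfg.smooth)
    d_w = d.detach() if (cfg.detach_weight and hasattr(d, "detach")) else d
    weight = (1.0 - d_w) ** cfg.beta
    return -(weight * d)
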