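"""The two trainable networks of the cascade.

The fine network is a dual-channel 3D U-Net variant: a four-level encoder of
strided 3x3x3 convolutions each followed by a residual context block (two
stride-1 convolutions with dropout in between), a squeeze-and-excitation
block after the penultimate context block, and a decoder of nearest-neighbour
upsampling + localization blocks on concatenated skip features, with another
SE block after the first upsampling block.  Auxiliary segmentation heads at
the coarsest decoder levels are upsampled and summed into the final head
before the softmax (deep supervision).

The coarse network is a deliberately small single-channel encoder–decoder
whose only job is to localize candidate aneurysms at full-volume scale; it
honours the stage-one input contract and training schedule without
reproducing any specific detection architecture.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from . import nn
from .nn import Tensor, concat

__all__ = [
    "DUNetConfig",
    "CoarseConfig",
    "build_dunet",
    "build_coarse_cnn",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class DUNetConfig:
    """Fine-network hyperparameters.

    ``in_channels=2`` is the dual-channel (vessel + contour) model;
    ``in_channels=1`` is the single-channel ablation.  ``base_filters=16``
    matches the full-scale design; the desk preset uses 4.
    """

    in_channels: int = 2
    n_classes: int = 2
    depth: int = 4
    base_filters: int = 16
    dropout_p: float = 0.3
    se_reduction: int = 8
    deep_supervision_levels: int = 2
    norm: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.in_channels not in (1, 2):
            raise ValueError("in_channels must be 1 (ablation) or 2 (dual-channel)")
        if not (0.0 <= self.dropout_p < 1.0):
            raise ValueError("dropout_p must be in [0, 1)")
        if self.depth < 2:
            raise ValueError("depth must be >= 2")


@dataclass
class CoarseConfig:
    """Coarse-network hyperparameters (single-channel localizer)."""

    in_channels: int = 1
    input_side: int = 128
    base_filters: int = 8
    n_classes: int = 2
    depth: int = 3
    dropout_p: float = 0.1
    norm: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.in_channels != 1:
            raise ValueError("the coarse network is single-channel")


class _ConvBlock(nn.Module):
    """conv3x3x3 (given stride) -> optional instance norm -> leaky ReLU."""

    def __init__(self, in_ch, out_ch, stride, norm, rng):
        super().__init__()
        self.conv = nn.Conv3d(in_ch, out_ch, k=3, stride=stride, rng=rng)
        self.norm = nn.InstanceNorm3d(out_ch) if norm else None
        self.act = nn.LeakyReLU()

    def forward(self, x):
        x = self.conv(x)
        if self.norm is not None:
            x = self.norm(x)
        return self.act(x)


class _ContextBlock(nn.Module):
    """Two stride-1 conv blocks with dropout in between."""

    def __init__(self, ch, dropout_p, norm, rng, seed):
        super().__init__()
        self.c1 = _ConvBlock(ch, ch, 1, norm, rng)
        self.drop = nn.Dropout(dropout_p, seed=seed)
        self.c2 = _ConvBlock(ch, ch, 1, norm, rng)

    def forward(self, x):
        return self.c2(self.drop(self.c1(x)))


class _UpBlock(nn.Module):
    """Nearest-neighbour x2 upsampling followed by a 3x3x3 conv block."""

    def __init__(self, in_ch, out_ch, norm, rng):
        super().__init__()
        self.conv = _ConvBlock(in_ch, out_ch, 1, norm, rng)

    def forward(self, x):
        return self.conv(nn.functional.upsample_nearest(x, 2))


class _Localization(nn.Module):
    """3x3x3 conv then 1x1x1 conv, both activated."""

    def __init__(self, in_ch, out_ch, norm, rng):
        super().__init__()
        self.c3 = _ConvBlock(in_ch, out_ch, 1, norm, rng)
        self.c1 = nn.Conv3d(out_ch, out_ch, k=1, rng=rng)
        self.act = nn.LeakyReLU()

    def forward(self, x):
        return self.act(self.c1(self.c3(x)))


def _to_channels_last(x):
    """Accept (C, s, s, s) or (N, C, s, s, s); return (N, D, H, W, C) tensor."""
    t = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))
    squeeze = t.data.ndim == 4
    if squeeze:
        t = t.reshape(1, *t.data.shape)
    if t.data.ndim != 5:
        raise ValueError(f"expected (C, s, s, s) or (N, C, s, s, s), got {t.data.shape}")
    return t.transpose(0, 2, 3, 4, 1), squeeze


def _to_channels_first(probs, squeeze):
    out = probs.transpose(0, 4, 1, 2, 3)
    return out.reshape(*out.data.shape[1:]) if squeeze else out


class DUNet(nn.Module):
    """See module docstring; built by :func:`build_dunet`."""

    def __init__(self, cfg: DUNetConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        d, f0 = cfg.depth, cfg.base_filters
        filters = [f0 * 2 ** i for i in range(d)]

        # lists must be complete at assignment time for submodule registration
        self.in_conv = _ConvBlock(cfg.in_channels, filters[0], 1, cfg.norm, rng)
        enc_ctx = [_ContextBlock(filters[0], cfg.dropout_p, cfg.norm, rng, cfg.seed + 1)]
        downs = []
        for i in range(1, d):
            downs.append(_ConvBlock(filters[i - 1], filters[i], 2, cfg.norm, rng))
            enc_ctx.append(
                _ContextBlock(filters[i], cfg.dropout_p, cfg.norm, rng, cfg.seed + 1 + i)
            )
        self.enc_ctx = enc_ctx
        self.downs = downs
        # SE after the penultimate context block (encoder level d-2)
        self.enc_se = nn.SEBlock(filters[d - 2], cfg.se_reduction, rng)

        ups, locs = [], []
        for lvl in range(d - 2, -1, -1):
            ups.append(_UpBlock(filters[lvl + 1], filters[lvl], cfg.norm, rng))
            locs.append(_Localization(2 * filters[lvl], filters[lvl], cfg.norm, rng))
        self.ups = ups
        self.locs = locs
        # SE after the first upsampling block (decoder level d-2)
        self.dec_se = nn.SEBlock(filters[d - 2], cfg.se_reduction, rng)

        # deep-supervision heads at the coarsest decoder levels + final head
        self.ds_levels = [
            lvl for lvl in range(d - 2, 0, -1)
        ][: cfg.deep_supervision_levels]
        self.heads = [
            nn.Conv3d(filters[lvl], cfg.n_classes, k=1, rng=rng) for lvl in self.ds_levels
        ]
        self.out_conv = _ConvBlock(filters[0], filters[0], 1, cfg.norm, rng)
        self.final_head = nn.Conv3d(filters[0], cfg.n_classes, k=1, rng=rng)

    def forward(self, x):
        t, squeeze = _to_channels_last(x)
        div = 2 ** (self.cfg.depth - 1)
        if any(s % div for s in t.data.shape[1:4]):
            raise ValueError(
                f"input spatial shape {t.data.shape[1:4]} not divisible by {div}"
            )
        d = self.cfg.depth
        h = self.in_conv(t)
        skips = []
        for i in range(d):
            if i > 0:
                h = self.downs[i - 1](h)
            ctx = self.enc_ctx[i](h)
            h = h + ctx  # residual between the stage convolution and context block
            if i == d - 2:
                h = self.enc_se(h)
            skips.append(h)

        seg_sum = None
        h = skips[-1]
        for step, lvl in enumerate(range(d - 2, -1, -1)):
            h = self.ups[step](h)
            if step == 0:
                h = self.dec_se(h)
            h = concat([h, skips[lvl]], axis=-1)
            h = self.locs[step](h)
            if lvl in self.ds_levels:
                seg = self.heads[self.ds_levels.index(lvl)](h)
                for _ in range(lvl):
                    seg = nn.functional.upsample_nearest(seg, 2)
                seg_sum = seg if seg_sum is None else seg_sum + seg
        logits = self.final_head(self.out_conv(h))
        if seg_sum is not None:
            logits = logits + seg_sum
        return _to_channels_first(logits.softmax(axis=-1), squeeze)


class CoarseCNN(nn.Module):
    """Small single-channel encoder–decoder localizer."""

    def __init__(self, cfg: CoarseConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        d, f0 = cfg.depth, cfg.base_filters
        filters = [f0 * 2 ** i for i in range(d)]
        self.in_conv = _ConvBlock(cfg.in_channels, filters[0], 1, cfg.norm, rng)
        self.downs = [
            _ConvBlock(filters[i - 1], filters[i], 2, cfg.norm, rng) for i in range(1, d)
        ]
        self.mids = [
            _ContextBlock(filters[i], cfg.dropout_p, cfg.norm, rng, cfg.seed + 7 + i)
            for i in range(1, d)
        ]
        self.ups = [
            _UpBlock(filters[lvl + 1], filters[lvl], cfg.norm, rng)
            for lvl in range(d - 2, -1, -1)
        ]
        self.locs = [
            _Localization(2 * filters[lvl], filters[lvl], cfg.norm, rng)
            for lvl in range(d - 2, -1, -1)
        ]
        self.head = nn.Conv3d(filters[0], cfg.n_classes, k=1, rng=rng)

    def forward(self, x):
        t, squeeze = _to_channels_last(x)
        div = 2 ** (self.cfg.depth - 1)
        if any(s % div for s in t.data.shape[1:4]):
            raise ValueError(
                f"input spatial shape {t.data.shape[1:4]} not divisible by {div}"
            )
        h = self.in_conv(t)
        skips = [h]
        for down, mid in zip(self.downs, self.mids):
            h = down(h)
            h = h + mid(h)
            skips.append(h)
        for step, lvl in enumerate(range(self.cfg.depth - 2, -1, -1)):
            h = self.ups[step](h)
            h = concat([h, skips[lvl]], axis=-1)
            h = self.locs[step](h)
        return _to_channels_first(self.head(h).softmax(axis=-1), squeeze)


def build_dunet(cfg: DUNetConfig) -> DUNet:
    """Construct the fine (dual- or single-channel) network."""
    return DUNet(cfg)


def build_coarse_cnn(cfg: CoarseConfig) -> CoarseCNN:
    """Construct the coarse localizer network."""
    return CoarseCNN(cfg)


def save_checkpoint(net, path) -> None:
    """Save weights (.npz) plus a JSON sidecar echoing the config."""
    np.savez(path, **net.state_dict())
    sidecar = str(path).removesuffix(".npz") + ".json"
    kind = "dunet" if isinstance(net, DUNet) else "coarse"
    with open(sidecar, "w") as fh:
        json.dump({"kind": kind, "config": asdict(net.cfg)}, fh, indent=2)


def load_checkpoint(path):
    """Rebuild a network from a checkpoint written by :func:`save_checkpoint`."""
    sidecar = str(path).removesuffix(".npz") + ".json"
    with open(sidecar) as fh:
        meta = json.load(fh)
    if meta["kind"] == "dunet":
        net = build_dunet(DUNetConfig(**meta["config"]))
    else:
        net = build_coarse_cnn(CoarseConfig(**meta["config"]))
    with np.load(str(path) if str(path).endswith(".npz") else str(path) + ".npz") as zf:
        net.load_state_dict({k: zf[k] for k in zf.files})
    return net
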