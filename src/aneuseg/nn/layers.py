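"""Layer library for the segmentation networks.

Modules register parameters and submodules automatically on attribute
assignment (torch-style), support train/eval switching, and expose flat
parameter dictionaries for the optimizers and for checkpointing.
"""

from __future__ import annotations

import numpy as np

from . import functional as F
from .tensor import Tensor, concat

__all__ = [
    "Module",
    "Sequential",
    "Conv3d",
    "InstanceNorm3d",
    "Dropout",
    "LeakyReLU",
    "SEBlock",
    "concat",
]


class Module:
    """Base class with automatic parameter/submodule registration."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Tensor):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        elif isinstance(value, (list, tuple)) and value and all(
            isinstance(v, Module) for v in value
        ):
            for i, v in enumerate(value):
                self._modules[f"{name}.{i}"] = v
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = "") -> dict:
        out = {prefix + k: v for k, v in self._params.items()}
        for name, mod in self._modules.items():
            out.update(mod.named_parameters(prefix + name + "."))
        return out

    def parameters(self) -> list:
        return list(self.named_parameters().values())

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def train(self, mode: bool = True):
        object.__setattr__(self, "training", mode)
        for mod in self._modules.values():
            mod.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self) -> dict:
        return {k: v.data.copy() for k, v in self.named_parameters().items()}

    def load_state_dict(self, state: dict) -> None:
        params = self.named_parameters()
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"parameter name mismatch: {sorted(missing)[:5]}")
        for k, v in params.items():
            v.data[...] = state[k]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x


class Conv3d(Module):
    """3x3x3 (or 1x1x1) convolution, 'same' padding, He-initialised."""

    def __init__(self, in_ch: int, out_ch: int, k: int = 3, stride: int = 1,
                 bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * k ** 3
        scale = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(rng.normal(0.0, scale, size=(out_ch, in_ch, k, k, k)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True) if bias else None
        self.stride = stride

    def forward(self, x):
        return F.conv3d(x, self.weight, self.bias, stride=self.stride)


class InstanceNorm3d(Module):
    """Per-sample, per-channel spatial normalization with affine parameters.

    Channels-last layout: normalizes over the spatial axes (1, 2, 3).
    """

    def __init__(self, channels: int, eps: float = 1e-5, affine: bool = True):
        super().__init__()
        self.eps = eps
        if affine:
            self.gamma = Tensor(np.ones(channels), requires_grad=True)
            self.beta = Tensor(np.zeros(channels), requires_grad=True)
        else:
            self.gamma = None
            self.beta = None

    def forward(self, x):
        mu = x.mean(axis=(1, 2, 3), keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=(1, 2, 3), keepdims=True)
        norm = centered * (var + self.eps) ** -0.5
        if self.gamma is not None:
            norm = norm * self.gamma + self.beta
        return norm


class Dropout(Module):
    """Inverted dropout with its own seeded stream (identity in eval mode)."""

    def __init__(self, p: float, seed: int = 0):
        super().__init__()
        if not (0.0 <= p < 1.0):
            raise ValueError(f"dropout probability must be in [0, 1), got {p}")
        self.p = p
        self.rng = np.random.default_rng(seed)

    def forward(self, x):
        return F.dropout(x, self.p, self.rng, self.training)


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.01):
        super().__init__()
        self.slope = slope

    def forward(self, x):
        return x.leaky_relu(self.slope)


class SEBlock(Module):
    """Squeeze-and-excitation channel attention.

    Global average pool -> bottleneck 1x1x1 conv (reduction r) -> ReLU ->
    1x1x1 conv -> sigmoid gate multiplied onto the input channels.
    """

    def __init__(self, channels: int, reduction: int = 8,
                 rng: np.random.Generator | None = None):
        super().__init__()
        hidden = max(1, channels // reduction)
        self.fc1 = Conv3d(channels, hidden, k=1, rng=rng)
        self.fc2 = Conv3d(hidden, channels, k=1, rng=rng)

    def forward(self, x):
        s = F.global_avg_pool(x)
        s = self.fc1(s).relu()
        gate = self.fc2(s).sigmoid()
        return x * gate
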