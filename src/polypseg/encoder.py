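"""Pre-activation residual encoder (ResNetV2-style) with group norm.

Four stages — a strided 7x7 stem plus three residual blocks — produce
feature maps at 1/2, 1/4, 1/8 and 1/16 of the input resolution.  Every
residual unit is GN -> ReLU -> conv with an identity shortcut, and all
downsampling is done by stride-2 convolutions, never pooling.  The
deepest map (1/16) is what the transformer bridge consumes.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .nn import tensor as T
from .nn.layers import Conv2d, GroupNorm, Module, ModuleList, Sequential
from .nn.tensor import Tensor

ENCODER_SCALES = (2, 4, 8, 16)


@dataclasses.dataclass
class FeatureMap:
    """A C x H x W activation grid tagged with its downsampling factor."""

    values: Tensor
    scale: int

    @property
    def channels(self) -> int:
        return self.values.shape[-3]


@dataclasses.dataclass
class EncoderConfig:
    stage_channels: tuple[int, int, int, int] = (64, 256, 512, 1024)
    units_per_block: tuple[int, int, int] = (3, 4, 6)
    gn_groups: int = 32
    in_channels: int = 3
    bottleneck_expansion: int = 4

    def __post_init__(self):
        if any(c <= 0 for c in self.stage_channels):
            raise ValueError(f"stage channels must be positive: {self.stage_channels}")
        if any(u < 1 for u in self.units_per_block):
            raise ValueError(f"units per block must be >= 1: {self.units_per_block}")
        for c in self.stage_channels:
            _check_groups(self.gn_groups, c)

    def groups_for(self, channels: int) -> int:
        _check_groups(self.gn_groups, channels)
        return self.gn_groups


def _check_groups(groups: int, channels: int) -> None:
    if channels % groups:
        raise ValueError(
            f"gn_groups={groups} does not divide channel count {channels}; "
            f"pick a divisor (e.g. gn_groups=min(32, channels))")


class PreactBottleneck(Module):
    """GN-ReLU-conv bottleneck unit (1x1 -> 3x3 -> 1x1) with identity map.

    When its convolution weights are all zero the unit reduces to the
    shortcut path, i.e. the identity for matching shapes.
    """

    def __init__(self, in_channels: int, out_channels: int, mid_channels: int,
                 gn_groups: int, stride: int, rng: np.random.Generator):
        super().__init__()
        self.stride = stride
        self.gn1 = GroupNorm(_valid_groups(gn_groups, in_channels), in_channels)
        self.conv1 = Conv2d(in_channels, mid_channels, 1, rng, bias=False)
        self.gn2 = GroupNorm(_valid_groups(gn_groups, mid_channels), mid_channels)
        self.conv2 = Conv2d(mid_channels, mid_channels, 3, rng,
                            stride=stride, bias=False)
        self.gn3 = GroupNorm(_valid_groups(gn_groups, mid_channels), mid_channels)
        self.conv3 = Conv2d(mid_channels, out_channels, 1, rng, bias=False)
        if in_channels != out_channels or stride != 1:
            self.shortcut = Conv2d(in_channels, out_channels, 1, rng,
                                   stride=stride, bias=False)
        else:
            self.shortcut = None

    def forward(self, x: Tensor) -> Tensor:
        pre = T.relu(self.gn1(x))
        # ResNetV2: a projection shortcut taps the pre-activated input
        residual = self.shortcut(pre) if self.shortcut is not None else x
        y = self.conv1(pre)
        y = self.conv2(T.relu(self.gn2(y)))
        y = self.conv3(T.relu(self.gn3(y)))
        return y + residual


def _valid_groups(groups: int, channels: int) -> int:
    g = min(groups, channels)
    _check_groups(g, channels)
    return g


class Encoder(Module):
    """Stem + three residual blocks; returns four feature maps."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        c0, c1, c2, c3 = cfg.stage_channels
        self.stem = Conv2d(cfg.in_channels, c0, 7, rng, stride=2, bias=True)
        ins = (c0, c1, c2)
        outs = (c1, c2, c3)
        blocks = []
        for b, (cin, cout, units) in enumerate(zip(ins, outs, cfg.units_per_block)):
            mid = max(cout // cfg.bottleneck_expansion, 1)
            layers = []
            for u in range(units):
                layers.append(PreactBottleneck(
                    cin if u == 0 else cout, cout, mid,
                    cfg.gn_groups, stride=2 if u == 0 else 1, rng=rng))
            blocks.append(Sequential(*layers))
        self.blocks = ModuleList(blocks)

    def forward(self, x: Tensor) -> tuple[FeatureMap, ...]:
        _validate_input(x)
        f0 = self.stem(x)
        feats = [f0]
        y = f0
        for block in self.blocks:
            y = block(y)
            feats.append(y)
        return tuple(FeatureMap(values=v, scale=s)
                     for v, s in zip(feats, ENCODER_SCALES))


def _validate_input(x: Tensor) -> None:
    if x.ndim != 4 or x.shape[1] < 1:
        raise ValueError(f"expected B x C x H x W input, got shape {x.shape}")
    h, w = x.shape[2], x.shape[3]
    if h % 16 or w % 16:
        raise ValueError(
            f"input spatial size {h}x{w} must be divisible by 16 "
            f"(four stride-2 stages)")


def build_encoder(cfg: EncoderConfig, rng: np.random.Generator | int = 0) -> Encoder:
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return Encoder(cfg, rng)


def encode(encoder: Encoder, batch) -> tuple[FeatureMap, ...]:
    """Run the encoder on a B x 3 x H x W batch (array or Tensor)."""
    x = batch if isinstance(batch, Tensor) else Tensor(batch)
    return encoder(x)
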