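"""Multi-scale feature fusion (MSFF) unit.

An MSFF node takes the channel-concatenation of upsampled deeper
features and skip features, compresses it with a conv block (3x3 conv +
BN + ReLU), and enriches it with a modified Inception-ResNet stage:
three parallel convolutional branches of growing receptive field
(1x1; 1x1->3x3; 1x1->3x3->3x3, every conv followed by BN), whose
concatenation is linearly projected back to the node width, scaled by a
residual factor ``alpha`` in [0,1], added to the identity path, and
passed through a final ReLU:

    x  <- CB(x)
    out = ReLU( x + alpha * Proj([b1(x), b2(x), b3(x)]) )

With ``alpha = 0`` the stage is an exact pass-through of the conv-block
output (which is nonnegative, so the final ReLU is the identity on it).
``alpha = 1`` is the default used throughout.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .nn import tensor as T
from .nn.layers import BatchNorm2d, Conv2d, Module, Sequential
from .nn.tensor import Tensor


@dataclasses.dataclass
class MSFFConfig:
    out_channels: int
    alpha: float = 1.0
    branch_channels: int | None = None  # default: max(out_channels // 2, 4)

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0,1], got {self.alpha}")
        if self.out_channels < 1:
            raise ValueError(f"out_channels must be positive, got {self.out_channels}")

    @property
    def branch_width(self) -> int:
        if self.branch_channels is not None:
            return self.branch_channels
        return max(self.out_channels // 2, 4)

    def branch_spec(self) -> dict:
        """Serializable description of the three branch kernel stacks."""
        w = self.branch_width
        return {"b1": [[1, w]], "b2": [[1, w], [3, w]],
                "b3": [[1, w], [3, w], [3, w]],
                "projection": [1, self.out_channels], "alpha": self.alpha}


class ConvBlock(Module):
    """3x3 convolution + batch norm + ReLU; spatial size preserved."""

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator):
        super().__init__()
        self.conv = Conv2d(in_channels, out_channels, 3, rng, bias=False)
        self.bn = BatchNorm2d(out_channels)

    def forward(self, x: Tensor) -> Tensor:
        return T.relu(self.bn(self.conv(x)))


def _conv_bn(cin: int, cout: int, k: int, rng: np.random.Generator) -> Sequential:
    return Sequential(Conv2d(cin, cout, k, rng, bias=False), BatchNorm2d(cout))


class InceptionResNetFuse(Module):
    """Three-branch Inception-ResNet stage with residual scaling."""

    def __init__(self, cfg: MSFFConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        c, w = cfg.out_channels, cfg.branch_width
        self.b1 = _conv_bn(c, w, 1, rng)
        self.b2 = Sequential(_conv_bn(c, w, 1, rng), _conv_bn(w, w, 3, rng))
        self.b3 = Sequential(_conv_bn(c, w, 1, rng), _conv_bn(w, w, 3, rng),
                             _conv_bn(w, w, 3, rng))
        # linear 1x1 projection restores the node width for the residual add
        self.proj = Conv2d(3 * w, c, 1, rng, bias=False)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.cfg.out_channels:
            raise ValueError(
                f"inception_resnet_fuse expects {self.cfg.out_channels} input "
                f"channels, got {x.shape[1]}")
        branches = T.concatenate([self.b1(x), self.b2(x), self.b3(x)], axis=1)
        out = x + self.cfg.alpha * self.proj(branches)
        return T.relu(out)


class MSFF(Module):
    """Conv block followed by the Inception-ResNet fusion stage."""

    def __init__(self, in_channels: int, cfg: MSFFConfig,
                 rng: np.random.Generator):
        super().__init__()
        self.conv_block = ConvBlock(in_channels, cfg.out_channels, rng)
        self.fuse = InceptionResNetFuse(cfg, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fuse(self.conv_block(x))
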