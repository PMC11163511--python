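"""Full segmentation model: nested-UNet grid + transformer bridge.

The model is a UNet++-style grid of nodes X[i][j] over four scales
(i = 0..3, resolutions 1/2 .. 1/16).  Column j = 0 holds the encoder
outputs; when the transformer is enabled the deepest feature X[3][0] is
replaced by the bridge output (tokens mapped back to a feature map with
the same channel count).  Every other node fuses all earlier features
of its row with the 2x-upsampled node below-left:

    X[i][j] = MSFF( concat(X[i][0], ..., X[i][j-1], up2(X[i+1][j-1])) )

With MSFF disabled each node degrades to a plain conv block, and with
the transformer disabled the bridge is simply absent — the ablation
arms contain no parameters of the removed component.  A 1x1 head on
X[0][3] followed by a bilinear 2x upsample yields per-pixel logits at
the input resolution.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from typing import Any

import numpy as np

from .bridge import BridgeConfig, TokensToMap, TransformerBridge
from .encoder import Encoder, EncoderConfig, FeatureMap
from .msff import MSFF, ConvBlock, MSFFConfig
from .nn import tensor as T
from .nn.layers import Conv2d, Module, ModuleList
from .nn.tensor import Tensor

N_LEVELS = 4


@dataclasses.dataclass
class ModelConfig:
    encoder: EncoderConfig = dataclasses.field(default_factory=EncoderConfig)
    bridge: BridgeConfig = dataclasses.field(default_factory=BridgeConfig)
    decoder_channels: tuple[int, int, int, int] = (64, 128, 256, 512)
    enable_transformer: bool = True
    enable_msff: bool = True
    alpha: float = 1.0
    upsample_mode: str = "bilinear"
    ref_input_size: tuple[int, int] = (224, 224)

    def __post_init__(self):
        if len(self.decoder_channels) != N_LEVELS:
            raise ValueError(
                f"decoder_channels must list {N_LEVELS} levels, "
                f"got {self.decoder_channels}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0,1], got {self.alpha}")
        if self.upsample_mode not in ("bilinear", "nearest"):
            raise ValueError(f"unknown upsample_mode '{self.upsample_mode}'")
        if min(self.ref_input_size) % 16:
            raise ValueError("ref_input_size must be divisible by 16")

    # -- serialization -------------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ModelConfig":
        d = dict(d)
        d["encoder"] = EncoderConfig(**_tupled(d["encoder"]))
        d["bridge"] = BridgeConfig(**d["bridge"])
        return cls(**_tupled(d))

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _tupled(d: dict[str, Any]) -> dict[str, Any]:
    return {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}


@dataclasses.dataclass
class SegmentationOutput:
    """Logits with derived probabilities and the 0.5-threshold mask."""

    logits: Tensor            # B x 1 x H x W, in the autodiff graph
    probabilities: Tensor     # sigmoid(logits), in the autodiff graph

    @property
    def mask(self) -> np.ndarray:
        return (self.probabilities.data >= 0.5).astype(np.uint8)


class NestedUNetTransformer(Module):
    """The assembled encoder / bridge / nested-decoder network."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.encoder = Encoder(cfg.encoder, rng)
        enc_ch = cfg.encoder.stage_channels
        dec_ch = cfg.decoder_channels

        if cfg.enable_transformer:
            ref_grid = (cfg.ref_input_size[0] // 16 // cfg.bridge.patch_size,
                        cfg.ref_input_size[1] // 16 // cfg.bridge.patch_size)
            self.bridge = TransformerBridge(enc_ch[3], cfg.bridge, ref_grid, rng)
            self.bridge_out = TokensToMap(cfg.bridge.hidden_dim, enc_ch[3], rng)
        else:
            self.bridge = None
            self.bridge_out = None

        # row-wise channel bookkeeping: column 0 = encoder widths,
        # columns >= 1 = decoder widths for that row
        def width(i: int, j: int) -> int:
            return enc_ch[i] if j == 0 else dec_ch[i]

        nodes: list[Module] = []
        self._node_index: dict[tuple[int, int], int] = {}
        for j in range(1, N_LEVELS):
            for i in range(0, N_LEVELS - j):
                in_ch = sum(width(i, k) for k in range(j)) + width(i + 1, j - 1)
                if cfg.enable_msff:
                    node = MSFF(in_ch, MSFFConfig(dec_ch[i], alpha=cfg.alpha), rng)
                else:
                    node = ConvBlock(in_ch, dec_ch[i], rng)
                self._node_index[(i, j)] = len(nodes)
                nodes.append(node)
        self.nodes = ModuleList(nodes)
        self.head = Conv2d(dec_ch[0], 1, 1, rng, padding=0, bias=True)

    # -- forward -------------------------------------------------------------
    def forward(self, batch) -> SegmentationOutput:
        x = batch if isinstance(batch, Tensor) else Tensor(batch)
        b, c, h, w = x.shape
        feats = self.encoder(x)
        grid: dict[tuple[int, int], Tensor] = {
            (i, 0): f.values for i, f in enumerate(feats)}

        if self.bridge is not None:
            seq = self.bridge(feats[3])
            grid[(3, 0)] = self.bridge_out(seq, scale=16).values

        sizes = [f.values.shape[2:] for f in feats]
        for j in range(1, N_LEVELS):
            for i in range(0, N_LEVELS - j):
                below = T.resize2d(grid[(i + 1, j - 1)], tuple(sizes[i]),
                                   self.cfg.upsample_mode)
                cat = T.concatenate(
                    [grid[(i, k)] for k in range(j)] + [below], axis=1)
                grid[(i, j)] = self.nodes[self._node_index[(i, j)]](cat)

        logits = T.resize2d(self.head(grid[(0, N_LEVELS - 1)]), (h, w), "bilinear")
        return SegmentationOutput(logits=logits, probabilities=T.sigmoid(logits))

    def node(self, i: int, j: int) -> Module:
        """The fusion module at grid position (i, j), j >= 1."""
        return self.nodes[self._node_index[(i, j)]]

    def node_input_arity(self, i: int, j: int) -> int:
        """Number of feature maps concatenated at node (i, j)."""
        return j + 1


def build_model(cfg: ModelConfig, seed: int | np.random.Generator = 0
                ) -> NestedUNetTransformer:
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    return NestedUNetTransformer(cfg, rng)
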