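"""Self-attention bridge between encoder and decoder.

The deepest encoder map (1/16 resolution) is cut into P x P patches,
each linearly projected to a D-dimensional token; a learnable 1-D
position embedding is added, L pre-norm transformer layers (multi-head
self-attention + MLP, both on residual paths) mix the tokens, and the
sequence is reshaped back into a feature map for the decoder.  With a
14 x 14 bottleneck and P = 1 this gives the usual N = 196 tokens.

Attention is Softmax(Q K^T / sqrt(d)) V with per-head dimension
d = D / h and a row-max-stabilised softmax.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .encoder import FeatureMap
from .nn import tensor as T
from .nn.layers import Conv2d, Dropout, LayerNorm, Linear, Module, ModuleList, parameter
from .nn.tensor import Tensor


@dataclasses.dataclass
class TokenSequence:
    """A batch of N x D token matrices with their spatial patch grid."""

    tokens: Tensor          # B x N x D
    grid: tuple[int, int]   # (Hp, Wp) with Hp * Wp = N

    def __post_init__(self):
        n = self.tokens.shape[-2]
        if self.grid[0] * self.grid[1] != n:
            raise ValueError(f"grid {self.grid} inconsistent with N={n} tokens")


@dataclasses.dataclass
class BridgeConfig:
    patch_size: int = 1
    hidden_dim: int = 768
    n_layers: int = 12
    n_heads: int = 12
    mlp_ratio: float = 4.0
    dropout: float = 0.0

    def __post_init__(self):
        if self.hidden_dim % self.n_heads:
            raise ValueError(
                f"hidden_dim {self.hidden_dim} must be divisible by "
                f"n_heads {self.n_heads}")
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if self.patch_size < 1:
            raise ValueError("patch_size must be >= 1")


def scaled_attention(q: Tensor, k: Tensor, v: Tensor) -> Tensor:
    """Softmax(Q K^T / sqrt(d)) V on (..., N, d) stacks."""
    d = q.shape[-1]
    if k.shape[-1] != d or v.shape[-2] != k.shape[-2]:
        raise ValueError(
            f"incompatible attention shapes q={q.shape} k={k.shape} v={v.shape}")
    logits = T.matmul(q, T.transpose(k, tuple(range(k.ndim - 2)) + (k.ndim - 1, k.ndim - 2)))
    weights = T.softmax(logits * (1.0 / np.sqrt(d)), axis=-1)
    return T.matmul(weights, v)


class PatchEmbed(Module):
    """P x P patches -> D-dim tokens + learnable position embedding.

    The position embedding is created for a reference grid and
    bilinearly interpolated if the runtime bottleneck grid differs.
    """

    def __init__(self, in_channels: int, cfg: BridgeConfig,
                 ref_grid: tuple[int, int], rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.ref_grid = ref_grid
        p, d = cfg.patch_size, cfg.hidden_dim
        self.proj = Conv2d(in_channels, d, p, rng, stride=p, padding=0,
                           bias=True, init_scale=float(np.sqrt(1.0 / (in_channels * p * p))))
        self.pos_embed = parameter(
            rng.normal(0.0, 0.02, (ref_grid[0] * ref_grid[1], d)))

    def forward(self, f: FeatureMap) -> TokenSequence:
        x = f.values
        b, c, h, w = x.shape
        p = self.cfg.patch_size
        if h % p or w % p:
            raise ValueError(f"feature size {h}x{w} not divisible by patch size {p}")
        hp, wp = h // p, w // p
        y = self.proj(x)                                  # B x D x Hp x Wp
        d = self.cfg.hidden_dim
        tokens = T.transpose(T.reshape(y, (b, d, hp * wp)), (0, 2, 1))
        pos = self.pos_embed
        if (hp, wp) != self.ref_grid:
            grid = T.transpose(T.reshape(pos, (1,) + self.ref_grid + (d,)), (0, 3, 1, 2))
            pos = T.transpose(T.reshape(T.resize2d(grid, (hp, wp), "bilinear"),
                                        (1, d, hp * wp)), (0, 2, 1))
            pos = T.reshape(pos, (hp * wp, d))
        tokens = tokens + pos
        return TokenSequence(tokens=tokens, grid=(hp, wp))


class MultiHeadSelfAttention(Module):
    """h parallel scaled-attention heads, concatenated and projected."""

    def __init__(self, cfg: BridgeConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        d = cfg.hidden_dim
        self.wq = Linear(d, d, rng)
        self.wk = Linear(d, d, rng)
        self.wv = Linear(d, d, rng)
        self.out = Linear(d, d, rng)

    def forward(self, x: Tensor) -> Tensor:
        b, n, d = x.shape
        h = self.cfg.n_heads
        dh = d // h

        def split(t: Tensor) -> Tensor:
            return T.transpose(T.reshape(t, (b, n, h, dh)), (0, 2, 1, 3))

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        heads = scaled_attention(q, k, v)                 # B x h x N x dh
        merged = T.reshape(T.transpose(heads, (0, 2, 1, 3)), (b, n, d))
        return self.out(merged)


class TransformerLayer(Module):
    """Pre-norm block: x + MSA(LN(x)), then x + MLP(LN(x))."""

    def __init__(self, cfg: BridgeConfig, rng: np.random.Generator):
        super().__init__()
        d = cfg.hidden_dim
        hidden = int(round(cfg.mlp_ratio * d))
        self.norm1 = LayerNorm(d)
        self.attn = MultiHeadSelfAttention(cfg, rng)
        self.norm2 = LayerNorm(d)
        self.fc1 = Linear(d, hidden, rng)
        self.fc2 = Linear(hidden, d, rng)
        self.drop = Dropout(cfg.dropout, np.random.default_rng(rng.integers(2**31)))

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.drop(self.attn(self.norm1(x)))
        x = x + self.drop(self.fc2(T.gelu(self.fc1(self.norm2(x)))))
        return x


class TransformerBridge(Module):
    """Patch embedding followed by L transformer layers."""

    def __init__(self, in_channels: int, cfg: BridgeConfig,
                 ref_grid: tuple[int, int], rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.embed = PatchEmbed(in_channels, cfg, ref_grid, rng)
        self.layers = ModuleList([TransformerLayer(cfg, rng)
                                  for _ in range(cfg.n_layers)])

    def transformer_forward(self, seq: TokenSequence) -> TokenSequence:
        x = seq.tokens
        for layer in self.layers:
            x = layer(x)
        return TokenSequence(tokens=x, grid=seq.grid)

    def forward(self, f: FeatureMap) -> TokenSequence:
        return self.transformer_forward(self.embed(f))


class TokensToMap(Module):
    """Reshape tokens onto their grid and 3x3-convolve to out_channels."""

    def __init__(self, hidden_dim: int, out_channels: int,
                 rng: np.random.Generator):
        super().__init__()
        self.conv = Conv2d(hidden_dim, out_channels, 3, rng, bias=True)

    def forward(self, seq: TokenSequence, scale: int = 16) -> FeatureMap:
        b, n, d = seq.tokens.shape
        hp, wp = seq.grid
        if hp * wp != n:
            raise ValueError(f"grid {seq.grid} inconsistent with N={n}")
        grid = T.reshape(T.transpose(seq.tokens, (0, 2, 1)), (b, d, hp, wp))
        return FeatureMap(values=self.conv(grid), scale=scale)


def tokens_to_grid(seq: TokenSequence) -> Tensor:
    """Plain reshape of a token sequence to B x D x Hp x Wp (no conv)."""
    b, n, d = seq.tokens.shape
    hp, wp = seq.grid
    return T.reshape(T.transpose(seq.tokens, (0, 2, 1)), (b, d, hp, wp))
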