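"""Conditional U-Net eps-predictor.

A DDPM-style U-Net predicts the injected noise from a noisy image, a
timestep, and the combined condition vector.  The timestep embedding
(sinusoidal followed by a two-layer MLP) and the condition vector share one
additive pathway: their sum is linearly projected per residual block and
added to the block's hidden activations, which realizes per-layer condition
injection across levels of different widths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .conditioning import ConditionBundle, EmbeddingTables, embed_bundles
from .nn import (Conv2d, GroupNorm, Linear, Module, Parameter,
                 SelfAttention2d, Tensor, avg_pool2d, concat, sinusoidal_embedding,
                 upsample_nearest)

__all__ = ["DenoiserConfig", "Denoiser", "build_denoiser", "predict_noise"]


@dataclass(frozen=True)
class DenoiserConfig:
    """Architecture hyperparameters.

    ``resolution`` must be divisible by ``2**(len(channel_multipliers)-1)``;
    each multiplier adds one resolution level.  ``attention_levels`` flags
    self-attention per level (innermost level = bottleneck).
    """

    resolution: int = 32
    base_channels: int = 32
    channel_multipliers: tuple[int, ...] = (1, 2)
    blocks_per_level: int = 1
    embedding_dim: int = 64
    attention_levels: tuple[bool, ...] | None = None

    def __post_init__(self):
        levels = len(self.channel_multipliers)
        if levels < 1:
            raise ValueError("need at least one channel multiplier")
        if self.resolution % (2 ** (levels - 1)) != 0:
            raise ValueError(
                f"resolution {self.resolution} not divisible by "
                f"2^{levels - 1} for {levels} levels")
        if self.embedding_dim <= 0:
            raise ValueError("embedding_dim must be positive")
        attn = self.attention_levels
        if attn is None:
            attn = tuple(i == levels - 1 for i in range(levels))
        elif len(attn) != levels:
            raise ValueError("attention_levels length must equal number of levels")
        object.__setattr__(self, "attention_levels", tuple(bool(a) for a in attn))
        object.__setattr__(self, "channel_multipliers",
                           tuple(int(m) for m in self.channel_multipliers))


class _ResBlock(Module):
    def __init__(self, c_in: int, c_out: int, emb_dim: int, rng: np.random.Generator):
        self.norm1 = GroupNorm(c_in)
        self.conv1 = Conv2d(c_in, c_out, 3, rng)
        self.emb_proj = Linear(emb_dim, c_out, rng)
        self.norm2 = GroupNorm(c_out)
        self.conv2 = Conv2d(c_out, c_out, 3, rng, zero_init=True)
        self.skip = Conv2d(c_in, c_out, 1, rng) if c_in != c_out else None

    def __call__(self, x: Tensor, emb: Tensor) -> Tensor:
        h = self.conv1(self.norm1(x).silu())
        b = emb.shape[0]
        h = h + self.emb_proj(emb.silu()).reshape(b, h.shape[1], 1, 1)
        h = self.conv2(self.norm2(h).silu())
        return h + (self.skip(x) if self.skip is not None else x)


class _UNet(Module):
    def __init__(self, config: DenoiserConfig, rng: np.random.Generator):
        cfg = config
        dim = cfg.embedding_dim
        self.config = cfg
        self.time_fc1 = Linear(dim, dim, rng)
        self.time_fc2 = Linear(dim, dim, rng)
        chans = [cfg.base_channels * m for m in cfg.channel_multipliers]
        self.conv_in = Conv2d(3, chans[0], 3, rng)

        self.down_blocks: list[Module] = []
        self.down_attn: list[Module | None] = []
        skip_chans = [chans[0]]
        c_prev = chans[0]
        for lvl, c in enumerate(chans):
            for _ in range(cfg.blocks_per_level):
                self.down_blocks.append(_ResBlock(c_prev, c, dim, rng))
                self.down_attn.append(SelfAttention2d(c, rng)
                                      if cfg.attention_levels[lvl] else None)
                skip_chans.append(c)
                c_prev = c
            if lvl < len(chans) - 1:
                skip_chans.append(c)  # skip recorded after each downsample too
        self._n_levels = len(chans)
        self._chans = chans

        self.mid1 = _ResBlock(c_prev, c_prev, dim, rng)
        self.mid_attn = SelfAttention2d(c_prev, rng)
        self.mid2 = _ResBlock(c_prev, c_prev, dim, rng)

        self.up_blocks: list[Module] = []
        self.up_attn: list[Module | None] = []
        for lvl in reversed(range(len(chans))):
            c = chans[lvl]
            for _ in range(cfg.blocks_per_level + 1):
                self.up_blocks.append(_ResBlock(c_prev + skip_chans.pop(), c, dim, rng))
                self.up_attn.append(SelfAttention2d(c, rng)
                                    if cfg.attention_levels[lvl] else None)
                c_prev = c
        self.norm_out = GroupNorm(chans[0])
        self.conv_out = Conv2d(chans[0], 3, 3, rng, zero_init=True)

    def __call__(self, x: Tensor, t: np.ndarray, cond: Tensor) -> Tensor:
        cfg = self.config
        temb = sinusoidal_embedding(t, cfg.embedding_dim)
        emb = self.time_fc2(self.time_fc1(Tensor(temb)).silu()) + cond

        h = self.conv_in(x)
        skips = [h]
        bi = 0
        for lvl in range(self._n_levels):
            for _ in range(cfg.blocks_per_level):
                h = self.down_blocks[bi](h, emb)
                if self.down_attn[bi] is not None:
                    h = self.down_attn[bi](h)
                skips.append(h)
                bi += 1
            if lvl < self._n_levels - 1:
                h = avg_pool2d(h, 2)
                skips.append(h)

        h = self.mid2(self.mid_attn(self.mid1(h, emb)), emb)

        bi = 0
        for lvl in reversed(range(self._n_levels)):
            for _ in range(cfg.blocks_per_level + 1):
                h = self.up_blocks[bi](concat([h, skips.pop()], axis=1), emb)
                if self.up_attn[bi] is not None:
                    h = self.up_attn[bi](h)
                bi += 1
            if lvl > 0:
                h = upsample_nearest(h, 2)
        return self.conv_out(self.norm_out(h).silu())


class Denoiser:
    """U-Net eps-predictor bundled with its condition-embedding tables."""

    def __init__(self, config: DenoiserConfig, unet: _UNet,
                 tables: EmbeddingTables):
        self.config = config
        self.unet = unet
        self.tables = tables

    @property
    def labels(self) -> list[str]:
        return self.tables.labels

    @property
    def genes(self) -> list[str]:
        return self.tables.genes

    @property
    def expression_genes(self) -> list[str]:
        return self.tables.expression_genes

    def params(self) -> dict[str, Parameter]:
        out = {f"unet.{k}": v for k, v in self.unet.params().items()}
        out.update({f"tables.{k}": v for k, v in self.tables.params().items()})
        return out

    def zero_grad(self) -> None:
        for p in self.params().values():
            p.zero_grad()

    def forward_batch(self, x: np.ndarray, t: np.ndarray,
                      bundles: list[ConditionBundle]) -> Tensor:
        """Graph-building forward pass on an NCHW float batch."""
        if x.ndim != 4 or x.shape[1] != 3 or x.shape[2] != x.shape[3] \
                or x.shape[2] != self.config.resolution:
            raise ValueError(f"expected (B, 3, {self.config.resolution}, "
                             f"{self.config.resolution}) input, got {x.shape}")
        cond = embed_bundles(bundles, self.tables)
        return self.unet(Tensor(x.astype(np.float32)), np.asarray(t), cond)


def build_denoiser(config: DenoiserConfig, labels: list[str], genes: list[str],
                   seed: int, expression_genes: list[str] | None = None,
                   ) -> Denoiser:
    """Initialize a denoiser; identical seeds give bit-identical parameters."""
    rng = np.random.default_rng(seed)
    tables = EmbeddingTables(labels, genes, config.embedding_dim, rng,
                             expression_genes=expression_genes)
    unet = _UNet(config, rng)
    return Denoiser(config, unet, tables)


def _hwc_to_nchw(x: np.ndarray) -> np.ndarray:
    return x.transpose(2, 0, 1)[None]


def predict_noise(model: Denoiser, x_t: np.ndarray, t: int,
                  bundle: ConditionBundle) -> np.ndarray:
    """Predict eps for one HxWx3 image in [-1, 1]; deterministic."""
    x_t = np.asarray(x_t, dtype=np.float32)
    if x_t.ndim != 3 or x_t.shape[2] != 3:
        raise ValueError(f"expected HxWx3 image, got shape {x_t.shape}")
    out = model.forward_batch(_hwc_to_nchw(x_t), np.array([t]), [bundle])
    eps = out.data[0].transpose(1, 2, 0)
    if not np.all(np.isfinite(eps)):
        raise FloatingPointError("denoiser produced non-finite output")
    return eps
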