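"""1D U-Net noise-prediction network.

Encoder-decoder over the time axis with residual blocks, optional
single-head self-attention per level, and skip connections that
concatenate encoder feature maps into the decoder.  Conditioning enters
in two ways: a sinusoidal timestep embedding (plus, in label mode, a
learned class embedding) is projected and added inside every residual
block; in signal mode the conditioning signal is concatenated
channel-wise with the sampling state and fused by a width-1 convolution
before the first encoder layer.

The network has two signal-shaped output branches: the noise prediction
eps and a variance-interpolation weight v squashed to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .diffusion import NoiseModelOutput
from .nn import (Conv1d, Embedding, GroupNorm, Linear, Module,
                 SelfAttention1d, Tensor, concat)

__all__ = ["UNetConfig", "UNet1d", "build_unet", "sinusoidal_embedding"]


@dataclass
class UNetConfig:
    length: int = 64
    in_channels: int = 1
    base_channels: int = 16
    channel_mults: tuple[int, ...] = (1, 2, 4)
    n_res_blocks_per_level: int = 1
    attention: tuple[bool, ...] | None = None   # default: deepest level only
    time_embed_dim: int = 64
    n_classes: int | None = None                # label mode
    cond_channels: int = 0                      # signal mode
    downsample: str = "stride"                  # "stride" | "maxpool"
    n_norm_groups: int = 8

    def __post_init__(self):
        n_levels = len(self.channel_mults)
        factor = 2 ** (n_levels - 1)
        if self.length % factor:
            raise ValueError(
                f"length {self.length} must be divisible by {factor} "
                f"(2^(n_levels-1) with {n_levels} levels)")
        if self.attention is None:
            self.attention = tuple(i == n_levels - 1 for i in range(n_levels))
        self.attention = tuple(bool(a) for a in self.attention)
        if len(self.attention) != n_levels:
            raise ValueError("attention flags must match number of levels")
        if self.time_embed_dim % 2:
            raise ValueError("time_embed_dim must be even")
        if self.n_classes is not None and self.cond_channels:
            raise ValueError("label and signal conditioning are mutually exclusive")
        if self.downsample not in ("stride", "maxpool"):
            raise ValueError("downsample must be 'stride' or 'maxpool'")

    @property
    def n_levels(self) -> int:
        return len(self.channel_mults)


def sinusoidal_embedding(t: np.ndarray, dim: int) -> np.ndarray:
    """Sinusoidal position embedding: [sin(t w_k), cos(t w_k)], k < dim/2."""
    if dim % 2:
        raise ValueError("embedding dimension must be even")
    t = np.atleast_1d(np.asarray(t, dtype=np.float64))
    half = dim // 2
    freqs = np.exp(-np.log(10_000.0) * np.arange(half) / max(half - 1, 1))
    angles = t[:, None] * freqs[None, :]
    return np.concatenate([np.sin(angles), np.cos(angles)], axis=1)


class _ResBlock(Module):
    def __init__(self, in_ch: int, out_ch: int, temb_dim: int,
                 rng: np.random.Generator, groups: int):
        g_in = min(groups, in_ch)
        g_out = min(groups, out_ch)
        self.norm1 = GroupNorm(g_in, in_ch)
        self.conv1 = Conv1d(in_ch, out_ch, 3, rng, padding=1)
        self.temb_proj = Linear(temb_dim, out_ch, rng)
        self.norm2 = GroupNorm(g_out, out_ch)
        self.conv2 = Conv1d(out_ch, out_ch, 3, rng, padding=1)
        self.skip = Conv1d(in_ch, out_ch, 1, rng) if in_ch != out_ch else None

    def __call__(self, x: Tensor, temb: Tensor) -> Tensor:
        h = self.conv1(self.norm1(x).silu())
        B, C, L = h.shape
        h = h + self.temb_proj(temb.silu()).reshape(B, C, 1)
        h = self.conv2(self.norm2(h).silu())
        s = x if self.skip is None else self.skip(x)
        return s + h


class _Downsample(Module):
    def __init__(self, channels: int, rng: np.random.Generator, kind: str):
        self.kind = kind
        self.conv = Conv1d(channels, channels, 3, rng, stride=2, padding=1) \
            if kind == "stride" else None

    def __call__(self, x: Tensor) -> Tensor:
        return self.conv(x) if self.conv is not None else x.maxpool1d(2)


class _Upsample(Module):
    def __init__(self, channels: int, rng: np.random.Generator):
        self.conv = Conv1d(channels, channels, 3, rng, padding=1)

    def __call__(self, x: Tensor) -> Tensor:
        return self.conv(x.upsample_nearest(2))


class UNet1d(Module):
    def __init__(self, config: UNetConfig, rng: np.random.Generator):
        self.config = config
        self.length = config.length
        self.in_channels = config.in_channels
        ch = config.base_channels
        tdim = config.time_embed_dim
        groups = config.n_norm_groups

        self.time_mlp = [Linear(tdim, tdim, rng), Linear(tdim, tdim, rng)]
        self.label_emb = (Embedding(config.n_classes, tdim, rng)
                          if config.n_classes is not None else None)
        self.cond_fuse = (Conv1d(config.in_channels + config.cond_channels,
                                 config.in_channels, 1, rng)
                          if config.cond_channels else None)

        self.stem = Conv1d(config.in_channels, ch, 3, rng, padding=1)

        chans = [ch * m for m in config.channel_mults]
        self.enc_blocks: list = []
        self.enc_attn: list = []
        self.downs: list = []
        cur = ch
        for level, (c_out, attn) in enumerate(zip(chans, config.attention)):
            blocks = []
            attns = []
            for b in range(config.n_res_blocks_per_level):
                blocks.append(_ResBlock(cur, c_out, tdim, rng, groups))
                cur = c_out
                attns.append(SelfAttention1d(cur, rng, groups) if attn else None)
            self.enc_blocks.append(blocks)
            self.enc_attn.append(attns)
            if level < config.n_levels - 1:
                self.downs.append(_Downsample(cur, rng, config.downsample))

        self.mid1 = _ResBlock(cur, cur, tdim, rng, groups)
        self.mid_attn = SelfAttention1d(cur, rng, groups)
        self.mid2 = _ResBlock(cur, cur, tdim, rng, groups)

        self.ups: list = []
        self.dec_blocks: list = []
        self.dec_attn: list = []
        for level in reversed(range(config.n_levels)):
            c_out = chans[level]
            attn = config.attention[level]
            if level < config.n_levels - 1:
                self.ups.append(_Upsample(cur, rng))
            blocks = []
            attns = []
            skip_ch = chans[level]  # concatenated encoder feature map
            for b in range(config.n_res_blocks_per_level):
                in_ch = cur + skip_ch if b == 0 else cur
                blocks.append(_ResBlock(in_ch, c_out, tdim, rng, groups))
                cur = c_out
                attns.append(SelfAttention1d(cur, rng, groups) if attn else None)
            self.dec_blocks.append(blocks)
            self.dec_attn.append(attns)

        self.out_norm = GroupNorm(min(groups, cur), cur)
        self.head_eps = Conv1d(cur, config.in_channels, 3, rng, padding=1)
        self.head_v = Conv1d(cur, config.in_channels, 3, rng, padding=1)

    # ------------------------------------------------------------------ forward
    def __call__(self, xt: np.ndarray | Tensor, t: np.ndarray,
                 condition: dict | None = None) -> NoiseModelOutput:
        cfg = self.config
        x = xt if isinstance(xt, Tensor) else Tensor(np.asarray(xt, dtype=np.float64))
        B = x.shape[0]
        if x.shape[-1] != cfg.length:
            raise ValueError(f"input length {x.shape[-1]} != model length {cfg.length}")
        condition = condition or {}

        temb = Tensor(sinusoidal_embedding(np.asarray(t, dtype=np.float64), cfg.time_embed_dim))
        temb = self.time_mlp[1](self.time_mlp[0](temb).silu())
        if self.label_emb is not None:
            if "label" not in condition:
                raise ValueError("label-conditional model requires condition['label']")
            temb = temb + self.label_emb(np.asarray(condition["label"]))
        elif "label" in condition:
            raise ValueError("model was not built for label conditioning")

        if self.cond_fuse is not None:
            if "signal" not in condition:
                raise ValueError("signal-conditional model requires condition['signal']")
            cond = condition["signal"]
            cond = cond if isinstance(cond, Tensor) else Tensor(np.asarray(cond, dtype=np.float64))
            if cond.shape[-1] != cfg.length:
                raise ValueError(
                    f"conditioning length {cond.shape[-1]} != model length {cfg.length}")
            x = self.cond_fuse(concat([x, cond], axis=1))
        elif "signal" in condition:
            raise ValueError("model was not built for signal conditioning")

        h = self.stem(x)
        skips: list[Tensor] = []
        for level in range(cfg.n_levels):
            for block, attn in zip(self.enc_blocks[level], self.enc_attn[level]):
                h = block(h, temb)
                if attn is not None:
                    h = attn(h)
            skips.append(h)
            if level < cfg.n_levels - 1:
                h = self.downs[level](h)

        h = self.mid2(self.mid_attn(self.mid1(h, temb)), temb)

        up_i = 0
        for di, level in enumerate(reversed(range(cfg.n_levels))):
            if level < cfg.n_levels - 1:
                h = self.ups[up_i](h)
                up_i += 1
            h = concat([h, skips[level]], axis=1)
            for block, attn in zip(self.dec_blocks[di], self.dec_attn[di]):
                h = block(h, temb)
                if attn is not None:
                    h = attn(h)

        h = self.out_norm(h).silu()
        eps = self.head_eps(h)
        v = self.head_v(h).sigmoid()
        return NoiseModelOutput(eps_pred=eps, v_pred=v)


def build_unet(config: UNetConfig, seed: int = 0) -> UNet1d:
    """Construct a U-Net with parameters drawn from ``seed`` (deterministic)."""
    return UNet1d(config, np.random.default_rng(seed))
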