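"""Conditional denoiser backbone: a small U-net whose attention positions are
occupied by shifted-window transformer blocks.

The network maps ``(x_t, y, t)`` to an estimate of the clean slice.  ``x_t``
and ``y`` enter as two channels; the integer step ``t`` enters through a
sinusoidal embedding added to the feature maps inside every residual block.
A zero-initialised head plus a global skip from ``y`` make the untrained
network the identity on ``y``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor, concat, upsample_nearest2x
from .layers import Conv2d, GroupNorm, Linear, Module, timestep_embedding
from .swin import SwinBlock

__all__ = ["DenoiserConfig", "Denoiser", "build_denoiser", "denoise"]


@dataclass(frozen=True)
class DenoiserConfig:
    base_channels: int = 8
    channel_multipliers: tuple[int, ...] = (1, 2)
    swin_window: int = 4
    swin_heads: int = 2
    time_embed_dim: int = 32
    levels_with_swin: frozenset[int] = field(default_factory=lambda: frozenset({1}))

    def validate(self, image_side: int | None = None) -> None:
        levels = len(self.channel_multipliers)
        if levels < 1:
            raise ValueError("need at least one level")
        for lvl in self.levels_with_swin:
            if not 0 <= lvl < levels:
                raise ValueError(f"swin level {lvl} out of range")
        if image_side is not None:
            if image_side % (2 ** (levels - 1)):
                raise ValueError(
                    f"image side {image_side} not divisible by 2^{levels - 1}"
                )
            for lvl in self.levels_with_swin:
                side = image_side // (2**lvl)
                if side % self.swin_window:
                    raise ValueError(
                        f"window {self.swin_window} does not divide side {side} "
                        f"at level {lvl}"
                    )

    def to_dict(self) -> dict:
        return {
            "base_channels": self.base_channels,
            "channel_multipliers": list(self.channel_multipliers),
            "swin_window": self.swin_window,
            "swin_heads": self.swin_heads,
            "time_embed_dim": self.time_embed_dim,
            "levels_with_swin": sorted(self.levels_with_swin),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DenoiserConfig":
        return cls(
            base_channels=int(d["base_channels"]),
            channel_multipliers=tuple(d["channel_multipliers"]),
            swin_window=int(d["swin_window"]),
            swin_heads=int(d["swin_heads"]),
            time_embed_dim=int(d["time_embed_dim"]),
            levels_with_swin=frozenset(d["levels_with_swin"]),
        )


def _groups(c: int) -> int:
    g = min(8, c)
    while c % g:
        g -= 1
    return g


class ResBlock(Module):
    def __init__(self, c_in: int, c_out: int, temb_dim: int, rng: np.random.Generator):
        self.norm1 = GroupNorm(_groups(c_in), c_in)
        self.conv1 = Conv2d(c_in, c_out, 3, rng)
        self.temb_proj = Linear(temb_dim, c_out, rng)
        self.norm2 = GroupNorm(_groups(c_out), c_out)
        self.conv2 = Conv2d(c_out, c_out, 3, rng, zero_init=True)
        self.skip = Conv2d(c_in, c_out, 1, rng, padding=0) if c_in != c_out else None

    def __call__(self, x: Tensor, temb: Tensor) -> Tensor:
        h = self.conv1(self.norm1(x).silu())
        B = h.shape[0]
        h = h + self.temb_proj(temb).reshape(B, h.shape[1], 1, 1)
        h = self.conv2(self.norm2(h).silu())
        s = self.skip(x) if self.skip is not None else x
        return s + h


class Denoiser(Module):
    """f(x_t, y, t) -> x0_hat, same spatial shape as its inputs."""

    def __init__(self, cfg: DenoiserConfig, rng_seed: int):
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(rng_seed)
        ch = [cfg.base_channels * m for m in cfg.channel_multipliers]
        td = cfg.time_embed_dim
        self.t_fc1 = Linear(td, td, rng)
        self.t_fc2 = Linear(td, td, rng)
        self.stem = Conv2d(2, ch[0], 3, rng)

        self.down_res: list[ResBlock] = []
        self.down_swin: list[SwinBlock | None] = []
        self.downsamplers: list[Conv2d] = []
        prev = ch[0]
        for lvl, c in enumerate(ch):
            self.down_res.append(ResBlock(prev, c, td, rng))
            self.down_swin.append(
                SwinBlock(c, cfg.swin_window, cfg.swin_heads, rng)
                if lvl in cfg.levels_with_swin
                else None
            )
            if lvl < len(ch) - 1:
                self.downsamplers.append(Conv2d(c, ch[lvl + 1], 3, rng, stride=2))
                prev = ch[lvl + 1]

        cb = ch[-1]
        self.mid_res1 = ResBlock(cb, cb, td, rng)
        self.mid_swin = SwinBlock(cb, cfg.swin_window, cfg.swin_heads, rng)
        self.mid_swin_shifted = SwinBlock(cb, cfg.swin_window, cfg.swin_heads, rng, shift=True)
        self.mid_res2 = ResBlock(cb, cb, td, rng)

        self.up_convs: list[Conv2d] = []
        self.up_res: list[ResBlock] = []
        self.up_swin: list[SwinBlock | None] = []
        for lvl in range(len(ch) - 2, -1, -1):
            self.up_convs.append(Conv2d(ch[lvl + 1], ch[lvl], 3, rng))
            self.up_res.append(ResBlock(2 * ch[lvl], ch[lvl], td, rng))
            self.up_swin.append(
                SwinBlock(ch[lvl], cfg.swin_window, cfg.swin_heads, rng)
                if lvl in cfg.levels_with_swin
                else None
            )

        self.out_norm = GroupNorm(_groups(ch[0]), ch[0])
        self.head = Conv2d(ch[0], 1, 3, rng, zero_init=True)

    # -- shape plumbing -----------------------------------------------------
    @staticmethod
    def _batched(a: np.ndarray) -> tuple[np.ndarray, bool]:
        a = np.asarray(a, dtype=np.float64)
        if a.ndim == 2:
            return a[None], True
        if a.ndim == 3:
            return a, False
        raise ValueError(f"expected (H, W) or (B, H, W), got shape {a.shape}")

    def forward(self, x_t: np.ndarray, y: np.ndarray, t) -> Tensor:
        """Differentiable forward pass; returns a (B, H, W) tensor."""
        x_t, _ = self._batched(x_t)
        y, _ = self._batched(y)
        if x_t.shape != y.shape:
            raise ValueError("x_t and y must share shape")
        B, H, W = x_t.shape
        self.cfg.validate(image_side=max(H, W))
        t = np.broadcast_to(np.asarray(t, dtype=np.int64).ravel(), (B,))
        temb = Tensor(timestep_embedding(t, self.cfg.time_embed_dim))
        temb = self.t_fc2(self.t_fc1(temb).silu())

        h = self.stem(Tensor(np.stack([x_t, y], axis=1)))
        skips: list[Tensor] = []
        for lvl, (res, swin) in enumerate(zip(self.down_res, self.down_swin)):
            h = res(h, temb)
            if swin is not None:
                h = swin(h)
            skips.append(h)
            if lvl < len(self.downsamplers):
                h = self.downsamplers[lvl](h)

        h = self.mid_res1(h, temb)
        h = self.mid_swin_shifted(self.mid_swin(h))
        h = self.mid_res2(h, temb)

        for i, (up, res, swin) in enumerate(zip(self.up_convs, self.up_res, self.up_swin)):
            h = up(upsample_nearest2x(h))
            h = res(concat([h, skips[-(i + 2)]], axis=1), temb)
            if swin is not None:
                h = swin(h)

        out = self.head(self.out_norm(h).silu())  # (B, 1, H, W)
        return out.reshape(B, H, W) + Tensor(y)

    def __call__(self, x_t: np.ndarray, y: np.ndarray, t) -> np.ndarray:
        """Evaluation-mode denoise: plain array in, plain array out."""
        _, squeeze = self._batched(x_t)
        out = self.forward(x_t, y, t).data
        return out[0] if squeeze else out


def build_denoiser(cfg: DenoiserConfig, rng_seed: int) -> Denoiser:
    return Denoiser(cfg, rng_seed)


def denoise(model: Denoiser, x_t: np.ndarray, y: np.ndarray, t: int) -> np.ndarray:
    """Evaluate f(x_t, y, t) deterministically (no parameter updates)."""
    if int(t) < 1:
        raise ValueError(f"step t={t} must be >= 1")
    return model(x_t, y, int(t))
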