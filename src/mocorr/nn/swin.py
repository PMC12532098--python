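"""Shifted-window transformer block used in place of attention layers."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, roll2d
from .layers import LayerNorm, Linear, Module, softmax

__all__ = ["SwinBlock"]

_NEG = -1e9


def _shift_mask(H: int, W: int, window: int, shift: int) -> np.ndarray:
    """Attention mask for cyclically shifted windows: tokens originating from
    different image regions must not attend to each other.
    Returns (n_windows, window*window, window*window) additive mask."""
    img = np.zeros((H, W), dtype=np.int64)
    cnt = 0
    slices = (slice(0, -window), slice(-window, -shift), slice(-shift, None))
    for hs in slices:
        for ws in slices:
            img[hs, ws] = cnt
            cnt += 1
    nh, nw = H // window, W // window
    ids = (
        img.reshape(nh, window, nw, window)
        .transpose(0, 2, 1, 3)
        .reshape(nh * nw, window * window)
    )
    diff = ids[:, :, None] != ids[:, None, :]
    return np.where(diff, _NEG, 0.0)


class SwinBlock(Module):
    """Windowed multi-head self-attention + MLP with pre-norm residuals.

    Operates on NCHW feature maps whose spatial side is divisible by
    ``window``.  With ``shift=True`` windows are cyclically shifted by half a
    window, with the standard region mask.
    """

    def __init__(self, dim: int, window: int, heads: int, rng: np.random.Generator, shift: bool = False):
        if dim % heads:
            raise ValueError("dim must be divisible by heads")
        self.dim = dim
        self.window = window
        self.heads = heads
        self.shift = window // 2 if shift else 0
        self.norm1 = LayerNorm(dim)
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)
        self.norm2 = LayerNorm(dim)
        self.fc1 = Linear(dim, 2 * dim, rng)
        self.fc2 = Linear(2 * dim, dim, rng, zero_init=True)

    def _attend(self, tokens: Tensor, n_windows: int, mask: np.ndarray | None) -> Tensor:
        Bw, S, C = tokens.shape
        hd = C // self.heads
        qkv = self.qkv(tokens).reshape(Bw, S, 3, self.heads, hd).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]  # (Bw, heads, S, hd)
        attn = (q @ k.transpose(0, 1, 3, 2)) * (hd**-0.5)
        if mask is not None:
            B = Bw // n_windows
            attn = attn.reshape(B, n_windows, self.heads, S, S) + Tensor(mask[:, None])
            attn = attn.reshape(Bw, self.heads, S, S)
        out = softmax(attn) @ v  # (Bw, heads, S, hd)
        out = out.transpose(0, 2, 1, 3).reshape(Bw, S, C)
        return self.proj(out)

    def __call__(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        w = self.window
        if H % w or W % w:
            raise ValueError(f"feature side ({H},{W}) not divisible by window {w}")
        t = x.transpose(0, 2, 3, 1)  # NHWC
        if self.shift:
            t = roll2d(t, (-self.shift, -self.shift), axes=(1, 2))
        nh, nw = H // w, W // w
        tokens = (
            t.reshape(B, nh, w, nw, w, C)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(B * nh * nw, w * w, C)
        )
        mask = _shift_mask(H, W, w, self.shift) if self.shift else None
        tokens = tokens + self._attend(self.norm1(tokens), nh * nw, mask)
        tokens = tokens + self.fc2(self.fc1(self.norm2(tokens)).silu())
        t = (
            tokens.reshape(B, nh, nw, w, w, C)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(B, H, W, C)
        )
        if self.shift:
            t = roll2d(t, (self.shift, self.shift), axes=(1, 2))
        return t.transpose(0, 3, 1, 2)
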