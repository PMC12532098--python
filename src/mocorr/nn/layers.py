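"""Building blocks for the denoiser: modules, norms, linear/conv layers and
the sinusoidal step embedding."""

from __future__ import annotations

import math

import numpy as np

from .autograd import DTYPE, Parameter, Tensor, conv2d

__all__ = [
    "Module",
    "Linear",
    "Conv2d",
    "GroupNorm",
    "LayerNorm",
    "softmax",
    "timestep_embedding",
]


class Module:
    """Parameter container with recursive collection, torch-style."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()
        stack: list[object] = [self]
        while stack:
            obj = stack.pop()
            for v in vars(obj).values():
                if isinstance(v, Parameter) and id(v) not in seen:
                    seen.add(id(v))
                    params.append(v)
                elif isinstance(v, Module):
                    stack.append(v)
                elif isinstance(v, (list, tuple)):
                    stack.extend(m for m in v if isinstance(m, Module))
        return params

    def state_dict(self) -> dict[str, np.ndarray]:
        return {str(i): p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError(
                f"checkpoint has {len(state)} arrays, model has {len(params)}"
            )
        for i, p in enumerate(params):
            arr = np.asarray(state[str(i)])
            if arr.shape != p.data.shape:
                raise ValueError(f"parameter {i}: shape {arr.shape} != {p.data.shape}")
            p.data = arr.astype(DTYPE)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, zero_init: bool = False):
        if zero_init:
            w = np.zeros((n_in, n_out))
        else:
            w = rng.normal(0.0, math.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.w = Parameter(w)
        self.b = Parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Conv2d(Module):
    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        rng: np.random.Generator,
        stride: int = 1,
        padding: int | None = None,
        zero_init: bool = False,
    ):
        fan_in = c_in * kernel * kernel
        if zero_init:
            w = np.zeros((c_out, c_in, kernel, kernel))
        else:
            w = rng.normal(0.0, math.sqrt(2.0 / fan_in), size=(c_out, c_in, kernel, kernel))
        self.w = Parameter(w)
        self.b = Parameter(np.zeros(c_out))
        self.stride = stride
        self.padding = kernel // 2 if padding is None else padding

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, stride=self.stride, padding=self.padding)


class GroupNorm(Module):
    def __init__(self, n_groups: int, n_channels: int, eps: float = 1e-5):
        if n_channels % n_groups:
            raise ValueError("channels must divide into groups")
        self.n_groups = n_groups
        self.eps = eps
        self.weight = Parameter(np.ones((1, n_channels, 1, 1)))
        self.bias = Parameter(np.zeros((1, n_channels, 1, 1)))

    def __call__(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        g = x.reshape(B, self.n_groups, (C // self.n_groups) * H * W)
        m = g.mean(axis=2, keepdims=True)
        v = ((g - m) * (g - m)).mean(axis=2, keepdims=True)
        norm = ((g - m) * (v + self.eps) ** -0.5).reshape(B, C, H, W)
        return norm * self.weight + self.bias


class LayerNorm(Module):
    """Normalisation over the trailing (channel) axis of token tensors."""

    def __init__(self, dim: int, eps: float = 1e-5):
        self.eps = eps
        self.weight = Parameter(np.ones(dim))
        self.bias = Parameter(np.zeros(dim))

    def __call__(self, x: Tensor) -> Tensor:
        m = x.mean(axis=-1, keepdims=True)
        v = ((x - m) * (x - m)).mean(axis=-1, keepdims=True)
        return (x - m) * (v + self.eps) ** -0.5 * self.weight + self.bias


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - x.data.max(axis=axis, keepdims=True)  # max is constant wrt grad
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def timestep_embedding(t: np.ndarray, dim: int, max_period: float = 10000.0) -> np.ndarray:
    """Sinusoidal embedding of integer steps; shape (len(t), dim)."""
    t = np.atleast_1d(np.asarray(t, dtype=np.float64))
    half = dim // 2
    freqs = np.exp(-math.log(max_period) * np.arange(half) / half)
    args = t[:, None] * freqs[None, :]
    emb = np.concatenate([np.cos(args), np.sin(args)], axis=1)
    if dim % 2:
        emb = np.concatenate([emb, np.zeros((len(t), 1))], axis=1)
    return emb
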