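"""Synthetic brain-like 2-D phantoms and paired desk-scale datasets.

Each phantom is a head-shaped ellipse with a bright closed rim just inside
its boundary (mimicking subcutaneous fat, so ghost copies land visibly
outside the head), internal ellipses and smooth texture standing in for
soft-tissue structure.  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .diffusion import PairedSample
from .simulate import SeverityPreset, corrupt

__all__ = ["PhantomSpec", "DatasetSplit", "make_phantom", "phantom_masks", "build_dataset"]


@dataclass(frozen=True)
class PhantomSpec:
    size: int = 64
    n_inner_ellipses: int = 4
    rim_intensity: float = 0.95
    texture_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size < 32 or self.size % 4:
            raise ValueError("size must be >= 32 and divisible by 4")
        if not 0.0 < self.rim_intensity <= 1.0:
            raise ValueError("rim_intensity must be in (0, 1]")


def _ellipse_mask(size: int, cy: float, cx: float, ay: float, ax: float, angle: float = 0.0) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    y, x = yy - cy, xx - cx
    c, s = np.cos(angle), np.sin(angle)
    u = c * y + s * x
    v = -s * y + c * x
    return (u / ay) ** 2 + (v / ax) ** 2 <= 1.0


def _geometry(spec: PhantomSpec, rng: np.random.Generator):
    n = spec.size
    c = n / 2.0
    ay = n * rng.uniform(0.36, 0.42)
    ax = n * rng.uniform(0.30, 0.36)
    head = _ellipse_mask(n, c, c, ay, ax)
    inner = _ellipse_mask(n, c, c, ay - max(2.0, 0.05 * n), ax - max(2.0, 0.05 * n))
    rim = head & ~inner
    return head, rim, inner


def phantom_masks(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(head, rim, interior) boolean masks for the phantom of ``spec``."""
    rng = np.random.default_rng(spec.seed)
    return _geometry(spec, rng)


def make_phantom(spec: PhantomSpec) -> np.ndarray:
    """Render one phantom slice with values in [0, 1]."""
    rng = np.random.default_rng(spec.seed)
    head, rim, inner = _geometry(spec, rng)
    n = spec.size

    img = np.zeros((n, n), dtype=np.float64)
    img[inner] = 0.35
    for _ in range(spec.n_inner_ellipses):
        cy = rng.uniform(0.3, 0.7) * n
        cx = rng.uniform(0.3, 0.7) * n
        ey = rng.uniform(0.04, 0.15) * n
        ex = rng.uniform(0.04, 0.15) * n
        ang = rng.uniform(0.0, np.pi)
        level = rng.uniform(0.15, 0.8)
        blob = _ellipse_mask(n, cy, cx, ey, ex, ang) & inner
        img[blob] = level
    if spec.texture_sigma > 0:
        tex = ndimage.gaussian_filter(rng.standard_normal((n, n)), spec.texture_sigma)
        img[inner] += 0.08 * tex[inner] / max(1e-12, np.abs(tex).max())
    img[rim] = spec.rim_intensity
    return np.clip(img, 0.0, 1.0)


@dataclass
class DatasetSplit:
    """Deterministic train/val/test partition of paired samples."""

    train: list[PairedSample] = field(default_factory=list)
    val: list[PairedSample] = field(default_factory=list)
    test: list[PairedSample] = field(default_factory=list)

    @property
    def all(self) -> list[PairedSample]:
        return self.train + self.val + self.test

    def __len__(self) -> int:
        return len(self.train) + len(self.val) + len(self.test)


def build_dataset(
    n: int,
    spec: PhantomSpec,
    preset: SeverityPreset,
    seed: int,
    split: tuple[float, float, float] = (0.8, 0.1, 0.1),
    noise_sigma: float = 0.0,
) -> DatasetSplit:
    """n independent phantoms, each corrupted once with an independent
    sub-seed, partitioned into train/val/test by ``split`` ratios."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if abs(sum(split) - 1.0) > 1e-9:
        raise ValueError("split ratios must sum to 1")
    children = np.random.SeedSequence(seed).spawn(n)
    samples: list[PairedSample] = []
    for child in children:
        s1, s2 = child.spawn(2)
        p_seed = int(s1.generate_state(1)[0])
        c_seed = int(s2.generate_state(1)[0])
        img = make_phantom(replace(spec, seed=p_seed))
        samples.append(corrupt(img, preset, c_seed, noise_sigma=noise_sigma))
    n_train = int(round(split[0] * n))
    n_val = int(round(split[1] * n))
    n_train = min(n_train, n)
    n_val = min(n_val, n - n_train)
    return DatasetSplit(
        train=samples[:n_train],
        val=samples[n_train : n_train + n_val],
        test=samples[n_train + n_val :],
    )
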