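"""Image-quality metrics (PSNR, SSIM, NMSE, pooled Pearson r) and mean/std
report aggregation.

Conventions: images are evaluated whole (no brain mask) at a declared data
range (1.0 for normalized slices); NMSE is reported in percent; aggregation
uses the population standard deviation (n divisor).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = ["MetricsReport", "psnr", "ssim", "nmse", "pearson_r", "evaluate_dataset"]

PSNR_CAP_DB = 100.0  # sentinel for identical inputs (MSE = 0)

SSIM_WINDOW = 11
SSIM_SIGMA = 1.5
SSIM_K1 = 0.01
SSIM_K2 = 0.03


def _check_pair(ref, est) -> tuple[np.ndarray, np.ndarray]:
    ref = np.asarray(ref, dtype=np.float64)
    est = np.asarray(est, dtype=np.float64)
    if ref.shape != est.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {est.shape}")
    return ref, est


def psnr(ref, est, data_range: float = 1.0) -> float:
    """10 log10(range^2 / MSE), capped at ``PSNR_CAP_DB`` for identical input."""
    ref, est = _check_pair(ref, est)
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    mse = float(np.mean((ref - est) ** 2))
    if mse == 0.0:
        return PSNR_CAP_DB
    return min(PSNR_CAP_DB, 10.0 * np.log10(data_range**2 / mse))


def _gaussian_kernel(size: int, sigma: float) -> np.ndarray:
    ax = np.arange(size, dtype=np.float64) - (size - 1) / 2.0
    g = np.exp(-0.5 * (ax / sigma) ** 2)
    k = np.outer(g, g)
    return k / k.sum()


def ssim(ref, est, data_range: float = 1.0) -> float:
    """Mean local SSIM with an 11x11 Gaussian window, sigma 1.5,
    K1 = 0.01, K2 = 0.03 (the usual evaluation-library defaults).

    Windows are fully interior ('valid' correlation), matching reference
    implementations that crop the window radius from each border.
    """
    ref, est = _check_pair(ref, est)
    if min(ref.shape) < SSIM_WINDOW:
        raise ValueError(f"image smaller than the {SSIM_WINDOW}x{SSIM_WINDOW} window")
    kern = _gaussian_kernel(SSIM_WINDOW, SSIM_SIGMA)

    def filt(a: np.ndarray) -> np.ndarray:
        out = ndimage.correlate(a, kern, mode="constant")
        r = SSIM_WINDOW // 2
        return out[r:-r, r:-r]

    mu_x = filt(ref)
    mu_y = filt(est)
    sxx = filt(ref * ref) - mu_x * mu_x
    syy = filt(est * est) - mu_y * mu_y
    sxy = filt(ref * est) - mu_x * mu_y
    c1 = (SSIM_K1 * data_range) ** 2
    c2 = (SSIM_K2 * data_range) ** 2
    num = (2 * mu_x * mu_y + c1) * (2 * sxy + c2)
    den = (mu_x**2 + mu_y**2 + c1) * (sxx + syy + c2)
    return float(np.mean(num / den))


def nmse(ref, est) -> float:
    """100 * ||est - ref||^2 / ||ref||^2 (percent)."""
    ref, est = _check_pair(ref, est)
    energy = float(np.sum(ref**2))
    if energy == 0.0:
        raise ValueError("NMSE undefined for an all-zero reference")
    return 100.0 * float(np.sum((est - ref) ** 2)) / energy


def pearson_r(refs: Sequence[np.ndarray], ests: Sequence[np.ndarray]) -> float:
    """Pearson correlation pooled over all pixels of all slices jointly."""
    a = np.concatenate([np.asarray(r, dtype=np.float64).ravel() for r in refs])
    b = np.concatenate([np.asarray(e, dtype=np.float64).ravel() for e in ests])
    if a.shape != b.shape:
        raise ValueError("refs and ests must cover the same pixels")
    return float(np.corrcoef(a, b)[0, 1])


@dataclass(frozen=True)
class MetricsReport:
    """Per-slice metrics aggregated as mean and population std."""

    psnr_mean: float
    psnr_std: float
    ssim_mean: float
    ssim_std: float
    nmse_mean: float
    nmse_std: float
    pearson: float
    n_slices: int

    def to_dict(self) -> dict:
        return {
            "psnr_db": {"mean": self.psnr_mean, "std": self.psnr_std},
            "ssim": {"mean": self.ssim_mean, "std": self.ssim_std},
            "nmse_percent": {"mean": self.nmse_mean, "std": self.nmse_std},
            "pearson_r": self.pearson,
            "n_slices": self.n_slices,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "MetricsReport":
        return cls(
            psnr_mean=d["psnr_db"]["mean"],
            psnr_std=d["psnr_db"]["std"],
            ssim_mean=d["ssim"]["mean"],
            ssim_std=d["ssim"]["std"],
            nmse_mean=d["nmse_percent"]["mean"],
            nmse_std=d["nmse_percent"]["std"],
            pearson=d["pearson_r"],
            n_slices=d["n_slices"],
        )


def evaluate_dataset(
    pairs: Sequence[tuple[np.ndarray, np.ndarray]],
    data_range: float = 1.0,
) -> MetricsReport:
    """Aggregate per-slice PSNR/SSIM/NMSE over (ref, est) pairs."""
    if len(pairs) == 0:
        raise ValueError("need at least one (ref, est) pair")
    ps = np.array([psnr(r, e, data_range) for r, e in pairs])
    ss = np.array([ssim(r, e, data_range) for r, e in pairs])
    ns = np.array([nmse(r, e) for r, e in pairs])
    rho = pearson_r([r for r, _ in pairs], [e for _, e in pairs])
    return MetricsReport(
        psnr_mean=float(ps.mean()),
        psnr_std=float(ps.std()),
        ssim_mean=float(ss.mean()),
        ssim_std=float(ss.std()),
        nmse_mean=float(ns.mean()),
        nmse_std=float(ns.std()),
        pearson=rho,
        n_slices=len(pairs),
    )
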