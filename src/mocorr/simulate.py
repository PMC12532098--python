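"""In-silico rigid-motion corruption of MRI slices.

Random slabs of phase-encode lines in the slice's k-space are replaced by
the corresponding lines from rigidly transformed copies of the image (one
independent transform per slab), emulating a subject that moves between
acquisitions of those lines.  This produces the two classic artifact
families: in-plane ringing and ghost copies of bright rim structures along
the phase-encode direction.

Conventions: the phase-encode axis is array axis 0 (rows); k-space is stored
centred (zero frequency at the matrix centre); the DFT pair is orthonormal so
image and spectrum carry equal energy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .diffusion import PairedSample

__all__ = [
    "MotionEvent",
    "SeverityPreset",
    "KSpaceMatrix",
    "PRESETS",
    "to_kspace",
    "from_kspace",
    "apply_rigid",
    "draw_slabs",
    "draw_motion_event",
    "corrupt",
]

logger = logging.getLogger(__name__)

DEFAULT_ROT_BOUND = 7.0  # degrees
DEFAULT_TRANS_BOUND = 5.0  # mm
DEFAULT_WIDTH_RANGE = (3, 7)  # k-space lines per slab


@dataclass(frozen=True)
class MotionEvent:
    """One rigid-motion state applied to one slab of phase-encode lines."""

    rotation: float  # degrees, about the image centre
    shift_x: float  # mm, along array axis 1
    shift_y: float  # mm, along array axis 0
    slab_start: int  # first phase-encode line of the slab
    slab_width: int  # number of lines

    def to_dict(self) -> dict:
        return {
            "rotation_deg": self.rotation,
            "shift_x_mm": self.shift_x,
            "shift_y_mm": self.shift_y,
            "slab_start": self.slab_start,
            "slab_width": self.slab_width,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MotionEvent":
        return cls(
            rotation=float(d["rotation_deg"]),
            shift_x=float(d["shift_x_mm"]),
            shift_y=float(d["shift_y_mm"]),
            slab_start=int(d["slab_start"]),
            slab_width=int(d["slab_width"]),
        )


@dataclass(frozen=True)
class SeverityPreset:
    """Simulator configuration for one distortion level."""

    name: str
    n_lines: int
    slab_width_range: tuple[int, int] = DEFAULT_WIDTH_RANGE
    rot_bound: float = DEFAULT_ROT_BOUND
    trans_bound: float = DEFAULT_TRANS_BOUND
    center_exclusion: int = 0  # radius of central lines kept pristine

    def __post_init__(self) -> None:
        lo, hi = self.slab_width_range
        if not (0 < lo <= hi):
            raise ValueError("invalid slab width range")
        if self.n_lines < 0 or self.rot_bound < 0 or self.trans_bound < 0:
            raise ValueError("n_lines and bounds must be non-negative")


PRESETS: dict[str, SeverityPreset] = {
    "minor": SeverityPreset("minor", n_lines=7),
    "moderate": SeverityPreset("moderate", n_lines=10),
    "heavy": SeverityPreset("heavy", n_lines=15),
}


@dataclass(frozen=True)
class KSpaceMatrix:
    """Centred complex spectrum of a slice."""

    data: np.ndarray
    pe_axis: int = 0
    spacing: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.data)):
            raise ValueError("k-space entries must be finite")


def to_kspace(img: np.ndarray, spacing: tuple[float, float] = (1.0, 1.0)) -> KSpaceMatrix:
    """Centred orthonormal 2-D DFT of a real slice."""
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2 or not np.all(np.isfinite(img)):
        raise ValueError("img must be a finite 2-D array")
    k = np.fft.fftshift(np.fft.fft2(img, norm="ortho"))
    return KSpaceMatrix(data=k, pe_axis=0, spacing=spacing)


def from_kspace(k: KSpaceMatrix) -> np.ndarray:
    """Magnitude image of the inverse transform (real, non-negative)."""
    return np.abs(np.fft.ifft2(np.fft.ifftshift(k.data), norm="ortho"))


def apply_rigid(
    img: np.ndarray,
    motion: MotionEvent,
    spacing: tuple[float, float] = (1.0, 1.0),
) -> np.ndarray:
    """Rotate about the image centre then translate (bilinear, zero fill)."""
    if spacing[0] <= 0 or spacing[1] <= 0:
        raise ValueError(f"spacing must be positive, got {spacing}")
    out = np.asarray(img, dtype=np.float64)
    if motion.rotation != 0.0:
        out = ndimage.rotate(out, motion.rotation, reshape=False, order=1, mode="constant", cval=0.0)
    dy = motion.shift_y / spacing[0]
    dx = motion.shift_x / spacing[1]
    if dy != 0.0 or dx != 0.0:
        out = ndimage.shift(out, (dy, dx), order=1, mode="constant", cval=0.0)
    return out


def draw_slabs(
    n_lines: int,
    width_range: tuple[int, int],
    n_pe: int,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Disjoint (start, width) slabs totalling exactly ``n_lines`` lines.

    Widths are drawn uniformly from ``width_range``; when the remaining budget
    cannot accommodate another in-range width the current slab is stretched or
    the final slab clipped (a clip below the minimum width is logged, not
    raised).  Slab positions are uniform over all disjoint placements.
    """
    if n_lines > n_pe:
        raise ValueError(f"cannot perturb {n_lines} of {n_pe} lines")
    if n_lines <= 0:
        return []
    lo, hi = width_range

    widths: list[int] = []
    remaining = n_lines
    while remaining > 0:
        w = int(rng.integers(lo, hi + 1))
        if w >= remaining:
            w = remaining
            if w < lo:
                logger.warning(
                    "final slab clipped to width %d below minimum %d", w, lo
                )
        elif remaining - w < lo:
            # stretch or shrink so the leftover stays partitionable
            w = remaining if remaining <= hi else remaining - lo
        widths.append(w)
        remaining -= w

    # uniform disjoint placement: k blocks among the free lines
    k = len(widths)
    free = n_pe - n_lines
    bars = np.sort(rng.choice(free + k, size=k, replace=False))
    cumw = np.concatenate([[0], np.cumsum(widths)[:-1]])
    starts = bars - np.arange(k) + cumw
    return [(int(s), int(w)) for s, w in zip(starts, widths)]


def draw_motion_event(
    slab: tuple[int, int],
    preset: SeverityPreset,
    rng: np.random.Generator,
) -> MotionEvent:
    """One rigid-motion state, uniform within the preset bounds."""
    return MotionEvent(
        rotation=float(rng.uniform(-preset.rot_bound, preset.rot_bound)),
        shift_x=float(rng.uniform(-preset.trans_bound, preset.trans_bound)),
        shift_y=float(rng.uniform(-preset.trans_bound, preset.trans_bound)),
        slab_start=slab[0],
        slab_width=slab[1],
    )


def _slabs_clear_center(slabs: list[tuple[int, int]], n_pe: int, radius: int) -> bool:
    c = n_pe // 2
    return all(s + w <= c - radius or s >= c + radius for s, w in slabs)


def corrupt(
    img: np.ndarray,
    preset: SeverityPreset,
    rng_seed: int,
    noise_sigma: float = 0.0,
    spacing: tuple[float, float] = (1.0, 1.0),
    return_kspace: bool = False,
) -> PairedSample | tuple[PairedSample, KSpaceMatrix]:
    """Produce a motion-corrupted copy of ``img`` plus the full motion log.

    For each slab one motion state is drawn, the slice is rigidly transformed
    in image space, and the slab's phase-encode lines in the centred spectrum
    are replaced by the transformed copy's.  Lines outside all slabs remain
    bit-identical to the original spectrum.  Optional additive Gaussian noise
    of standard deviation ``noise_sigma`` models acquisition noise.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.min() < -1e-9 or img.max() > 1.0 + 1e-9:
        raise ValueError("img must be normalized to [0, 1]")
    rng = np.random.default_rng(rng_seed)
    n_pe = img.shape[0]

    slabs = draw_slabs(preset.n_lines, preset.slab_width_range, n_pe, rng)
    if preset.center_exclusion > 0:
        for _ in range(100):
            if _slabs_clear_center(slabs, n_pe, preset.center_exclusion):
                break
            slabs = draw_slabs(preset.n_lines, preset.slab_width_range, n_pe, rng)
        else:
            logger.warning("could not clear central band of radius %d", preset.center_exclusion)

    k = to_kspace(img, spacing)
    mixed = k.data.copy()
    log: list[MotionEvent] = []
    for slab in slabs:
        ev = draw_motion_event(slab, preset, rng)
        moved = apply_rigid(img, ev, spacing)
        k_moved = to_kspace(moved, spacing)
        s, w = ev.slab_start, ev.slab_width
        mixed[s : s + w, :] = k_moved.data[s : s + w, :]
        log.append(ev)

    k_mixed = KSpaceMatrix(mixed, pe_axis=0, spacing=spacing)
    y = from_kspace(k_mixed)
    if noise_sigma > 0:
        y = y + rng.normal(0.0, noise_sigma, size=y.shape)
    pair = PairedSample(x=img, y=y, motion_log=log, spacing=spacing)
    if return_kspace:
        return pair, k_mixed
    return pair
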