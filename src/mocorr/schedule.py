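"""Geometric shifting sequence driving the residual-shifting diffusion.

The sequence ``{beta_t}`` grows monotonically from ``beta_1`` (near zero) to
``beta_N`` (near one) following a non-uniform geometric law; the per-step
increments ``alpha_t = beta_t - beta_{t-1}`` control how much of the residual
and noise each forward step injects.  ``beta_0 := 0`` so that
``alpha_1 = beta_1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NoiseSchedule",
    "build_schedule",
    "beta_decreases_in_p",
    "DEFAULT_N_STEPS",
    "DEFAULT_GAMMA",
    "DEFAULT_GROWTH_P",
    "DEFAULT_BETA_N",
    "TRAINING_PROFILE_N_STEPS",
]

DEFAULT_N_STEPS = 4
DEFAULT_GAMMA = 2.0
DEFAULT_GROWTH_P = 0.3
DEFAULT_BETA_N = 0.999

#: Step count of the forward schedule in the reference training configuration
#: (the few-step sampler default above remains N=4).
TRAINING_PROFILE_N_STEPS = 20


class ScheduleConfigError(ValueError):
    """Raised for invalid scheduler hyperparameters."""


@dataclass(frozen=True)
class NoiseSchedule:
    """Immutable shifting sequence with its generating hyperparameters.

    Attributes
    ----------
    n_steps : int
        Number of diffusion steps N.
    gamma : float
        Noise-scaling factor multiplying every injected standard deviation.
    growth_p : float
        Growth-rate exponent; smaller values front-load the shift.
    beta : ndarray, shape (N + 1,)
        ``beta[0] = 0`` and ``beta[t]`` for t = 1..N.
    alpha : ndarray, shape (N + 1,)
        First differences; ``alpha[0] = 0`` is a placeholder, valid
        entries are ``alpha[1..N]``.
    sqrt_beta1_times_gamma : float
        ``gamma * sqrt(beta[1])``, recorded for audit.
    """

    n_steps: int
    gamma: float
    growth_p: float
    beta: np.ndarray = field(repr=False)
    alpha: np.ndarray = field(repr=False)
    sqrt_beta1_times_gamma: float

    def __post_init__(self) -> None:
        if self.beta.shape != (self.n_steps + 1,):
            raise ScheduleConfigError("beta must have length n_steps + 1")
        if self.beta[0] != 0.0:
            raise ScheduleConfigError("beta[0] must be exactly zero")
        if not np.all(np.diff(self.beta) > 0):
            raise ScheduleConfigError("beta must be strictly increasing")
        if self.beta[-1] >= 1.0:
            raise ScheduleConfigError("beta[N] must be < 1")

    def check_step(self, t: int, *, lo: int = 0) -> int:
        """Validate a step index, returning it unchanged."""
        t = int(t)
        if not lo <= t <= self.n_steps:
            raise ValueError(f"step t={t} outside [{lo}, {self.n_steps}]")
        return t


def build_schedule(
    n_steps: int = DEFAULT_N_STEPS,
    gamma: float = DEFAULT_GAMMA,
    growth_p: float = DEFAULT_GROWTH_P,
    beta1: float | None = None,
    betaN: float = DEFAULT_BETA_N,
) -> NoiseSchedule:
    """Construct the shifting sequence.

    Interior values satisfy

        sqrt(beta_t) = sqrt(beta_1) * exp(0.5 * ((t-1)/(N-1))**p
                                          * log(beta_N / beta_1))

    for t = 1..N, so the endpoints land exactly on ``beta1`` and ``betaN``.
    ``beta1`` defaults to ``(0.04 / gamma) ** 2`` so that
    ``gamma * sqrt(beta1) = 0.04``.
    """
    n_steps = int(n_steps)
    if n_steps < 2:
        raise ScheduleConfigError(f"n_steps must be >= 2, got {n_steps}")
    if gamma <= 0:
        raise ScheduleConfigError(f"gamma must be > 0, got {gamma}")
    if growth_p <= 0:
        raise ScheduleConfigError(f"growth_p must be > 0, got {growth_p}")
    if beta1 is None:
        beta1 = (0.04 / gamma) ** 2
    if not 0.0 < beta1 < betaN < 1.0:
        raise ScheduleConfigError(
            f"need 0 < beta1 < betaN < 1, got beta1={beta1}, betaN={betaN}"
        )

    t = np.arange(1, n_steps + 1, dtype=np.float64)
    frac = ((t - 1.0) / (n_steps - 1.0)) ** growth_p
    sqrt_beta = np.sqrt(beta1) * np.exp(0.5 * frac * np.log(betaN / beta1))
    beta = np.concatenate([[0.0], sqrt_beta**2])
    # pin endpoints exactly (exp/log round-trip leaves ~1 ulp otherwise)
    beta[1] = beta1
    beta[n_steps] = betaN
    alpha = np.concatenate([[0.0], np.diff(beta)])
    sched = NoiseSchedule(
        n_steps=n_steps,
        gamma=float(gamma),
        growth_p=float(growth_p),
        beta=beta,
        alpha=alpha,
        sqrt_beta1_times_gamma=float(gamma * np.sqrt(beta1)),
    )
    return sched


def beta_decreases_in_p(
    t: int,
    p_small: float,
    p_large: float,
    n_steps: int = DEFAULT_N_STEPS,
    gamma: float = DEFAULT_GAMMA,
    beta1: float | None = None,
    betaN: float = DEFAULT_BETA_N,
) -> bool:
    """True iff beta[t] under ``p_small`` strictly exceeds beta[t] under
    ``p_large`` (interior steps only; endpoints are pinned and equal)."""
    t = int(t)
    if not 1 < t < n_steps:
        raise ValueError(f"t={t} must be an interior step of 1..{n_steps}")
    if p_small > p_large:
        raise ValueError("require p_small <= p_large")
    lo = build_schedule(n_steps, gamma, p_small, beta1, betaN)
    hi = build_schedule(n_steps, gamma, p_large, beta1, betaN)
    return bool(lo.beta[t] > hi.beta[t])
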