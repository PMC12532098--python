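"""Residual-shifting diffusion: forward process, reverse posterior, loss,
training loop, and the few-step sampler.

The forward chain moves a clean slice ``x`` toward its corrupted counterpart
``y`` by injecting fractions ``alpha_t`` of the residual ``r = y - x``
together with Gaussian noise scaled by ``gamma``:

    q(x_t | x_{t-1}, y) = N(x_{t-1} + alpha_t r,  gamma^2 alpha_t I)
    q(x_t | x, y)       = N(x + beta_t r,         gamma^2 beta_t I)

so the terminal state is centred on ``y`` rather than on pure noise, and the
reverse chain only has to bridge the residual — a handful of steps suffices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable, Sequence

import numpy as np

from .schedule import NoiseSchedule

__all__ = [
    "PairedSample",
    "NoisyState",
    "GaussianParams",
    "TrainConfig",
    "forward_step",
    "forward_marginal",
    "posterior_params",
    "predict_mean",
    "loss",
    "train",
    "sample",
]

_ATOL_RESIDUAL = 1e-12


@dataclass
class PairedSample:
    """A (motion-free, motion-corrupted) slice pair with its residual.

    ``r`` is derived as ``y - x`` when omitted; when supplied it is checked
    against that identity.
    """

    x: np.ndarray
    y: np.ndarray
    r: np.ndarray | None = None
    motion_log: list = field(default_factory=list)
    spacing: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must share shape")
        if self.r is None:
            self.r = self.y - self.x
        else:
            self.r = np.asarray(self.r, dtype=np.float64)
            if self.r.shape != self.x.shape:
                raise ValueError("r must share shape with x")
            if not np.allclose(self.r, self.y - self.x, atol=_ATOL_RESIDUAL):
                raise ValueError("r must equal y - x")


@dataclass(frozen=True)
class NoisyState:
    """A forward-process state ``x_t`` at step ``t``."""

    x_t: np.ndarray
    t: int | np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.x_t)):
            raise ValueError("x_t must be finite everywhere")


@dataclass(frozen=True)
class GaussianParams:
    """Isotropic Gaussian: per-pixel mean plus one scalar variance
    (per-sample array of variances in the batched case)."""

    mean: np.ndarray
    variance: float | np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.variance) < 0):
            raise ValueError("variance must be non-negative")


def _coeff(values: np.ndarray, t: int | np.ndarray, ndim: int) -> np.ndarray | float:
    """Index a schedule array at ``t``; array ``t`` broadcasts over leading
    batch axis of an ``ndim``-dimensional signal."""
    t = np.asarray(t)
    if t.ndim == 0:
        return float(values[int(t)])
    out = values[t.astype(int)]
    return out.reshape(out.shape + (1,) * (ndim - 1))


def forward_step(
    x_prev: np.ndarray,
    r: np.ndarray,
    sched: NoiseSchedule,
    t: int,
    eps: np.ndarray,
) -> NoisyState:
    """One forward transition: draw from N(x_{t-1} + alpha_t r, gamma^2 alpha_t I).

    ``eps`` carries unit-normal semantics; pass zeros for the mean path.
    """
    t = sched.check_step(t, lo=1)
    x_prev, r, eps = map(np.asarray, (x_prev, r, eps))
    if not (x_prev.shape == r.shape == eps.shape):
        raise ValueError("x_prev, r, eps must share shape")
    a = sched.alpha[t]
    x_t = x_prev + a * r + sched.gamma * np.sqrt(a) * eps
    return NoisyState(x_t=x_t, t=t)


def forward_marginal(
    x: np.ndarray,
    y: np.ndarray,
    sched: NoiseSchedule,
    t: int | np.ndarray,
    eps: np.ndarray,
) -> NoisyState:
    """Marginal draw from N(x + beta_t (y - x), gamma^2 beta_t I).

    ``t`` may be a per-sample integer array when ``x`` is batched; t = 0
    returns ``x`` exactly.
    """
    x, y, eps = map(np.asarray, (x, y, eps))
    if not (x.shape == y.shape == eps.shape):
        raise ValueError("x, y, eps must share shape")
    t_arr = np.asarray(t)
    if np.any(t_arr < 0) or np.any(t_arr > sched.n_steps):
        raise ValueError(f"t out of range 0..{sched.n_steps}")
    b = _coeff(sched.beta, t, x.ndim)
    x_t = x + b * (y - x) + sched.gamma * np.sqrt(b) * eps
    return NoisyState(x_t=x_t, t=t)


def posterior_params(
    x_t: np.ndarray,
    x: np.ndarray,
    sched: NoiseSchedule,
    t: int,
) -> GaussianParams:
    """Closed-form reverse posterior q(x_{t-1} | x_t, x, y).

    mean = (beta_{t-1}/beta_t) x_t + (alpha_t/beta_t) x,
    variance = gamma^2 (beta_{t-1}/beta_t) alpha_t.  The residual cancels,
    so neither y nor r appears.  At t = 1 this collapses to (x, 0).
    """
    t = sched.check_step(t, lo=1)
    bt, btm1, at = sched.beta[t], sched.beta[t - 1], sched.alpha[t]
    mean = (btm1 / bt) * np.asarray(x_t) + (at / bt) * np.asarray(x)
    var = sched.gamma**2 * (btm1 / bt) * at
    return GaussianParams(mean=mean, variance=var)


def predict_mean(
    x_t: np.ndarray,
    x0_hat: Any,
    sched: NoiseSchedule,
    t: int,
) -> GaussianParams:
    """Model-side reverse mean: posterior mean with the denoiser estimate
    ``x0_hat`` substituted for the true clean image; variance stays fixed at
    the posterior value (it does not depend on x or y)."""
    t = sched.check_step(t, lo=1)
    bt, btm1, at = sched.beta[t], sched.beta[t - 1], sched.alpha[t]
    mean = (btm1 / bt) * x_t + (at / bt) * x0_hat
    var = sched.gamma**2 * (btm1 / bt) * at
    return GaussianParams(mean=mean, variance=var)


def loss(x0_hat: Any, x: Any, mode: str = "l1l2"):
    """Training objective on the denoiser estimate.

    ``l1l2`` (default): mean-per-pixel squared error plus mean-per-pixel
    absolute error, weighted 1:1.  ``l2``: squared term only (ablation mode).
    Works on plain arrays and on autograd tensors alike.
    """
    if mode not in ("l1l2", "l2"):
        raise ValueError(f"unknown loss mode {mode!r}")
    d = x0_hat - x
    out = (d * d).mean()
    if mode == "l1l2":
        out = out + abs(d).mean()
    return out


@dataclass
class TrainConfig:
    """Scaled-down training hyperparameters (reference run: RAdam, cosine
    annealing 2e-4 -> 2e-5 with warm-up)."""

    iterations: int = 1000
    batch_size: int = 4
    lr_start: float = 2e-4
    lr_min: float = 2e-5
    warmup_steps: int = 100
    loss_mode: str = "l1l2"

    def __post_init__(self) -> None:
        if self.iterations < 1 or self.batch_size < 1:
            raise ValueError("iterations and batch_size must be positive")
        if not 0 <= self.lr_min <= self.lr_start:
            raise ValueError("need 0 <= lr_min <= lr_start")
        if self.loss_mode not in ("l1l2", "l2"):
            raise ValueError(f"unknown loss mode {self.loss_mode!r}")


def train(
    dataset: Sequence[PairedSample],
    denoiser,
    sched: NoiseSchedule,
    config: TrainConfig,
    rng_seed: int,
):
    """Train the denoiser on paired slices.

    Each iteration draws a batch of pairs, a per-sample step t ~ U{1..N},
    forms x_t from the marginal with fresh noise, and steps RAdam on the
    combined loss between f(x_t, y, t) and x.  Returns ``(denoiser,
    loss_trace)`` with one loss value per iteration.

    Independent RNG streams (t draws, forward noise, batch order) are spawned
    from the one master seed, so traces are reproducible bit-for-bit.
    """
    from .nn.optim import RAdam, WarmupCosine

    if len(dataset) == 0:
        raise ValueError("dataset must be non-empty")
    t_ss, eps_ss, order_ss = np.random.SeedSequence(rng_seed).spawn(3)
    t_rng = np.random.default_rng(t_ss)
    eps_rng = np.random.default_rng(eps_ss)
    order_rng = np.random.default_rng(order_ss)

    xs = np.stack([s.x for s in dataset]).astype(np.float64)
    ys = np.stack([s.y for s in dataset]).astype(np.float64)

    opt = RAdam(denoiser.parameters(), lr=config.lr_start)
    lr_sched = WarmupCosine(
        lr_start=config.lr_start,
        lr_min=config.lr_min,
        warmup_steps=config.warmup_steps,
        total_steps=config.iterations,
    )

    trace = np.empty(config.iterations, dtype=np.float64)
    for it in range(config.iterations):
        idx = order_rng.integers(0, len(dataset), size=config.batch_size)
        x, y = xs[idx], ys[idx]
        t = t_rng.integers(1, sched.n_steps + 1, size=config.batch_size)
        eps = eps_rng.standard_normal(x.shape)
        x_t = forward_marginal(x, y, sched, t, eps).x_t

        opt.lr = lr_sched(it)
        x0_hat = denoiser.forward(x_t, y, t)
        obj = loss(x0_hat, x, mode=config.loss_mode)
        val = float(obj.data)
        if not np.isfinite(val):
            raise RuntimeError(
                f"non-finite loss {val} at iteration {it}; "
                "lower the learning rate or check the inputs"
            )
        trace[it] = val
        opt.zero_grad()
        obj.backward()
        opt.step()
    return denoiser, trace


def sample(
    y: np.ndarray,
    denoiser: Callable[[np.ndarray, np.ndarray, int], np.ndarray],
    sched: NoiseSchedule,
    rng_seed: int,
) -> np.ndarray:
    """Few-step reverse sampling from the corrupted slice ``y``.

    Initialises x_N ~ N(y, gamma^2 beta_N I), then for t = N..1 sets

        x_{t-1} = mu_theta + gamma * sqrt(beta_{t-1} alpha_t / beta_t) * eps

    with eps = 0 at t = 1.  Exactly N denoiser evaluations are performed.
    ``denoiser`` is any callable (x_t, y, t) -> x0_hat.
    """
    y = np.asarray(y, dtype=np.float64)
    if not np.all(np.isfinite(y)):
        raise ValueError("y must be finite")
    rng = np.random.default_rng(rng_seed)
    N = sched.n_steps
    x_t = y + sched.gamma * np.sqrt(sched.beta[N]) * rng.standard_normal(y.shape)
    for t in range(N, 0, -1):
        x0_hat = np.asarray(denoiser(x_t, y, t))
        if x0_hat.shape != y.shape:
            raise ValueError(
                f"denoiser returned shape {x0_hat.shape}, expected {y.shape}"
            )
        mu = predict_mean(x_t, x0_hat, sched, t)
        eps = rng.standard_normal(y.shape) if t > 1 else 0.0
        x_t = mu.mean + np.sqrt(mu.variance) * eps
    return x_t
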