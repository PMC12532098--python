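"""Checkpoints: denoiser weights plus the full schedule hyperparameters and a
config snapshot, so any artifact can be regenerated from the file alone."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .nn.unet import Denoiser, DenoiserConfig
from .schedule import NoiseSchedule, build_schedule

__all__ = ["save_checkpoint", "load_checkpoint"]


def save_checkpoint(
    path: str | Path,
    denoiser: Denoiser,
    sched: NoiseSchedule,
    config: dict,
    seed: int,
) -> Path:
    meta = {
        "model": denoiser.cfg.to_dict(),
        "schedule": {
            "n_steps": sched.n_steps,
            "gamma": sched.gamma,
            "growth_p": sched.growth_p,
            "beta1": float(sched.beta[1]),
            "betaN": float(sched.beta[-1]),
        },
        "config": config,
        "seed": int(seed),
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **denoiser.state_dict())
    return path


def load_checkpoint(path: str | Path) -> tuple[Denoiser, NoiseSchedule, dict]:
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["__meta__"]).decode())
        state = {k: npz[k] for k in npz.files if k != "__meta__"}
    cfg = DenoiserConfig.from_dict(meta["model"])
    denoiser = Denoiser(cfg, rng_seed=0)
    denoiser.load_state_dict(state)
    s = meta["schedule"]
    sched = build_schedule(
        n_steps=s["n_steps"],
        gamma=s["gamma"],
        growth_p=s["growth_p"],
        beta1=s["beta1"],
        betaN=s["betaN"],
    )
    return denoiser, sched, meta
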