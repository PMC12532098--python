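# mocorr

Retrospective motion-artifact correction for brain MRI slices with a
residual-shifting diffusion model, plus the matching in-silico k-space
rigid-motion simulator. The full loop — simulate → train → sample → evaluate —
runs at desk scale on synthetic phantoms, on a single CPU, with no external
data.

## How it works

- **Simulator** (`mocorr.simulate`): random slabs (3–7 lines wide) of
  phase-encode lines in a slice's centred k-space are replaced by lines from
  rigidly transformed copies of the image (rotations up to ±7°, translations
  up to ±5 mm, one independent transform per slab). Severity presets
  `minor` / `moderate` / `heavy` perturb exactly 7 / 10 / 15 lines.
- **Diffusion** (`mocorr.schedule`, `mocorr.diffusion`): the forward chain
  shifts the clean slice `x` toward the corrupted slice `y` by injecting
  fractions `alpha_t` of the residual `r = y − x` plus Gaussian noise scaled
  by `gamma`, following a geometric shifting sequence `beta_t` with
  `gamma·sqrt(beta_1) = 0.04` and `beta_N = 0.999`. Because the terminal
  state is centred on `y`, reverse sampling needs only `N = 4` steps.
- **Denoiser** (`mocorr.nn`): a small U-net whose attention positions are
  occupied by shifted-window transformer blocks, conditioned on `y` by
  channel concatenation and on the step `t` by sinusoidal embedding. It runs
  on a self-contained NumPy reverse-mode autograd engine (no GPU framework
  required), trained with RAdam under a warm-up + cosine schedule on a
  combined ℓ1+ℓ2 loss (ℓ2-only mode available for ablation).
- **Metrics** (`mocorr.metrics`): PSNR, SSIM (11×11 Gaussian window,
  σ = 1.5), NMSE in percent, pooled Pearson r, aggregated mean ± population
  std.
- **Phantoms** (`mocorr.phantoms`): brain-like ellipse phantoms with a bright
  outer rim, so both artifact families (in-head ringing, out-of-head
  ghosting) are visible on fixtures.

## CLI

```sh
# paired phantom fixtures (clean + corrupted volumes + motion log)
mocorr fixtures --n 50 --size 64 --severity heavy --seed 0 --out data/

# corrupt an existing NIfTI volume slice-by-slice
mocorr simulate --in t1.nii.gz --severity moderate --seed 0 --out sim/

# train the denoiser on paired slices
mocorr train --data data/ --config config.yaml --seed 0 --out ckpt.npz

# few-step correction of a corrupted volume
mocorr correct --in data/corrupted.nii.gz --ckpt ckpt.npz --seed 0 --out corrected.nii.gz

# metrics report
mocorr evaluate --pred corrected.nii.gz --ref data/clean.nii.gz --report metrics.json
```

Configuration is YAML with sections `diffusion:` (`n_steps`, `gamma`,
`growth_p`, `beta1`, `betaN`), `model:` (channels, multipliers, window,
heads, embedding size, Swin levels) and `train:` (iterations, batch size,
learning rates, warm-up, `loss_mode: l2|l1l2`, seed); see
`mocorr.config.default_config()` for the defaults. Every artifact written
embeds the config and seed that produced it.

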