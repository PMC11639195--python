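# cherenkov-denoise

Noise and mottle suppression for **cumulative Cherenkov images** of
radiotherapy delivery.  A time-gated camera pointed at the patient (or
phantom) sums thousands of per-pulse frames into one image of the
Cherenkov light escaping the surface — a surrogate map of surface dose.
Because only a handful of photons arrive per pixel per frame, images
accumulated over clinically realistic outputs (25–50 MU) are dominated
by shot noise, read noise, stray x-ray impulses, and the blotchy
low-frequency mottle that survives the camera's own temporal/spatial
median filtering.

This package is a complete, tested pipeline for benchmarking classical
denoisers on such data, for medical-physics researchers who want to
quantify what post-processing can recover before reaching for learned
methods:

* **synthetic acquisitions** — a beam-plateau scene on a phantom
  silhouette with a slanted occluder edge, per-frame Poisson + Gaussian
  + impulse noise, the camera's median/background-subtraction chain,
  and MU-proportional frame summation (a 9000 MU accumulation is the
  ground truth; 25/50 MU accumulations are the noisy inputs);
* **five denoisers**, each written against its published formulation:
  TV-L1 (primal-dual, cost trace exposed), non-local means (literal
  double-loop oracle *and* the integral-image fast variant, value-
  identical), two-stage BM3D (DCT + Haar, hard threshold then Wiener),
  an adaptive trimmed mean (window size and trim fraction driven by
  local signal), and the bilateral filter;
* **metrics** — PSNR = 20·log₁₀(max(truth)/RMSE); slanted-edge
  sharpness (ESF → LSF → MTF, MTF50/MTF10, 10–90% rise distance); and
  the radially averaged noise power spectrum,
  NPS(ν_x, ν_y) = ΔxΔy/(MN²)·Σ|FFT₂(ROI)|², with per-bin error bars
  across ROIs;
* **the study driver** — per-image parameter sweeps over the published
  ranges, percent PSNR gains, one-way ANOVA and Tukey HSD across
  filters.

`docs/methods.md` describes the model, defaults and numerical choices
in detail.

## Worked example

Sweep all five filters on one synthetic 25 MU-equivalent image
(`python analysis/02_sweep_filters.py`, ~2 min):

```
     tvl1: best {'lam': 0.389}                      -> 20.15 dB -> 27.56 dB (+36.8%)
      nlm: best {'sigma': 4375.0}                   -> 20.15 dB -> 30.65 dB (+52.1%)
     bm3d: best {'noise_sigma': 3333.3}             -> 20.15 dB -> 30.62 dB (+52.0%)
      atm: best {'lam': 2.0}                        -> 20.15 dB -> 20.48 dB (+1.7%)
bilateral: best {'sigma_s': 1.0, 'sigma_r': 1.6e8}  -> 20.15 dB -> 23.76 dB (+17.9%)
```

Each line is one filter's PSNR-optimal operating point: the noisy
baseline is 20.15 dB against the 9000 MU ground truth, and e.g. NLM's
best σ (4375, interior to its 0–7000 grid) lifts it to 30.65 dB, a
52.1% gain.  The optima landing inside the published ranges — and the
adaptive trimmed mean trailing the field — reproduce the qualitative
pattern reported for real camera data.  Edge sharpness and noise
texture for the same scene (`python analysis/03_sharpness_and_nps.py`):

```
    noisy: MTF50 0.230 cy/px, rise 1.65 px, mean NPS(0-1.5/mm) 2.5e+05 counts^2 mm^2
      nlm: MTF50 0.219 cy/px, rise 2.08 px, mean NPS(0-1.5/mm) 1.05e+05 counts^2 mm^2
      atm: MTF50 0.039 cy/px, rise 13.94 px, mean NPS(0-1.5/mm) 1.55e+05 counts^2 mm^2
bilateral: MTF50 0.183 cy/px, rise 2.70 px, mean NPS(0-1.5/mm) 1.89e+05 counts^2 mm^2
```

NLM suppresses the noise power below even the ground-truth floor while
nearly preserving the edge; the adaptive trimmed mean trades a 13.9 px
rise distance (vs 1.65 px noisy) for its modest PSNR gain.

The numbered scripts under `analysis/` run the study end to end:
`01_generate_images.py` (image sets), `02_sweep_filters.py` (per-image
optimization), `03_sharpness_and_nps.py` (sharpness + NPS),
`04_compare_filters.py` (full 5-scene × 2-MU benchmark with ANOVA and
Tukey HSD; tables under `results/benchmark/`).  A `cherenkov-denoise`
CLI exposes the same steps (`generate`, `denoise`, `sweep`,
`evaluate`, `benchmark`) for use on your own TIFF images.

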