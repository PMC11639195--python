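# Methods

## The problem

Cherenkov imaging during external-beam radiotherapy records the faint
visible light emitted where the beam's secondary electrons traverse
tissue, giving a surrogate map of surface dose.  A time-gated camera
captures one frame per linac pulse; summing all frames of a delivery
yields a *cumulative* image whose noise level is set by the delivered
monitor units (MU): a long 9000 MU exposure is clean enough to act as
ground truth, while clinically realistic 25–50 MU deliveries are
photon-starved and mottled.  This package benchmarks five classical
denoisers on such data — total-variation minimization with an L1
fidelity (TV-L1), fast non-local means (NLM), block-matching 3D
collaborative filtering (BM3D), an adaptive trimmed mean (ATM), and the
bilateral filter — scoring each by peak signal-to-noise ratio (PSNR),
slanted-edge sharpness, and the radially averaged noise power spectrum
(NPS), and closing with a one-way ANOVA and Tukey HSD comparison of the
filters' percent PSNR gains.

## Synthetic acquisitions

Real camera data for this problem is not redistributable, so the
package generates its own with the statistical structure the analysis
assumes.  A scene is a per-frame photon-expectation map: a smooth beam
plateau shaped by a Gaussian vignette, zero outside a phantom margin,
and cut by a slanted occluder edge (2–12° from vertical) that later
serves the slanted-edge sharpness measurement.  Each simulated frame
draws Poisson counts on (scene + ambient background), adds Gaussian
read noise and sparse stray-radiation impulses (salt-type: impulses
only ever add signal, with amplitudes large enough to saturate a pixel
relative to its per-frame counts), then passes through the camera-side
preprocessing chain: a centered rolling temporal median across frames
(window truncated at the sequence ends), a per-frame spatial median,
and subtraction of the configured background expectation.  Frames are
summed and the sum clipped at zero.

Default study conditions (all configurable):

| parameter | default | why |
| --- | --- | --- |
| scene size | 256 × 256 px | desk-scale; all window defaults checked against it |
| pixel pitch | 0.5 mm/px | object-plane sampling is mounting-dependent; every mm⁻¹ axis is conditional on this value |
| field level | 1.8–2.4 photons/px/frame | photon-starved regime; see calibration below |
| background | 0.5 photons/px/frame | dim ambient light surviving time gating |
| read noise | 0.5 counts/frame | small relative to shot noise, as for a cooled CMOS |
| impulse rate / amplitude | 10⁻⁴ /px/frame, U[30, 80] counts | rare stray x-ray hits that locally saturate a frame |
| temporal / spatial median | 3 frames / 3 × 3 px | the camera applies both; the true window sizes are unpublished, so modest defaults are declared rather than inferred |
| truth / noisy accumulations | 1800 frames (9000 MU at 5 MU/frame) vs 5 or 10 frames (25 / 50 MU) | noise level ∝ 1/√frames, as in the real acquisition chain |

The ground truth is, by default, itself a simulated 9000 MU
accumulation through the same camera pipeline: the small bias a median
filter introduces on skewed low-count data is then common to truth and
noisy images and cancels in the comparison.  An analytic
(expectation × frames) truth is available and flagged in metadata.
The noisy image is rescaled by frames_truth/frames_noisy so both share
one intensity scale.  One RNG stream per dataset is split per frame by
counter, so identical seeds give bit-identical images and changing the
frame count never reshuffles earlier frames.

**Calibration.** The per-frame intensity scale was fixed once so that
the PSNR-optimal filter parameters land inside the operating ranges reported for these filters on
real camera Cherenkov data (TV-L1 λ* ≈ 0.3–0.5, NLM
σ* ≈ 4500–5500 of a 0–7000 range, BM3D σ* ≈ 1500–3900 of 0–10000, ATM
λ* at the aggressive end of 2–14).  With the defaults above, the 25
MU-equivalent residual on the plateau has σ ≈ 500–900 counts at the
truth scale and a baseline PSNR near 20 dB, and the swept optima
reproduce those interior positions (λ* ≈ 0.39, σ*_NLM ≈ 4400–5600,
σ*_BM3D ≈ 1700–3300, λ*_ATM = 2).

**What the generator does not emulate:** lens point-spread and
perspective, time-gating electronics, patient motion, skin-tone
dependent attenuation, and the true (unpublished) camera median window
sizes.  Passing tests therefore demonstrate correctness of the
algorithms and the qualitative noise-level behavior, not quantitative
agreement with any particular camera.

## The five denoisers

All filters are pure maps on images: shape and pixel pitch are
preserved, finite input gives finite output, a constant image is a
fixed point, and windowed filters use symmetric (mirror) padding to
avoid zero-padding bias in plateau statistics.  Outputs are clipped at
zero (frequency-domain shrinkage can produce microscopic negative
excursions).

**TV-L1** minimizes ‖∇I‖₂ + λ‖I − G‖₁ (isotropic total variation,
forward differences, Neumann boundary) with a Chambolle–Pock primal-dual
scheme, τ = 0.25 and dual step 0.125, default 100 iterations.  Two
in-house choices: (i) the image is normalized by its maximum before
iterating — both objective terms are 1-homogeneous, so the minimizer is
unchanged, but the conventional λ range ≈ 0.01–3.5 and the fixed step
sizes then apply at any intensity scale; (ii) the returned iterate is
the best-so-far in objective value (a monotone variant in the spirit of
monotone FISTA): the internal primal-dual sequence advances normally
while the output sequence, and the cost trace exposed for diagnostics,
never increases.  λ = 10⁶ reproduces the input to well below 10⁻³
relative; λ → 0 flattens aggressively.

**NLM** weights each candidate pixel by exp(−SSD/σ²), the SSD taken
over a patch with a uniform kernel.  The "20 × 20 window / 4 × 4
patch" convention is stored as centered half-sizes (10 and 2), giving
odd effective supports of 21 and 5.  The self term d = (0,0) enters
with weight 1.  Two implementations share this definition: a literal
per-pixel evaluation (the oracle, with an optional Gaussian patch
kernel), and the fast variant that, for each window shift, box-filters
the squared-difference image with an exact integral image and
accumulates one weighted shifted copy per shift.  They agree to
floating-point rounding (≤ 10⁻⁸ of the dynamic range), which the tests
enforce on batches of random images.

**BM3D** runs the standard two stages.  Matching uses the
bias-corrected squared distance ‖z_R − z_j‖² − 2γNσ² (γ = 3 in stage
1, 0 in stage 2); under the white-noise model the correction is the
same constant for every candidate and cannot reorder matches, but it is
kept for fidelity to the formulation.  The reference block is always
its own first match (relevant when a flat region makes every candidate
tie).  Groups of 16 blocks (8 × 8, stride-4 reference grid, 39 × 39
search window) are transformed with an orthonormal 2D DCT per block and
an orthonormal 1D Haar across the group.  Stage 1 hard-thresholds at
λ_thr·σ (λ_thr = 2.7) and aggregates with weights 1/(σ²·N_kept); stage
2 re-matches on the stage-1 estimate and applies empirical Wiener
shrinkage Y²/(Y² + μ²σ²) with weights 1/(σ²‖shrink‖²).  The general
PSD-per-coefficient path is an extension point; with an orthonormal
transform and white noise the coefficient variance collapses to σ².
Internal refinements of the reference implementation (Kaiser-window
aggregation, per-group transform switching) are deliberately omitted.

**ATM** computes, per pixel, a window size
M = 2βλ·Max/(2λ·Max + β·p(x−δ)) and trim fraction α = x/(λ·Max)
(clipped to [0, 0.5]), with p(z) = max(z, 0), Max the image maximum,
β = 31 the largest window, δ = 5 counts the low-signal cutoff, and
λ ≥ 2 the (inverse) aggressiveness.  M is rounded to the nearest odd
integer, ties upward, clipped to [3, β].  The trimmed mean sorts the
window, discards the ⌈αM²⌉ smallest and largest entries and averages
the rest; if trimming removes everything (the α → 0.5 endpoint) the
median element is returned.  Note the ceiling: any α > 0 trims at
least one element per end, so the exact box-mean limit exists only at
α = 0.  The vectorized implementation groups pixels by window size and
is verified against a literal per-pixel loop.

**Bilateral** combines a spatial Gaussian (scale σ_s, support
2⌈2σ_s⌉+1) with an intensity-range Gaussian (scale σ_r); σ_r → ∞
degenerates to the truncated Gaussian blur, σ_r small preserves edges.
In the parameter sweep the σ_r axis spans [100·v, 11000·v] with v the
variance of a zero-signal background patch, matching the common reference implementation, whose
smoothing parameter is variance-like; the axis value is applied directly as the σ_r of the
range kernel.

## Metrics

**PSNR** = 20·log₁₀(max(truth)/RMSE), the peak taken from the ground
truth image per the formulation used in the study; a data-type peak
can be supplied instead and gives systematically different values, so
the choice is an explicit argument.  Identical images return +inf.

**Slanted edge.** Each row's 50% crossing (between robust per-row
plateau estimates) locates the edge; a least-squares line fit gives
the edge angle; all ROI pixels are projected onto the edge normal and
averaged in bins of 1/4 pixel (4× oversampling, the standard choice).
The LSF is the two-point finite difference of the oversampled ESF —
centered on the half-sample grid — and the MTF is the normalized
magnitude of its FFT divided by the difference filter's |sinc|
response, so an ideal step reports a flat MTF through the band of
interest.  Before the FFT the LSF is windowed with a Hann-tapered
(Tukey) window, flat over the central half of the span around the LSF
peak: a full-width Hann would attenuate the tails of even a
well-resolved Gaussian LSF by several percent, while the tapered window
leaves a σ_b = 2 px edge untouched (closed-form checks: MTF50
= √(ln2/(2π²σ_b²)), MTF10 = √(ln10/(2π²σ_b²)), 10–90 rise = 2.563·σ_b,
all reproduced within 3%).  MTF50/MTF10 are first crossings with
linear interpolation and are reported absent — never extrapolated —
when a level is not reached below Nyquist.  The 10–90 rise scans
outward from the steepest point of the transition, so plateau noise
far from the edge cannot fake a crossing.

**NPS.**  Overlapping square ROIs (default 100 × 100 px, 50% overlap)
are mean-subtracted (first-order detrend only: the synthetic plateaus
are flat; a polynomial detrend is the obvious extension for real
data), and NPS(ν_x, ν_y) = ΔxΔy/(M·N²)·Σ|FFT2(ROI)|².  For white noise
of variance σ² this integrates to σ²ΔxΔy per 2D frequency sample
(625 counts²·mm² for σ = 50 at 0.5 mm pitch), and total spectral power
equals the mean detrended ROI variance (Parseval), both enforced in
tests.  Radial averaging uses bins one 2D-frequency sample wide,
1/(N·Δx); bins beyond the axis Nyquist are dropped because the sampled
square truncates those annuli and biases their mean; the per-bin
standard deviation across ROIs supplies the error bars.  All mm⁻¹ axes
are conditional on the configured pixel pitch.

## Sweeps and the benchmark

Each filter is optimized per image by exhaustive grid search over the
published ranges (λ ∈ [0.01, 3.5] for TV-L1; σ ∈ (0, 7000] for NLM;
σ ∈ (0, 10000] for BM3D; λ ∈ [2, 14] for ATM; σ_s ∈ [1, 18] ×
σ_r ∈ [100v, 11000v] for bilateral).  Axes that nominally start at 0
begin at the smallest positive grid value, since the weight formulas
divide by σ².  The full grids use 15 points per axis (10 × 10
bilateral), log-spaced where a range spans decades.  Ties break toward
the least aggressive setting; a boundary argmax triggers a logged
warning to extend the grid.  Filter failures at individual grid points
are recorded as missing and excluded from the argmax.

The benchmark's default problem size — five 256 × 256 scenes, 25 and
50 MU-equivalent levels, reduced grids of 9/8/6/7 points (4 × 4 for
bilateral, with its spatial axis capped at 12 because the support
grows as 4σ_s and dominates runtime) — was chosen so the whole study
runs in minutes on one CPU core; every range still matches the
published sweeps.  Per MU level the five filters' percent PSNR gains
(one value per scene) feed a classical one-way ANOVA and Tukey's HSD
at 95% family-wise confidence (studentized-range distribution;
degenerate zero-variance input reported as its exact limit).
Sharpness statistics skip images whose edge ROI fails the
edge-detection precondition rather than failing the run.

## Known limitations

* The ATM filter's adaptive windows average across high-contrast
  boundaries: a dim pixel whose β-sized window overlaps the bright
  plateau receives a halo unless the trim removes the bright samples.
  On scenes with hard zero regions its PSNR gain is therefore marginal
  and can be negative for individual images — the same behavior is
  reported for individual real camera images — while its
  dataset-mean gain stays positive under the default conditions.
* BM3D's white-noise PSD is an approximation; on very smooth truths the
  swept σ can rail at the top of the published range because
  over-smoothing pays.  The boundary-argmax warning flags this.
* The synthetic mottle is the residue of median-filtered shot noise; it
  reproduces the qualitative low-frequency blotchiness of cumulative
  images but not any specific camera's noise texture, so percent PSNR
  gains are larger than the camera-data figures and only the direction
  and ordering of effects should be compared.
* Slanted-edge preconditions (near-vertical edge, ≥ 15–20 px of
  plateau either side) are enforced, not worked around; ROIs that
  violate them are reported absent.
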