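# Methods

## The AM-FM image model

A grayscale image is modelled as a sum of amplitude- and
frequency-modulated components

    f(x, y) = sum_n a_n(x, y) cos(phi_n(x, y)),

where `a_n` is the instantaneous amplitude (IA, local texture contrast) and
the gradient of the phase, `grad(phi_n)`, is the instantaneous frequency
(IF, local texture granularity, reported in rad/pixel internally and
cycles/mm at a known pixel density). Axis convention throughout: `x` is the
row (vertical) axis 0, `y` the column axis 1; `ifx = d(phi)/dx`.

Demodulation proceeds in four steps (`amfmtex.amfm`):

1. **Analytic image.** The 2D FFT rows at positive vertical frequency are
   doubled and the negative rows zeroed; DC and Nyquist rows keep weight
   one. The real part of the result equals the input, and every in-band
   cosine becomes a complex exponential whose modulus and argument carry IA
   and phase.
2. **Channel filterbank.** Each frequency scale is an annulus of the
   retained half-plane, split into orientation sectors (4 by default,
   centered on the 0°, ±45° and 90° orientations). Scales in cycles/mm:
   low 1.04–2.95, medium 2.08–5.89, high 4.17–11.79 — dyadically spaced,
   covering instantaneous wavelengths of 5.66–16, 2.83–8 and 1.41–4 pixels
   at the reference density of 16.66 px/mm. Radial edges are raised-cosine
   with transition width 0.1 of the band edge; angular edges are
   raised-cosine with half-overlap 1/3 of the sector width. Smooth edges
   matter: hard sector boundaries produce slowly decaying spatial kernels
   whose ringing from region discontinuities dominates the IF error budget
   (measured on the phantom: background IF MSE improves by more than an
   order of magnitude with smooth angular edges).
3. **Dominant component.** Per pixel and scale, the channel with maximal
   response modulus supplies IA (the modulus) and the phase (the
   argument); ties go to the lowest channel index.
4. **IF estimation.** From the FM image `F = cos(phase)`, for spacing n,
   `(F(x+n) + F(x-n)) / (2 F(x)) = cos(n w)` exactly when `F = cos(w x + c)`.
   Allowed spacings are n ∈ {1,2,3,4} (low), {1,2} (medium), {1} (high);
   among the spacings whose ratio falls in [-1, 1] the one with the
   smallest absolute ratio is kept — arccos is best conditioned near zero
   argument — and `w = arccos(ratio)/n`. The estimator recovers the
   frequency *magnitude* only (cosine is even); signs are not available.
   A spacing n aliases when `n·w > pi`; the per-scale spacing sets accept
   this for the top of each band in exchange for conditioning, and the
   in-band validity check (below) discards most aliased estimates.

**Validity masking.** A pixel's estimate at a scale is valid only if
(i) |F| ≥ 1e-3 (the ratio denominator), (ii) some spacing yields a ratio in
[-1, 1], (iii) IA exceeds 1e-8 of the image's dynamic range, and (iv) the
estimated IF magnitude lies inside the scale's passband. Invalid pixels
carry IF 0 and are excluded from statistics; on structureless input (white
noise, constants) most pixels are invalid by design.

`demodulate(..., pad=N)` optionally mirror-extends the image before the
FFT; the default is no padding, which keeps demodulation exact on periodic
tones. `reconstruct_fm` integrates the IF field (first-row column ramp plus
row-wise accumulation) for visual inspection.

## The synthetic phantom

`amfmtex.phantom` renders a 1024×1024 image that mimics a longitudinal
carotid view: five horizontal bands — three dark backgrounds (amplitudes
158, 102, 182; rows 0–272, 307–702, 751–1023) and two bright strips
(amplitude 250; rows 273–306, 703–750) standing in for the intima-media
complex. Within each band the vertical IF sweeps linearly across the image
width (backgrounds over [π/7.5, π/4.5] rad/px with `ify = -ifx`; strips
over [π/6.5, π/5.5] with `ify = +ifx`), giving diagonally oriented chirps.

The prescribed IF field is non-conservative (its curl is `ifx'(c) ≠ 0`), so
no exact phase generates it. The phase is synthesized as
`phi(r, c) = r·ifx(c) + sign·cumsum(ifx)`, which makes the row derivative
equal the stated `ifx` *exactly* and concentrates the unavoidable residual
`r·ifx'(c)` in the column derivative. That residual is the floor of the
y-component IF error on the noise-free phantom (≈2.6e-2 (rad/px)² MSE over
backgrounds); it is a property of the phantom definition, not of the
estimator.

Speckle is multiplicative uniform noise, `g = f + n·f`, with `n` i.i.d.
uniform on [-a, a], `a = sqrt(3·variance)`, zero mean and variance 0.07 by
default — drawn once for the whole image from a fixed seed.

What the phantom does *not* emulate: the ultrasound point-spread function,
log compression of the RF envelope, spatially correlated speckle, or
anatomical curvature. Passing benchmarks on the phantom demonstrates
correct IF recovery under piecewise-stationary chirped texture and
multiplicative noise, not clinical performance.

## Despeckle filters

All filters use reflect (edge-repeating mirror) padding and return new
arrays. Defaults follow the standard usage for IMC despeckling: 5×5
windows; lsmv/wiener/kuhawara run 2 iterations, the others 1.

* **dsf_lsmv** — `f = mean + k(g - mean)` with
  `k = (var - mean²·sn²) / (var·(1 + sn²))`, clipped to [0, 1]; `sn²` is the
  speckle variance (supplied, or estimated — see below). Homogeneous
  windows collapse to the mean; structured windows pass through.
* **dsf_wiener** — same update with `k = (var - sn²)/var`.
* **dsf_kuhawara** — of the four 1×5 line segments through the pixel
  (horizontal, vertical, two diagonals) take the one with minimal variance
  (ties in that order) and substitute its median.
* **dsf_lsminsc** — of the nine 3×3 subwindows inside the 5×5
  neighbourhood, take the one minimizing the speckle index C = var/mean
  computed on log(1+g) (ties in row-major order) and substitute its
  intensity-domain mean; subwindows with zero log-mean are skipped.
* **dsf_median / dsf_hybrid_median** — 5×5 median; the hybrid variant
  averages the medians over the "+" cross, the "×" cross and the full
  square, preserving corners and thin lines better than the plain median.
* **dsf_srad** — speckle-reducing anisotropic diffusion:
  `g ← g + div(c·grad g)/eta_s` with
  `c² = [½|∇g|² - (1/16)(∇²g)²] / (g + ¼∇²g)²` clipped to [0, 1] (c is an
  edge detector for speckled images: high relative gradient with low
  relative Laplacian marks an edge). Defaults `eta_s = 4` (4-neighbour
  normalization), 100 steps; the divergence uses the upwind face stencil
  documented in the docstring, which satisfies a discrete max principle.
* **dsf_nldif** — coherence-enhancing diffusion `dg/dt = div(D ∇g)` with
  tensor eigenvalues `lambda_1 = alpha·(1 - (mu1-mu2)²/s²)` while
  `(mu1-mu2)² ≤ s²` and 0 beyond, `lambda_2 = alpha`, where mu1 ≥ mu2 are
  the eigenvalues of the structure tensor (gradient at sigma 1 px, tensor
  smoothing 2 px). Defaults `s² = 2`, `alpha = 0.9`, step `m = 0.2`,
  10 steps. The explicit step uses a conservative face-flux discretisation:
  a twice-central-difference divergence is blind to checkerboard modes and
  was observed to violate the range of noisy inputs, while the face scheme
  contracts it.

**Noise-variance estimation** (`estimate_noise_variance`): the average of
per-tile sample variances of log(1+g) over non-overlapping 21×21 tiles
(required: tile ≥ 4× the filter window, so tiles see noise, not window-scale
structure). Log compression turns multiplicative noise approximately
additive, making tile variance an estimate of the noise variance wherever
the underlying tissue is locally homogeneous.

## Features and statistics

Per image and scale: 32-bin normalized histograms of IA and of the IF
magnitude in cycles/mm over `roi ∩ valid`. IF histogram ranges are the
scale passbands (fixed, hence comparable across images); IA ranges default
to the per-image maximum and accept a cohort-wide maximum. The per-image
scalar feature is the ROI *median* of the per-pixel values (six features:
L/M/H × IA/IF). Group summaries report mean/STD/median and the
5/10/25/75/90/95 percentiles (linear interpolation) of the per-image
medians, ×100 for display. Group comparison is the two-sided Mann-Whitney
U test on per-image medians at alpha = 0.05 per feature, with no
multiple-testing correction by default (a Bonferroni option exists);
scipy's implementation is exact for small untied samples and uses the
continuity-corrected normal approximation otherwise. Groups smaller than 3
trigger a low-power warning rather than an error.

## Preprocessing

Images are bicubically resampled (spline order 3) to 16.66 px/mm, then
intensities linearly mapped so the user-selected blood median lands at 2.5
and the adventitia median at 185 (midpoints of the 0–5 and 180–190
reference ranges), clipped to [0, 255]. Resolution standardization precedes
normalization (the affine intensity map commutes with resampling up to
clipping, so the order is a convention). ROI masks are reduced to a
160-column (9.6 mm) window centered on the mask's column centroid (nearest
integer, ties rounded down) so that all images contribute regions of equal
physical length.

## Evaluation harness

`run_synthetic_experiment` scores low-scale demodulation against the
phantom truth for the noise-free image, the speckled image, and each
despeckled image. The error is the MSE (optionally MAE) of the IF
component *magnitudes* — the arccos estimator carries no sign — over a
region mask, after a 16-px image-border trim and intersection with the
validity mask; "combined" pools background and strip pixels (union mask),
it is not an average of the two sub-errors. The metric, seed and noise
variance are stamped on the report.

Problem sizes: the benchmark and phantom-recovery computations run on the
full 1024×1024 phantom; single-tone checks use 256×256; the null
calibration of the rank test uses 2000 simulated 20-vs-20 comparisons.

## Known limitations

* At the default noise level (variance 0.07), low-scale IF estimation is
  barely degraded by speckle (combined error +14%), because the channel
  filters average the in-band noise heavily. Consequently despeckling does
  **not** reduce the strip-region IF error here: filters blur the 34/48-px
  strips and add slightly more error than the noise they remove. Despeckle
  benefits for this benchmark only materialize for estimators whose
  noise-induced failure rate is substantial.
* IF signs are not recovered; all IF statistics are magnitudes.
* Region boundaries contaminate estimates within roughly a filter length
  (≈16 px at the low scale); the phantom's narrow strips are therefore
  partly transient-dominated even noise-free.
* The phantom's y-component IF truth is unattainable to within the curl
  residual discussed above.
* Diffusion-filter step counts (SRAD 100, nldif 10) are conventions, not
  convergence criteria; both are exposed in `FilterConfig`.
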