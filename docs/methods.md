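# Methods

## Stimulus model

Stimuli are square gray-level images `g = m + n + a·s_l`: mean level
`m = 100` gl, a stationary zero-mean Gaussian noise field `n`, and a
unit-peak Gaussian target `s` (σ = 3 px) at location `l` with amplitude
`a = contrast × m`.  "Contrast" is therefore peak target amplitude over the
mean level, the convention consistent with quoting the background as "20%
RMS contrast".

The noise power spectrum on the 2-D DFT grid (frequencies in cycles/pixel)
is `S_β(f) = C_β/|f|^β` with two conventions:

* **DC rule** — the singular `f = 0` value is replaced by the value at the
  first harmonic `f = 1/N`;
* **normalization** — `C_β` is set so the implied pixel variance equals
  `(0.20 × 100)² = 400 gl²`.

DFT scaling: noise is synthesized as `irfft2(rfft2(white) · √S)` with
unit-variance white input, under which the pixel variance equals the plain
mean of `S` over the grid and the covariance operator acts as
multiplication by `S(f)` under numpy's `fft2/ifft2` pair.  All whitened
inner products therefore reduce to frequency sums with a single `1/N²`
Parseval factor; any global rescaling of this convention cancels in every
decision and in efficiency.  Hermitian-symmetric frequency-domain sampling
(equivalently, filtering a real white field) keeps fields exactly real and
seed-stable.

Target placement uses integer pixel locations and circular shifts, matching
the circulant covariance model; the 64-pixel border around the central
half-side search region (one quarter of the image area) keeps wrap-around
effects negligible at the acceptance-disk scale.  Images are kept in
floating point: display quantization is a property of the hardware, not of
the decision theory, and is out of scope.

### White-to-pink processing

The processed condition filters β = 0 stimuli (after target embedding) with
an amplitude filter proportional to `1/f` (DC by the first-harmonic rule),
normalized so `mean(A²) = 1`.  This deterministic filter normalization
leaves the expected background variance at 400 gl², i.e. the 20% RMS
contrast, and maps the flat spectrum exactly onto the native β = 2 spectrum
grid.  The amplitude (not power) reading of the "1/f kernel" is adopted
because it is the only one that turns a white background into a β = 2
power-law background; the filtered target acquires visibly heavier tails
than the Gaussian.  Whether an additional per-image renormalization was
ever applied is immaterial for efficiency, which is scale-free.

## Ideal observers

*Detection*: statistic `t = wᵀ(g − m)` with `w = Σ_β⁻¹ s`; ties at the
criterion resolve to "not detected".  `d′ = contrast · m · √(sᵀΣ_β⁻¹s)`,
and PC at the unbiased (midpoint) criterion is `Φ(d′/2)`.

*Free localization*: the location posterior under a uniform prior is
`p(l|g) ∝ exp(a·s_lᵀΣ_β⁻¹g)` (the quadratic term is constant by
stationarity).  The pipeline is: circular correlation of the prewhitened
template with the mean-subtracted image; exponentiation **after subtracting
the in-region maximum** (the raw recipe overflows double precision at
realistic contrasts; the subtraction is exact for the normalized
posterior); masking to the search region; normalization; circular
convolution with the radius-5 disk (81 lattice offsets, `≤` radius test);
argmax with first-occurrence row-major tie-breaking (a measure-zero event,
fixed for oracle comparability).  The acceptance disk used for scoring and
the disk used to judge correctness share one radius unless explicitly
decoupled.

*Detect-and-localize*: as localization, with "absent" reported when the
maximum disk score does not exceed a criterion.

A brute-force oracle evaluates the same posterior by explicit
shifted-template inner products and direct disk summation on images up to
64 px; the convolutional path must agree with it exactly (tested on 1000
random instances).

## Monte-Carlo performance machinery

Look-up tables of PC vs. contrast run from 0 in steps of 0.01 (full-size
default) until PC exceeds 0.94, with 2000 trials per point, giving binomial
standard errors below 1% near the 80% level.  One bank of noise
correlations and target locations is reused across contrasts (common random
numbers): the template correlation separates into a noise part and a
deterministic shifted signal part, so each contrast costs only an
exponentiation and a disk convolution.  The batched engine uses an
FFT-based disk convolution on the zero-padded search block (identical to
the circular convolution because the border exceeds the disk radius) and
float32 score storage; its agreement with the exact per-image path is
tested directly.  LUT inversion applies isotonic regression before linear
interpolation, since Monte-Carlo PC curves are not exactly monotone.

Psychometric data are fit by maximum likelihood with
`p(c) = floor + (1 − floor)·Φ((c − µ)/σ)`; the floor is fixed (0.5 for
detection; for localization chance is approximately the disk/search area
ratio, ≈ 0.5% at full size) rather than fitted — at realistic trial counts
the data give it no leverage.  Degenerate (all-chance or saturated) data are rejected
with guidance.

Criterion matching: detection solves the two-equation Gaussian system
`z(hit) − z(fa) = c·d′₁`, with the criterion placed to reproduce the
false-alarm rate.  D&L matching pins the score criterion to the empirical
`1 − FP` quantile of absent-trial maximum scores at each candidate
contrast and root-finds the contrast on the correct-D&L rate, using common
random numbers across the search for stability.  Efficiency is reported as
a fraction internally and percent in summaries; standard errors are
computed session-by-session (synthetic sessions are blocks of 50 trials).

The uniform-response deviation baseline over the discrete acceptance region
(81 lattice offsets, |d| ≤ 5) is 3.392 px; in degrees this is 0.177° at
0.0522°/px.  A printed reference of 0.180° implies a rounded 0.053°/px
conversion; the degree value is reported from the exact pixel angle and not
forced to agree.

## Classification images

Whitening divides the noise DFT by the generating `S_β` — using any other
spectrum is an error, not a warning, because a mismatched inverse
covariance silently biases the estimate.  The detection estimator is the
unweighted signed sum of the four outcome-class means
(`q̄_FP − q̄_TN + q̄_TP − q̄_FN`); the localization estimator averages
whitened fields circularly shifted so the response lands at the image
center, over false-localization trials only (≈ 20% of trials at PC 80%).
Circular shifts keep the estimator unbiased under the wrap-around
generation model; motor jitter in synthetic observers degrades but does not
break recovery (quantified in tests).

Frequency summaries apply a radial spatial Butterworth window (order 4,
cutoff 1.05° ≈ 20 px) before the Fourier transform, then average the real
part in annuli one DFT step wide (bin center = mean radius of member
frequencies) and normalize the peak to 1.  The imaginary part is carried as
a diagnostic; windowing precedes any display smoothing, which is cosmetic
(order-4 Butterworth low-pass at 5.6 cyc/deg = 0.29 cyc/px).  The analytic
IO weights are `∝ f^β·exp(−2π²σ²f²)` with continuous peak `√β/(2πσ)` —
0 → 1.77 cyc/deg as β goes 0 → 3 at σ = 3 px × 0.0522°/px, and ≈ 1.72
after discrete radial binning at N = 256.

## Synthetic observers

Two model-human families provide ground truth:

* **Linear observer** — template (ideal, low-frequency-suppressed,
  peak-shifted, or fixed-β) with internal noise and criterion jitter
  expressed in units of the template response's noise standard deviation,
  plus integer-rounded isotropic Gaussian motor jitter on localization
  responses.  Internal noise is white in the statistic/map domain — the
  simplest standard model.  The localizer takes the argmax of its response
  map without the acceptance-disk integration (a principled suboptimality a
  human plausibly shares; separable by construction since the IO path is a
  different code path).  Detection efficiency is exactly
  `(wᵀs)²/(sᵀΣ⁻¹s · wᵀΣw · (1 + σ_int² + σ_jit²))`.
* **Equivalent-input-noise observer** — adds an independent noise field
  with the stimulus spectrum scaled by γ and applies the exact IO pipeline
  at the effective contrast; the degraded trial is statistically identical
  to an original trial at contrast `c/√(1+γ²)`, so efficiency is exactly
  `1/(1+γ²)` for *all three tasks*.  This is the closed-form oracle used
  for localization and D&L efficiency recovery, where no algebraic
  linear-observer formula is exact.

A fixed β = 2-tuned template reproduces the qualitative signature of a
non-adapting observer: efficiency is highest in the β = 2 background and
lowest in white noise.

## Problem sizes and tolerances

Monte-Carlo tests run at a 64-pixel image size (32-pixel search region,
same σ, radius, contrast conventions), where every structural property of
the full geometry — search fraction, disk size, spectrum conventions — is
preserved; the headline β = 1 threshold is additionally checked at the full
256-pixel geometry.  Statistical assertions use 3-standard-error bands at
the stated trial counts.  The classification-image recovery bound (mean
absolute deviation of peak-normalized radial profiles < 0.22 at 2000
trials, peak within 1.5 bins for β > 0) was calibrated by simulation; the
white-noise condition shows the known low-frequency bias of the
response-aligned estimator and is held to the profile bound only.

## Limitations

The synthetic observers emulate mechanisms (template mismatch, internal
noise, criterion jitter, motor jitter), not fitted humans: passing tests
show the *pipeline* recovers known ground truth, not that any particular
human matches a model.  Reaction times, display calibration, sub-pixel
response positions, and multi-target extensions are out of scope; human
classification-image curves cannot be reproduced without the (non-public)
human trial data.
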