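# Methods

## The model

A Z-spectrum is the normalized steady-state water signal `Z(ω) = S(ω)/S0`
as a function of saturation offset ω (ppm; water = 0). We model it as unity
minus a sum of five Lorentzian attenuation lines,

```
Z(ω) = 1 − Σ_n a_n σ_n² / (σ_n² + 4 (ω − ω_n)²),
```

one line per saturable pool — direct water saturation (DS), semi-solid
magnetization transfer (MT), relayed NOE, amide, amine — parameterized by
amplitude `a_n` (fraction of S0), center `ω_n` (ppm) and full width at half
maximum `σ_n` (ppm). This amplitude/FWHM parameterization satisfies
`L(ω_n) = a_n` and `L(ω_n ± σ_n/2) = a_n/2`, which is what the fitting
tests assert. (A commonly reprinted variant of this equation with a
first-power `σ_n` and a minus sign in the denominator is dimensionally
inconsistent and can be negative or singular; we use the standard form
throughout.)

The model is lineshape-level, not exchange-rate-level: saturation power and
duration do not appear, and amplitudes are phenomenological fractions, not
proton concentrations. This matches what the downstream analysis consumes —
every contrast in the pipeline is a functional of the lineshapes only.

## The phantom

The synthetic module generates everything the pipeline needs with known
ground truth:

* **Offset schedule.** Variably spaced segments 0–6 ppm (step 0.1), 6–10
  (0.5), 10–20 (1), 20–100 (10), mirrored about water: 173 unique offsets.
  (Enumerating these segments cannot produce the commonly quoted 174; the
  builder follows the segments and we note the one-count discrepancy here.)
  The WASSR schedule is ±1 ppm in 0.1-ppm steps (21 unique offsets; an
  acquisition that counts 0 once per polarity would list 22).
* **Labels.** A deterministic nested-ellipse "coronal slice" containing
  eight ROIs — cerebral cortex, entorhinal cortex, hippocampus, thalamus,
  hypothalamus (gray); corpus callosum, cerebral peduncle, fimbria (white)
  — each ≥ 50 pixels at any size ≥ 64².
* **Ground truth.** Per (group, ROI): the NOE/amide/amine amplitudes and
  the NOE_MTR target. Hippocampus, entorhinal cortex, hypothalamus and
  fimbria NOE_MTR values and the hippocampal pool amplitudes are reported
  WT/AD group means from the in-vivo literature; the remaining cells are
  plausible same-scale values fixed once. MT amplitude is 0.06 everywhere.
  Widths: DS 4, MT 25, NOE 3, amide 2, amine 2 ppm. The DS ground-truth
  width is deliberately wider than the fit initial (2 ppm): at −3.5 ppm a
  2-ppm water line attenuates at most ~7.6% of S0 even at amplitude 1, so
  no physical DS amplitude could produce ~40% NOE_MTR; a 4-ppm line makes
  every target reachable with `a_DS < 1`.
* **Calibration.** `calibrate_noe_mtr` scales the DS amplitude by root
  bracketing so the noiseless forward model reproduces the ROI's NOE_MTR
  target exactly (closure ≤ 1e−6); all other pools stay at their ground
  truths. `calibrate_decomposition` root-brackets the DS/MT/NOE amplitudes
  so the noiseless contributions at −3.5 ppm are 52/6/40% with the ~2%
  remainder from fixed amide/amine tails — the whole-brain fixture.
* **Noise and B0.** Additive zero-mean Gaussian noise (default sd 0.01 of
  S0) on every offset image, the WASSR stack and (multiplicatively) the
  reference image. High-SNR averaged acquisitions justify a Gaussian rather
  than Rician model. The static-field error is a low-order 2D polynomial
  over the slice (default peak 0.23 ppm, inside the ±1 ppm WASSR window);
  per-voxel spectra are the forward model evaluated at `ω − ΔB0(x, y)`. An
  optional mode multiplies the field by a per-subject standard-normal
  factor (shim quality and polarity vary between animals); the packaged
  `b0_sensitivity_config` uses it with a laterally concentrated field
  (0.02 + 0.55 v²) to probe what B0 correction buys downstream statistics.
* **Reference.** The unsaturated image is the noiseless forward value at
  ±300 ppm (polarity-averaged) times (1 + noise); calibration uses the same
  polarity-averaged reference, so contrast closure is exact by construction.
* **Cohorts.** n = 5 per group by default; subject seeds are spawned
  deterministically from the configuration seed, so identical configurations
  are byte-identical.

What the phantom does **not** emulate: exchange-rate physics (B1/T_sat
dependence, asymmetric super-Lorentzian MT), Rician magnitude noise,
coil/bias fields, motion, anatomy beyond a cartoon slice, and
between-subject biological variability — the per-ROI truth is constant
within group, so passing recovery tests demonstrates pipeline fidelity
(absence of processing bias), not in-vivo effect sizes or power.

## Preprocessing

**B0 mapping.** For each masked voxel a cubic spline is fit through its
WASSR spectrum and the minimum located on a 1e−3-ppm grid across the
sampled window; a voxel whose minimum lands on the window edge, or whose
spectrum is flat, is flagged invalid rather than raising. On noiseless
phantoms the field is recovered to < 0.01 ppm; at the default noise, to
~0.02 ppm worst-case.

**Spectral correction.** Each voxel's spectrum is re-evaluated at
`ω + ΔB0` using cubic-spline interpolation within the densely sampled
|ω| ≤ 6 ppm region and linear interpolation beyond, clamping outside the
acquired range. The dialect is fixed so results are bit-reproducible; the
shift-then-correct round trip errs < 1e−3 of S0 on the dense schedule.
Invalid voxels pass through unchanged.

**Casorati SVD denoising.** The masked voxels × offsets matrix is
decomposed and components above a median-based singular-value threshold are
retained. The multiplier defaults to the aspect-ratio-dependent
optimal-hard-threshold coefficient ω(β) ≈ 0.56β³ − 0.95β² + 1.82β + 1.43
(Gavish & Donoho 2014), β = min/max dimension — ~1.49 for a cohort-sized
matrix — with a fixed multiplier available via `threshold_factor`. A
relative floor (1e−10 of the leading value) lets exact low-rank inputs
report their true rank. Rank truncation is a bias/variance trade: on the
packaged cohorts the retained rank is ~5 and the residual bias on the most
extreme ROI amplitudes is ~+0.3% absolute, which the recovery tolerances
accommodate; a harsher threshold (e.g. fixed 2×median) visibly pulls
extreme ROIs toward the cohort mean. Denoised spectra feed only the
multi-pool fit; NOE_MTR uses B0-corrected, un-denoised data.

## Contrasts

NOE_MTR is computed per voxel from the corrected −3.5 ppm image and the
unsaturated reference (NaN where the reference is non-positive), optionally
also uncorrected + Gaussian-smoothed (σ = 0.75) for the correction-impact
comparison. MTR asymmetry is `100·(S(+Δω) − S(−Δω))/S_ref` reported
against negative offsets, signed so NOE-dominated asymmetry is positive.

The five-pool fit runs per voxel on `S/S0` over all offsets: bounded
trust-region least squares (`scipy.optimize.least_squares`, analytic
Jacobian, ftol = xtol = gtol = 1e−8, ≤ 200 evaluations) from fixed initial
values — DS (a 0.8, σ 2, center free ±0.3), MT (−2.5 ± 2, a 0.1,
σ 25 ∈ [10, 100]), NOE (−3.5 ± 0.5, a 0.1, σ 3), amide (+3.5 ± 0.5),
amine (+2.0 ± 0.5, center configurable; some protocols use 2.75 ppm).
Every voxel starts from the same initial values, so results are identical
for any worker count and processing order (asserted by test); fits are
independent, so restricting the fit mask to a single ROI does not change
any fitted value. Non-convergent voxels keep their initial parameters and
are flagged. The pool decomposition at an offset is each line's percentage
of the total attenuation there; percentages sum to 100 wherever defined.

## Registration

Skull stripping: three-cluster fuzzy c-means (m = 2, quantile-initialized
centers — deterministic) on intensities; the brain is the union of the two
brightest clusters (membership > 0.5), reduced to the largest connected
component and morphologically closed (radius 2). Which clusters constitute
brain is a documented choice; images without three intensity modes fall
back to Otsu. Intensity normalization is monotone quantile matching
(256 landmarks, computed within masks so a stripped image's zero background
cannot skew tissue quantiles; quantile runs map to their mean destination
so plateau intensities land mid-plateau). Affine alignment runs 10 rounds
of blur-both-then-register (geometric σ schedule 4.0 → 0.4) with
Mattes mutual information, full sampling (deterministic) and a
regular-step gradient-descent optimizer, each round warm-started from the
last and rolled back if it worsens the unblurred-image metric; MI tolerates
residual intensity mismatch after histogram matching. Refinement is
diffeomorphic demons (50 iterations, field smoothing σ = 1; Thirion
variant available), with a folding warning if > 1% of Jacobians are
non-positive. Labels ride through the chain with nearest-neighbor
interpolation only, so the output label set is always a subset of the
input's.

## Statistics

The analysis unit is the subject × ROI pixel mean. Per metric: a linear
mixed-effects model (REML) with group as fixed effect and a random
intercept per ROI (slope structure unspecified in the source design;
intercept chosen), Wald p for the group effect, ICC defined as
between-ROI over total variance from the fitted components; and per-ROI
OLS on the group indicator, which reproduces the classic equal-variance
two-sample t-test to 1e−10. Per-ROI p-values are uncorrected (an optional
Holm flag exists, off by default), α = 0.05, with `*`/`**` markers at
0.05/0.01. Degenerate layouts are handled, not raised: boundary
random-effect variance is reported as such, and ROIs with singleton groups
are skipped with a warning.

## Problem sizes and numerical choices

The packaged study conditions are a 128 × 128 slice, 173 offsets, n = 5
per group. The reproduction script fits the five-pool model over the
hippocampus label (the quantity reported is the hippocampal ROI mean, and
voxel fits are independent); full-brain fitting is the same call with a
different mask. The whole-brain decomposition fixture emulates a brain
**average** spectrum, so its noise is the per-voxel sd divided by the
square root of the number of averaged voxels. Tests use a coarser offset
schedule (0.25-ppm dense step) and smaller slices where the property under
test does not depend on sampling density; the B0 round-trip tolerance is
asserted on the dense schedule it presumes.

Tie-breaks and degenerate inputs: WASSR minima at window edges are
invalid, not clamped; zero total attenuation makes the decomposition NaN
with a warning; a rank-0 Casorati matrix returns the input unchanged;
σ = 0 smoothing is the identity; symmetric-schedule MTR_asym of missing
mirrored offsets interpolates with a warning.

## Known limitations

* Lineshape-level simulation cannot validate exchange-rate inference or B1
  dependence; it validates the processing chain only.
* The SVD threshold trades a small amplitude bias (~0.3% on extreme ROIs at
  default noise) for variance; studies with stronger ROI contrasts may
  prefer a lower multiplier or no denoising before fitting.
* Registration operates on a piecewise-constant cartoon: mutual information
  on such images is insensitive to sub-pixel drift, so self-registration is
  identity only to ~0.1 px translation (the matrix itself is identity to
  ~2e−3). Demons assumes intensity agreement; with very noisy anatomicals
  its gain over affine shrinks.
* With n = 5 and constant within-group truth, significance flags reflect
  measurement noise only; they are not a power analysis.
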