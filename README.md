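# noemri

Analysis pipeline for saturation-transfer (NOE/CEST) Z-spectrum MRI of the
mouse brain, exercised end-to-end on synthetic single-slice phantoms whose
region-level ground truths are the group means reported for wild-type (WT)
versus APP^NL-F knock-in (AD-model) mice.

Relayed nuclear Overhauser effect (rNOE) MRI saturates non-exchangeable
lipid/protein protons ~3.5 ppm upfield of water; cross-relaxation relays the
saturation to water and attenuates the image. Because membrane lipids and
proteins are disrupted early in Alzheimer's pathology, NOE-weighted contrast
is a candidate early-stage biomarker. The pipeline implements the two
standard readouts of the Z-spectrum `Z(ω) = S(ω)/S0`:

* the magnetization-transfer-ratio contrast at −3.5 ppm,

  `NOE_MTR (%) = 100 · (S_−300ppm − S_−3.5ppm) / S_−300ppm`,

  with the unsaturated ±300 ppm acquisition as reference — a lumped
  DS + MT + NOE measure; and

* five-pool Lorentzian decomposition,

  `Z(ω) = 1 − Σ_n a_n σ_n² / (σ_n² + 4(ω − ω_n)²)`,

  with pools for direct water saturation (DS, 0 ppm), semi-solid
  magnetization transfer (MT, broad), relayed NOE (−3.5 ppm), amide
  (+3.5 ppm) and amine (+2 ppm), fitted per voxel by bounded trust-region
  least squares; `a_n` (amplitude, % of S0), `ω_n` (center, ppm) and `σ_n`
  (FWHM, ppm).

Around these sit the supporting stages of a template-based small-animal
workflow: WASSR B0 mapping (per-voxel water-line minimum by spline search)
and spectral re-gridding; spatio-spectral denoising by singular-value
thresholding of the Casorati (voxels × offsets) matrix; fuzzy-c-means skull
stripping, multiscale affine + diffeomorphic demons atlas registration with
nearest-neighbor label transfer; and ROI statistics (linear mixed-effects
model with disease group as fixed effect and ROI as random intercept, ICC,
per-ROI OLS at α = 0.05).

## Layout

* `src/noemri/` — the library: `phantom` (schedules, labels, Lorentzian
  forward model, cohort simulation), `preproc` (B0, SVD denoising),
  `contrasts` (NOE_MTR, MTR_asym, five-pool fitting, decomposition),
  `registration`, `stats`, `cli` (`noemri run-all --config cfg.yaml`).
* `analysis/01…06_*.py` — numbered drivers that run each step of the study
  and write tables under `results/analysis/`.
* `docs/methods.md` — model, assumptions, parameter choices, limitations.

## Worked example

```sh
python analysis/02_noe_mtr.py
```

simulates both cohorts (128×128 slice, n = 5 per group, noise sd 0.01,
smooth B0 field peaking at 0.23 ppm), runs WASSR B0 correction and the
NOE_MTR contrast, and prints the recovered group means next to the phantom
ground truth:

```
NOE_MTR group means (%), recovered vs ground truth:
  entorhinal cortex    WT 36.99 (truth 37.0)   AD 34.76 (truth 34.8)
  fimbria              WT 40.69 (truth 40.7)   AD 37.31 (truth 37.3)
  hippocampus          WT 40.12 (truth 40.1)   AD 37.07 (truth 37.1)
  hypothalamus         WT 40.86 (truth 40.8)   AD 39.60 (truth 39.6)
  ...
```

Each number is the pixel mean over the named ROI, averaged over the five
subjects of the group; recovery to ~0.05% shows the B0 correction and the
contrast are unbiased at these noise levels. `analysis/03_multipool_fit.py`
does the same for the fitted hippocampal pool amplitudes (WT rNOE 15.32 vs
truth 15.4; AD 12.91 vs 12.9), `analysis/06_group_stats.py` runs the
statistical battery on the resulting tables (hippocampus and fimbria show
the largest AD decreases), and `analysis/05_registration.py` recovers a
known synthetic warp (mean label Dice 0.93 after the affine stage, 0.97
after demons refinement).

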