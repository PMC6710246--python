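# Methods

`batquant` quantifies brown adipose tissue (BAT) activity from three
modalities and relates them statistically. This note records the models, the
parameters that matter, the synthetic-data assumptions, and the numerical
choices, so that results can be interpreted and the package extended.

## PET kinetics

**Model.** The irreversible two-tissue compartment model (2TCM with k4 = 0)
describes FDG uptake: free tracer enters tissue at K1 (ml·ml⁻¹·min⁻¹),
returns to blood at k2 (min⁻¹), and is phosphorylated (trapped) at k3
(min⁻¹). The tissue concentration is

    C_T(t) = Ki·∫₀ᵗ Cp ds + A·(Cp ⊛ e^{−θt}),   Ki = K1·k3/(k2+k3),
    θ = k2+k3,  A = K1·k2/(k2+k3),

with Cp the plasma input. The basis-function method precomputes the
convolution term on a grid of 50 log-spaced clearance rates θ ∈ [0.02, 1.0]
min⁻¹ plus one irreversible basis (the running integral of Cp), and solves,
per voxel and per grid θ, the two-parameter non-negative linear fit
C_T ≈ Ki·B_irr + A·B_θ, keeping the θ with the smallest weighted residual.
The 2-variable NNLS is solved in closed form (KKT case enumeration) and
vectorised across voxels; ties go to the smaller θ. No blood-volume term is
fitted (the simulator's vb is a deliberate model-mismatch knob).

**Input function.** The whole-blood curve is the mean over an aortic ROI
(the lowest 5 slices dropped by default — edge-of-FOV quality); plasma =
1.1 × whole blood. Frame values are placed at frame midpoints and linearly
interpolated onto a 0.5-s fine grid, anchored at zero at t = 0. Midpoint
placement differs from the frame mean by a few percent on long frames of a
curving input; this is the dominant IDIF roundtrip error.

**Weights.** Per-frame weights default to frame duration (counting-statistics
proxy); uniform weighting is available via `frame_weighting="uniform"`.

**Frame model.** Model values are frame averages (integral over the frame
divided by duration), matching how PET frames are acquired, computed from the
fine-grid cumulative trapezoid.

**GUR.** GUR = Ki × mean(serum glucose pre, post) × 100 / LC in
µmol·(100 ml)⁻¹·min⁻¹, with lumped constant LC = 1. Total depot GUR sums
GUR × voxel volume (ml)/100 over the segmentation, in µmol/min.

**Accuracy.** On the default 45-min schedule (35 frames: 1×10, 8×5, 4×10,
2×15, 3×20, 2×30, 6×60, 4×150, 5×300 s), noiseless Ki recovery error is
bounded by the θ-grid quantisation (≲0.1% in Ki for mid-grid truths); with
5% frame noise the median relative Ki error is ~2%. The late-frame (>20 min)
Patlak slope agrees with the basis-function Ki to <1% once the exponential
transient has cleared (θ ≳ 0.4 min⁻¹); at θ ≈ 0.2 min⁻¹ Patlak itself is
still ~8% biased within 45 min, so the cross-check is only meaningful for
fast-equilibrating tissues.

## Water-fat MRI

**Multi-echo.** Magnitude-domain nonlinear least squares of

    |S(TE)| = M·|(1−FF) + FF·c(TE)|·e^{−R2*·TE}

with c(TE) a fixed six-peak triglyceride spectrum (shifts −3.80, −3.40,
−2.60, −1.94, −0.39, +0.60 ppm; relative amplitudes 0.087, 0.693, 0.128,
0.004, 0.039, 0.048, normalised), at 3.0 T by default. Multi-start
initialisation (FF ∈ {0.1, 0.9} × R2* ∈ {0, 100} s⁻¹) resolves the
water-fat dominance ambiguity of magnitude fitting; best residual wins, ties
to the lower R2*. Bounds: FF ∈ [0,1], R2* ∈ [0, 500] s⁻¹. Voxels with peak
magnitude below 10⁻⁶ of the volume maximum are flagged undefined (NaN)
rather than fitted. Magnitude fitting avoids phase/field-map estimation but
is noise-biased at low SNR and cannot separate FF from 1−FF without the
multi-start; both limitations are inherent to the design.

**Dual-echo.** Two-point separation at TE = 1.1/2.2 ms solves
S(TE_j) = W + F·c(TE_j) per voxel, neglecting R2* decay and B0 offset. At
R2* = 44 s⁻¹ this biases FF by about +0.013 at FF = 0.85 — acceptable on
synthetic data, documented as biased on real data. FF maps are F/(W+F),
NaN where W+F = 0.

## Segmentation

Rules follow the wording of the quantification protocol exactly:

- initial BAT mask: GUR **>** 10 µmol/100 ml/min (strict), minus a removal
  mask (file-based stand-in for manual editing of non-BAT uptake);
- refinement of a rough multi-echo delineation, in order: remove FF **<**
  0.40, 6-neighbourhood erosion, remove R2* **>** 120 s⁻¹ (strict removals:
  FF = 0.40 survives, R2* = 121 is removed);
- fat mask: include FF **≥** 0.40 (inclusive), then erode;
- dual-echo BAT FF is averaged over the intersection of the transferred
  refined mask and the fat mask.

Erosion uses the face-connected element with volume borders treated as
background. Slice exclusions (6+6 on the resampled GUR grid, 3+3 on the
multi-echo grid, slice axis = third voxel axis) zero the excluded slices so
they cannot contribute to masks or means. Map resampling is trilinear via
the voxel-to-world affines; masks are resampled nearest-neighbour to
preserve binarity.

## Thermography

The camera signal model is S(T) = R1/(R2·(e^{B/T_K} − F)) + O, a Planck-law
proxy with documented default calibration constants (R1 = 21106.77,
R2 = 0.012545258, B = 1501.0682, O = −7340, F = 1); vendor cameras carry
factory values, so recovery is validated by generate→process roundtrip, not
against any SDK. Atmospheric transmission uses the standard two-path
water-vapour model (X = 1.9, α₁ = 0.006569, α₂ = 0.01262, β₁ = −0.002276,
β₂ = −0.00667; humidity exponent coefficients 1.5587, 0.06939, −2.7816e−4,
6.8455e−7) with reflected temperature defaulting to atmospheric. Raw-signal
compensation: S_obj = (raw − (1−ε)·τ·S_refl − (1−τ)·S_atm)/(ε·τ), then
Planck inversion; emissivity 0.98 for skin. Missing humidity values are
imputed with the mean of the present ones. Window means: "neutral" is the
mean of per-frame ROI means over the first 5 frames, "cold" over the final
10 frames of a ≥15-frame series (35 one-per-minute frames by default).
The roundtrip is exact to <10⁻¹⁰ °C noise-free; the 0.01 °C tolerance quoted
in tests leaves room for float32 frame storage.

## Regressions

OLS with intercept (statsmodels), adjusted R² = 1 − (1−R²)(n−1)/(n−p−1),
two-sided t-test p-values, unadjusted for multiplicity. The pre-specified
set is seven simple models (SCF_neutral, SCF_cold, PNR_neutral, PNR_cold,
FF₂e, FF₁₅e, R2* against total BAT GUR) and four multiple models
(SCF_neutral+PNR_neutral, SCF_neutral+SCF_cold, SCF_cold+PNR_cold,
FF₁₅e+R2*), with significance at p < 0.05 and trend at p < 0.10. FF columns
carry percent units in I/O tables (`bat_ff2e_pct`, `bat_ff15e_pct`); the
fat-water module works in fractions and the pipeline converts once, at row
assembly.

## Synthetic data

The generators define the study conditions and what passing tests demonstrate:

- **Input function**: Feng-type (linear upslope × fast exponential + two
  slow exponentials, delay 0.4 min). Parameters are arbitrary but
  FDG-plausible defaults, not measured values.
- **PET phantom**: per-label 2TCM curves plus Gaussian frame noise with
  variance ∝ 1/frame duration (sd normalised at the mean duration); an
  aorta label carries the whole-blood curve (plasma/1.1). No decay,
  randoms, scatter, partial volume, or anatomy.
- **MR phantom**: the same signal model as the estimator plus complex
  Gaussian noise — recovery tests therefore check estimator correctness,
  not robustness to model mismatch (no B0/B1 inhomogeneity, no T1 bias,
  single R2* per voxel).
- **IRT**: frames built by exactly inverting the compensation model, plus
  optional Gaussian raw-signal noise. Roundtrip tests validate internal
  consistency, not camera calibration.
- **Cohorts**: 12 subjects by default; predictors drawn independently with
  means/sds matching the study population (SCF_cold 33.88 ± 0.65 °C, FF₁₅e
  79.8 ± 7.1%, R2* 44 ± 11 s⁻¹, …); response = −1591 + 48.07 × SCF_cold +
  ε, ε ~ N(0, 27.5²) µmol/min. The residual sd follows from the published
  effect size and fit quality (slope × predictor sd ≈ 31, adjusted R² ≈ 0.5
  at n = 12 → response sd ≈ 42, residual ≈ 27.5). A single driver keeps the
  generative model identifiable; the other predictors are null, so their
  regressions test calibration of p-values rather than power.

The study-condition noise magnitudes are not specified anywhere; defaults (0 for identity
tests, 2–5% where noise is the point) are placeholders chosen to exercise
the estimators, and every stochastic test fixes its seed.

## Problem sizes and determinism

Tests and the acceptance script use deliberately small instances: single-TAC
fits for the kinetic grids (the voxel map is the same vectorised code path,
exercised on a 10×10×16 phantom end-to-end), 20³ masks for the erosion
oracle, 100 noise replicates for kinetics, 500 cohorts for CI coverage, one
10 000-subject cohort for slope recovery. All randomness flows from explicit
seeds; identical seeds give bit-identical phantoms, cohorts and results.

## Known limitations

- No field-map/complex Dixon: magnitude fitting and zero-offset two-point
  separation are biased on real data with B0 inhomogeneity.
- Midpoint resampling of the IDIF (not frame-mean deconvolution) biases the
  plasma curve by a few percent on long frames.
- Mask transfer assumes aligned affines; no registration.
- The Patlak cross-check requires fast equilibration (θ ≳ 0.4 min⁻¹).
- Degenerate trapping (k2 = k3 = 0 with K1 > 0) is rejected rather than
  modelled.
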