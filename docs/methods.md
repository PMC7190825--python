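# Methods

## Signal models

All delivery signals are instances of one single-compartment kinetic model:
a rectangular bolus of inverted arterial blood water arriving at transit
time δ with temporal width τ, decaying at the blood longitudinal rate
R1a = 1/T1_blood before delivery and at the destination compartment's
apparent rate R1app afterwards. Integrating the delivery convolution gives

    ΔM(TI) = (2 M0 f α / φ) exp(−TI·R1app)
             [exp(min(TI, δ+τ)·ΔR) − exp(δ·ΔR)] / ΔR,   ΔR = R1app − R1a,

zero for TI ≤ δ. ΔR is implemented as R1app − R1a; the degenerate case
|ΔR| < 1e−6 s⁻¹ switches to the analytic limit
(2 M0 f α/φ)·exp(−TI·R1app)·(min(TI, δ+τ) − δ), below which scale
double-precision cancellation would dominate the quotient. A numerical
quadrature oracle (`delivery_convolution_oracle`, scipy adaptive quadrature
at 1e−12 tolerance) integrates the same convolution directly and is used in
the tests to verify both closed forms to 1e−8 relative error over
randomised parameters; the closed forms agree with it to ~1e−14 in
practice.

Two physical configurations share this solution:

* **Ventricular delivery (BCSFB).** Destination is ventricular CSF; f is
  the delivery rate of labelled blood water to CSF; R1app is the apparent
  CSF relaxation rate, estimated in the pipeline from the long-TE control
  signal; φ is the blood–CSF partition coefficient (default 1). No
  intravascular term: at TE = 220 ms blood signal is nulled.
* **Cortical perfusion (pulsed-ASL general kinetic model).** The fitted
  rate is the tissue-magnetisation-normalised delivery rate k = f/λ, which
  appears both as the amplitude (since M0_blood = M0_tissue/λ) and as the
  venous-clearance term in the apparent relaxation 1/T1′ = 1/T1_tissue + k.
  CBF in ml/100 g/min is k·λ·6000 at unit tissue density. This is the only
  parameterisation in which the amplitude, the clearance term and the
  reporting convention are mutually consistent, and it matches the
  convolution oracle exactly.

The inversion-recovery model for control data is
M0·(1 − 2β·exp(−TI/T1)) with an inversion-efficiency factor β (free by
default, initialised at 1.0, pinnable via config): magnitude mouse data
rarely achieve perfect inversion, and with signed data β is well
identified by the earliest TIs. Data are assumed signed; a magnitude mode
takes absolute values and restores polarity by null-point search over all
candidate sign splits, keeping the split with the best residual.

All times are seconds and rates s⁻¹ internally; only the reporting layer
converts (×6000 to ml/100 ml/min; mm³ ≡ µl; µl/(min·mg) ≡ ml/(min·g)).

## Estimation

All fitters use bounded trust-region least squares
(`scipy.optimize.least_squares`, method `trf`, tolerances 1e−14),
unweighted residuals (no weighting scheme is part of the measurement
design). The δ/τ trade-off of the kinetic models produces a shallow RSS
valley, so both kinetic fitters multi-start over δ ∈ {0.2, 0.5, 1.0} s and
keep the best-RSS solution, breaking ties towards the smaller δ. Bounds:
f ∈ [0, 0.1] s⁻¹, δ ∈ [0, max TI], τ ∈ [0.1, 10] s, T1 ∈ [0.1, 10] s,
β ∈ [0.2, 1]. τ is free by default — the FAIR bolus width is
geometry-dependent and not generally known — and can be pinned via
`fix_tau`. Standard errors come from the Gauss–Newton covariance
s²(JᵀJ)⁻¹; an all-zero difference series short-circuits to f = 0 exactly,
and a constant control series is flagged as non-converged (it carries no T1
information). The two-point apparent-diffusion fit uses the closed form
d = ln(S₁/S₂)/(b₂−b₁); more b-values use log-linear least squares.

## Quantification pipeline

Per subject: pairwise control−label subtraction averaged over repetitions
(sign convention configurable) → ROI summation → inversion-recovery fit of
the ROI control signal per echo time (M0 and T1 of cortex at TE = 20 ms; M0
and T1 of CSF at TE = 220 ms) → ventricle-volume correction
M0corr = M0 × V_ROI/V_ventricles → kinetic fits of ΔM/M0 (cortex) and
ΔM/M0corr (ventricles) → unit conversion. R1app for the ventricular fit is
1/T1_CSF from the long-TE control fit; the cortical fit fixes T1_tissue
from the short-TE control fit. Errors raised mid-pipeline are labelled with
the stage that failed.

The M0 correction is the step that makes the delivery estimate independent
of ventricle size: the ROI-summed ΔM is proportional to total delivered
label (independent of V_vent at fixed total delivery), while the
uncorrected M0 is proportional to V_vent. After correction both numerator
and denominator are ventricle-size-free, which the tests verify as ≤1 %
drift over V_vent ∈ [2, 5] mm³.

Cohort statistics: pooled two-sample t-test (Welch optional), one-tailed by
default; Pearson correlation with the two-sided t-distributed p; mean
absolute scan–rescan difference. The tests check both p-values against
label-permutation oracles. No multiple-testing correction is applied
(single planned comparisons). An optional, logged ±2 SD outlier exclusion
exists but is off by default. Per-fit standard errors are reported even
though group dispersion is usually summarised as SEM across animals.

## Synthetic data

`make_phantom` builds a 32×32 single slice (FOV 20×20 mm, 2.4 mm slice,
voxels 0.625×0.625×2.4 mm = 0.9375 mm³): a cortical band and two caudal
3×2-voxel ventricle blobs that define the 12-voxel (11.25 mm³) functional
ROI. CSF content is stored as per-voxel partial-volume fractions that
integrate exactly to the requested ventricle volume (default 3.75 mm³,
i.e. 4 voxels' worth spread over 12 voxels), so the M0-correction test is
meaningful. By default the non-CSF remainder of ROI voxels is empty;
`ventricle_tissue_fraction` can fill it with tissue to emulate parenchymal
partial-volume contamination (suppressed ~300× at TE = 220 ms).

Truth convention: `f_bcsfb_true` is stated in the reporting unit
(ml/100 ml/min) tied to the fixed functional-ROI volume, matching the
arithmetic total delivery = f/100 × 11.25 mm³ (= 2.7 µl/min at f = 24).
The simulator converts it to the native per-unit-CSF rate
f_csf = (f/100 × V_ROI)/(60 × V_vent) s⁻¹. The printed unit "per 100 ml of
CSF" and this ROI-volume normalisation are in tension; the package follows
the arithmetic that reproduces the total delivery rate, and this paragraph
documents the choice.

`simulate_acquisition` composes, per voxel and compartment: control =
inversion recovery × T2 attenuation at the protocol TE; label = control −
ΔM forward model × the same attenuation; optional diffusion weighting
multiplies each term by exp(−b·d) with d = 3.0e−3 mm²/s for CSF (free
water), 0.8e−3 for tissue, and an IVIM-elevated pseudo-diffusion
coefficient 1.0e−2 for the vascular part of the short-TE label — so the
ventricular ASL signal carries the CSF coefficient while the conventional
ASL signal shows an elevated apparent diffusion, as the hybrid
diffusion-ASL control experiment expects. Noise is additive Gaussian per
repetition (per-voxel SD `noise_sd`); ROI-level SNR therefore scales as
√repetitions. A Rician option exists for magnitude-reconstruction studies;
the Gaussian default is justified by the ROI-summed high-SNR regime.

Defaults and their rationale:

* Relaxation (mouse, 9.4 T): T1 blood 2.4 s, T1 CSF 4.0 s, T1 tissue
  1.7 s; T2 38/30/200 ms (parenchyma/blood/CSF); φ_CSF = 1, λ_tissue = 0.9.
* Kinetics: δ_CSF = 1.0 s (delivery via the CP lags tissue arrival),
  δ_cortex = 0.3 s, τ = 4.0 s for both (wide FAIR bolus).
* Labelling efficiency α = 1.0 by default (the value assumed in
  quantification is configurable).
* M0 densities 100 (CSF) and 80 (tissue) signal units/mm³ — arbitrary
  scanner units with a water-content-like ratio.
* `noise_sd = 0.2`: calibrated so the ventricular ΔM peak is ≈10× the
  ROI-summed noise SD after 20-repetition pairwise averaging (the
  ventricular signal is ~10 % of the conventional ASL signal, and the
  protocol's 20 repetitions exist precisely to reach this regime).
* Cohort generator: adult/aged means 20/13 ml/100 ml/min and 251/218
  ml/100 g/min; between-subject SDs 3.5 and 24 are printed-SEM × √n
  inferences at n = 12; ventricle volumes N(3.5, 0.75²) mm³ clipped to
  [1, 10]; scan–rescan within-subject SD 1.15 (so the expected mean
  absolute difference is 2·1.15/√π ≈ 1.3 ml/100 ml/min); an optional
  flow–volume slope induces the delivery/ventricle-volume correlation with
  the residual SD reduced to keep the marginal f SD fixed.

What the simulator does **not** emulate: CSF pulsation and bulk motion,
partial-volume geometry beyond a two-compartment mixture, B1/B0
inhomogeneity, labelling-efficiency spatial variation, and Rician floor
effects at very low SNR (unless the Rician flag is set). Passing tests
therefore demonstrate the correctness and self-consistency of the
quantification chain under the stated acquisition model, not robustness to
those physical confounders.

## Problem sizes

The test suite and the results script run single-slice 32×32 phantoms with
6 TIs and 5/20 repetitions, cohorts of 11–12 subjects quantified end to
end, a 200-replicate Monte-Carlo bias check of the ventricular fitter,
100-draw oracle-agreement sweeps, and 20 000-permutation oracles for the
statistics — the full suite completes in well under a minute.

## Known limitations

* ROI-level quantification by design (a global measure per ventricle); no
  voxelwise maps, registration or segmentation.
* The CP blood-flow conversion divides group-level quantities; computed on
  group means it differs slightly from averaging per-animal values.
* The one-compartment model ignores back-transfer of labelled water from
  CSF into CP tissue and dispersion of the bolus.
* The human pCASL variant of the measurement is out of scope.
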