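# Methods

## Kinetic model

The simplified reference tissue model (SRTM) describes a target region's
decay-corrected time-activity curve (TAC) as

C_T(t) = R1·C_R(t) + (k2 − R1·k2a)·∫₀ᵗ C_R(s)·e^(−k2a·(t−s)) ds,
k2a = k2/(1 + BP_ND),

where C_R is the reference-region TAC (bilateral cerebellar grey matter used
as a pseudoreference), R1 = K1/K1′ the tracer delivery ratio, k2 the target
efflux rate (1/min) and BP_ND the non-displaceable binding potential. The
reported binding outcome is the distribution volume ratio DVR = BP_ND + 1.
The model assumes both tissues are well approximated by one compartment, a
common non-displaceable distribution volume, and a reference region whose
specific binding — though non-zero for this ligand — is uniform across
subjects. All TACs are assumed decay-corrected; the package contains no decay
handling anywhere.

### Numerical evaluation

The reference curve is interpolated piecewise linearly through the
post-injection frame midpoints, anchored at (0, 0) and held constant from the
last midpoint to the final frame end. The exponential convolution is
evaluated analytically per linear segment via the recurrence
I(t+h) = I(t)·e^(−λh) + c(h), and frame values are *frame averages* obtained
by analytic integration (∫I = (∫C_R − ΔI)/λ per segment), not midpoint
samples — frames range from 5 s to 10 min, so midpoint sampling would bias
early frames. No FFT or discretisation grid is involved, which avoids
resolution artefacts on the irregular clinical schedules.

For a measured reference TAC the linear term R1·C_R uses the measured frame
values directly (they already are frame averages); the interpolant enters only
through the convolution. This is the standard basis-function convention and
makes the identity case exact: a target equal to the reference returns R1 = 1,
BP_ND = 0 bit-exactly.

### Fitting

`fit_srtm_basis` sweeps 256 logarithmically spaced k2a values on
[0.005, 1.0] /min — bracketing plausible PK11195 kinetics — solving a
2-parameter weighted linear least-squares problem per grid value, then
refines the winning k2a by golden-section search on the log scale between its
grid neighbours. Weights default to frame duration (variance ∝ 1/duration
under the noise model below); a uniform option exists. Background frames are
excluded. Solutions at a grid endpoint are flagged (`boundary_flag`), never
clamped silently; negative BP_ND is admitted down to the grid ceiling.

When θ2 = k2 − R1·k2a ≈ 0 the target is proportional to the reference and
k2/k2a are not separately identifiable; the ridge relation k2 = R1·k2a still
pins BP_ND = R1 − 1, which the fit reports together with a `degenerate_flag`
(an all-zero target reports zeros). `fit_srtm_nls_oracle` is an independent
multi-start nonlinear least-squares fitter over (R1, k2, k2a) used as a
brute-force cross-check; the two agree to ≈1e-7 in BP_ND on noiseless data.

SUV_40-60 is the overlap-weighted mean concentration over 40–60 min times
body weight over injected activity (dimensionless at 1 g/mL tissue density).

## Synthetic cohorts

The generator emulates a two-centre study: 50 subjects on an 18-frame
schedule with a 6-min pre-injection background frame and 26 subjects on a
17-frame schedule, both covering 60 min post-injection. Per subject:

* a global DVR intercept ~ N(0, `subject_sd` = 0.04), shared across regions;
* per region, side DVRs `DVR_bilat·(1 ± rel/200) ± pair/2` with
  pair ~ N(0, `pair_sd`), so the configured signed relative difference
  (positive = right > left) is exact in expectation on the DVR scale;
* R1 ~ N(1.0, 0.05) per region×side; k2 = R1·k2_ref with k2_ref = 0.15 /min;
* covariates (age, sex, handedness including an unknown fraction, injected
  activity, body weight) drawn per centre from the published demographic
  structure; covariate effects on DVR are zero by construction (the study
  conditions include null age/sex/handedness/centre effects);
* the reference TAC is a bi-exponential surge amp·(e^(−0.05t) − e^(−0.5t)),
  the simplest realistic peak-then-washout shape with a closed-form peak for
  testing; amp scales with injected dose per kg (6 kBq/mL per MBq/kg);
* frame noise is Gaussian with σ = α·sqrt(max(value, 0.05)/Δt), i.e.
  variance ∝ value/duration on decay-corrected data — no decay-factor term,
  keeping σ analytic for tests; negative outputs are permitted as in real
  decay-corrected PET;
* one RNG stream per subject, spawned from (master seed, subject index), so
  enlarging a cohort never reshuffles earlier subjects.

Default regional baseline DVRs and injected asymmetries follow the reported
healthy-cohort pattern (grey matter +1.87%, whole brain +1.90%, putamen
+3.55% … occipital +0.76%). The within-subject scales are not published;
`pair_sd` = 0.015 and `noise_alpha` = 0.13 were calibrated once so the paired
Cohen's d of *fitted* grey-matter DVRs averages ≈ 1.1 at the default cohort
size, and then frozen. A single scalar `pair_sd` is used, so simulated
per-region effect sizes track the injected relative differences rather than
reproducing each region's published d independently.

What the generator does **not** emulate: partial-volume and resolution
effects, attenuation/scatter residuals, co-registration errors, plasma-input
kinetics, metabolite correction, or biological covariate effects. Passing
tests therefore demonstrate the correctness and calibration of the
quantification and inference chain under the stated generative model, not
robustness to those real-data confounds.

Volumes receive their own signed asymmetries (subcortical leftward, cortical
rightward, parietal null) drawn independently of the DVR asymmetry, so the
volume-vs-DVR asymmetry correlation is null by construction, matching the
reported pattern. The phantom builder places mirror-image blobs on a small
grid and stamps each region's forward-model TAC into its voxels, with a GM
probability shell straddling the 0.5 threshold to exercise the inclusive
binarisation rule.

## Region handling

Grey-matter probability maps are binarised at ≥ 0.5; the inclusive boundary
keeps the printed threshold itself inside the mask (the boundary case is
otherwise unspecified). Composite regions are unions of atlas labels,
intersected with the GM mask for GM-tissue regions (cortices, grey matter,
cerebellum) and left unsegmented for thalamus, putamen and the whole-brain
composite. ROI statistics are unweighted voxel means after binarisation
(binarise-then-apply, not probability-weighted). The package default is to
fit the region-mean TAC; voxelwise fit-then-average is possible through the
same basis machinery but the two are not assumed interchangeable. Alignment
of images, labels and probability maps is the caller's responsibility.

## Statistics

* **Wilcoxon signed-rank** (paired, two-sided): zero differences dropped (a
  documented convention choice; all-zero yields p = 1 with a degenerate
  flag). Exact null distribution by dynamic programming over sign
  assignments for n ≤ 25 without ties; otherwise normal approximation with
  tie and continuity corrections. Two-sided exact p is the symmetric tail
  probability P(|W − μ| ≥ |w − μ|).
* **Mann-Whitney U** (two-sided): exact for min(n1, n2) ≤ 8 without ties,
  tie-corrected normal approximation otherwise.
* **Holm-Šídák**: step-down, adjusted_(i) = 1 − (1 − p_(i))^(m−i+1) on the
  sorted p-values, monotonised and capped at 1. The correction family is an
  explicit argument of the pipeline; the default family is the set of regions
  tested within one report block.
* **Shapiro-Wilk** and **Pearson** delegate to scipy (the t transform with
  n − 2 df for the correlation p-value).
* **Mixed model**: DVR ~ hemisphere + age + sex + handedness + centre +
  centre×hemisphere with a free per-subject random intercept, REML via
  statsmodels MixedLM. Reference levels: left hemisphere, female,
  left-handed, Manchester — chosen so the signs read "right vs left",
  "male vs female", "Turku vs Manchester". Subjects with unknown handedness
  are excluded before fitting. Satterthwaite degrees of freedom are not
  available in the backend, so Wald-normal standard errors, CIs and p-values
  are reported and labelled (`df_method = "wald_z"`); at the default cohort
  size the empirical 95% CI coverage of an injected hemisphere effect is
  94–95%. If a replicated draw leaves a categorical covariate without
  variation (e.g. no left-handed subjects after exclusion), that covariate is
  dropped for the run and recorded in the report; a genuinely singular
  user-specified design is rejected with the offending term named.

Quartiles throughout use linear interpolation between order statistics.
Cohort-level relative differences are computed from subject-level paired
differences (mean difference over the mean of the side means), since
medians of ratios do not compose.

## Replicated studies and problem sizes

The packaged simulation studies use these sizes, chosen to keep Monte-Carlo
error well below the decision thresholds: type-I calibration, 1000 replicate
cohorts at the table level (truth + pair noise — the Wilcoxon operates on
DVR tables, so TAC fitting adds nothing to a null calibration); headline
power, 200 seeds with full TAC simulation and fitting of the grey-matter and
whole-brain regions; DVR recovery, 500 single-region replicates plus a
200-seed bias sweep; mixed-model coverage, 200 cohorts at the table level
with the unknown-handedness exclusion applied. The acceptance script averages
cohort-level metrics over 12 replicate cohorts so reported values reflect the
calibrated expectation rather than one cohort's sampling noise.

## Known limitations

* The pseudoreference assumption (uniform cerebellar specific binding) is a
  modelling premise of the ligand literature, not something the package can
  verify from data.
* Wald-normal mixed-model inference is mildly anticonservative relative to
  Satterthwaite at small n; at n ≥ 67 the difference is within half a
  percentage point of coverage.
* The basis grid floor k2a ≥ 0.005 /min implies an upper bound on fit-able
  DVR of k2/0.005; fits at the floor are flagged rather than extrapolated.
* Image mode performs no registration, segmentation, atlas warping,
  partial-volume or spill-over correction; inputs must be pre-aligned.
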