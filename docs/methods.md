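# Methods

This note documents the models, estimators, numerical choices and known
limitations of the `oculobrain` pipeline, in the order the method runs.

## fMRI metric chain

The pipeline consumes 4-D volumes that are already realigned and on a
common grid (realignment, slice timing and spatial normalization are out of
scope; the synthetic generator produces post-realignment data directly).
Per subject:

1. **Volume discard** — the first `n_discard` frames (default 10 of 185)
   are dropped; motion rows are dropped in step.
2. **Linear detrend** — OLS residual of intercept + slope per voxel.
3. **Nuisance regression** — one OLS projection against intercept,
   Friston-24 motion expansion `[R, R², R_{t−1}, R_{t−1}²]` (lagged rows
   zero-padded at t = 0), the global mean signal over the subject brain
   mask, and optional WM/CSF means when masks are supplied. Rank deficiency
   raises an error naming the collinear columns.
4. **FALFF** — ratio of sqrt-power (|DFT|) summed over the closed band
   `f_lo ≤ f ≤ f_hi` (default 0.01–0.1 Hz) to sqrt-power over all positive
   frequencies. The DC bin is excluded (it carries only the mean). Two
   phrasings of this metric circulate ("ratio of power" vs. "average of the
   sqrt power spectrum"); the sqrt-amplitude convention implemented here is
   the one standard analysis toolboxes use. No band-pass filter is applied
   before FALFF — the band enters through the spectral ratio itself.
5. **ReHo** — Kendall's W with tie correction between each voxel and its
   in-mask subset of 26 neighbours, computed on series band-pass-filtered
   with a 4th-order zero-phase Butterworth (0.01–0.1 Hz). Neighbourhoods
   with fewer than two in-mask members, or with all-constant series, give 0
   with a warning rather than NaN.
6. **Standardization** — division by the mean over the brain mask, so the
   in-mask mean is exactly 1 (idempotent).
7. **Smoothing** — separable Gaussian with σ = FWHM/(2√(2 ln 2)) per axis,
   `scipy.ndimage` sampled-Gaussian kernel. The 4-mm FWHM smoothing is
   exposed for all maps but *off by default for functional maps*: the
   processing description ties the 4-mm kernel to cortical-thickness maps
   only, and unsmoothed functional maps keep the planted-blob geometry
   sharp for the recovery tests.

The group gray-matter mask is `mean(GM probability across subjects) ≥ 0.2`.
Voxel indices are 0-based; world coordinates follow the NIfTI affine.

## Retinal morphometry

Inputs are binary vessel and FAZ masks plus layer-thickness maps (µm) with
a pixel size in mm; segmentation itself (a deep-learning step in practice)
is out of scope. All component/boundary/skeleton operations use
8-connectivity; scans with quality index < 6 are rejected.

* **FAZ area** = pixel count of the largest connected component ×
  pixel_size². Multiple surviving components warn and use the largest.
* **FAZ perimeter** = length of the Moore-traced outer boundary polygon
  with unit and √2 segment weights, × pixel_size. This estimator is exact
  for axis-aligned rectangles (a 10×10-px square gives exactly 36 px) and
  sits a stable ~5% above the true circumference for smooth curves — the
  known bias of chain-code length, accepted here for its simplicity and
  exact testability; the tests pin the discretization band rather than
  asymptotic convergence. A single-pixel region has no closed contour and
  returns 0 with a warning.
* **Centerlines** — morphological thinning, junction pixels (> 2 skeleton
  neighbours) removed, remaining components ordered end-to-end; paths
  shorter than 5 px dropped.
* **RBVC** — per-point curvature κ = |x′y″ − y′x″|/(x′²+y′²)^{3/2} pooled
  (mean by default; median and length-weighted mean available) over all
  centerlines, reported in 1/px and 1/mm. Derivatives are taken along the
  sample index (skeleton spacing is near-uniform). Because a thinned mask
  carries a ±half-pixel staircase whose folded |κ| would otherwise dominate
  the mean, coordinates are first Gaussian-smoothed along the path
  (σ = 7.5 samples, mirror padding so straight runs stay exactly straight)
  and differentiated with wide central differences (spacing 6); 8 samples
  at each path end are excluded, where thinning rounds the vessel tips.
  These constants were fixed once against analytic oracles: straight lines
  at arbitrary angles measure ≤ 1e-3 px⁻¹, rasterized circular arcs are
  within a few percent of 1/R, and sinusoidal perturbations respond
  monotonically in amplitude. `path_curvature` on exact coordinate paths
  uses plain `np.gradient` central differences with no smoothing.
* **Layer thickness** — arithmetic mean over the region (whole map by
  default).

## Association engine

The per-element model is OLS of
`Y = β0 + β1 x_obj + β2 age + β3 sex + β4 edu + β5 hyp + β6 dia [+ β7 ETIV]`
with `t = β1/SE(β1)` on n − k − 1 df. ETIV is included exactly when
`x_obj` is cortical thickness. Covariate columns with zero variance in the
analysis sample (e.g. no diabetics in a small pooled pair) are dropped with
a warning; genuinely collinear designs are an error. Missing data are
deleted listwise upstream with a logged count.

**Stage 1 (voxel-wise).** The cognitive score is `Y`; every in-mask voxel
supplies `x_obj`. FWE control uses the permutation max-|t| distribution
with Freedman–Lane residual permutation: the score is residualized against
the covariates, residuals are permuted (the identity permutation is always
included, making the test valid — slightly conservative — at any n_perm),
re-projected, and the max over voxels of |t| recorded; selection keeps
voxels with |t| ≥ the (1−α) quantile (`method="higher"`). The whole
permutation loop is vectorized via the Frisch–Waugh partialling identity,
so one matrix product per cohort covers all voxels × permutations. The
mechanism behind the published "p < 0.05 with FWE" is not stated in the
source analysis; permutation max-|t| was chosen because it is
assumption-light, exactly valid at desk scale, and verifiable by
simulation. Random-field theory and cluster-extent inference are
non-goals. Inference is voxel-level, matching peak-location reporting.

**Stage 1 (ROI-wise).** Cortical thickness over the 62 DKT ROIs
(31 per hemisphere), selected by `p < 1/62` — strict inequality at the
boundary.

**Stage 2.** The ophthalmic biometric becomes `Y`, tested *only* at
elements selected in stage 1, with permutation FWE (voxels) or Bonferroni
1/|domain| (ROIs) over the reduced domain. Nesting (stage 2 ⊆ stage 1) is
asserted on every run. An empty stage-1 selection yields an empty stage-2
result with a warning. Peaks are the maximum |t| in the selection, ties
resolved to the smallest linear index; direction statements are encoded as
the sign of β1 with the biometric as Y.

Group-pair analyses pool HC with one patient group into a single
regression sample; group membership is not a covariate (it does not appear
in the model above). Open question resolved: the stage-1 voxel-wise model
places cognition as `Y` and the brain metric as `x_obj`, following the
model equation.

## Synthetic cohort: what it emulates and what it does not

Group sizes (16/35/18/7), per-group age means/SDs and sex, hypertension
and diabetes prevalences follow the published cohort table; education and
ETIV use plausible values for an elderly memory-clinic sample (medians
around 12 years; ETIV 1.45×10⁶ ± 1.4×10⁵ mm³). Cognitive scores are
continuous Gaussians around per-group baselines anchored to the published
medians (optional rounding to native scales is available but off by
default, keeping regression assumptions transparent). Sex and the
comorbidities are coded 0/1.

A `PlantedEffect` draws a latent `N(group shift, 1)` per subject — default
shifts 3.0/2.5/1.8/1.0 for HC/SCD/MCI/AD, a positive scale so the fMRI
amplitude below stays linear in the latent over essentially the whole
cohort — and couples it to:

* a **brain target**: inside a spherical voxel blob, an in-band (0.05 Hz)
  sinusoid of amplitude `brain_slope × latent` (per-voxel random phase;
  FALFF channel), or a shared band-limited component scaled the same way
  (ReHo channel), or a DKT ROI thickness shift `brain_slope × latent`.
  A latent of exactly zero therefore produces *no* signal — the null
  construction used by the calibration tests;
* a **cognitive score**: baseline + `cognitive_slope × (latent − group
  shift)` (the group-level score structure lives in the baselines, the
  latent adds within-group covariation);
* an **ophthalmic biometric**: base + `ocular_slope × (latent − HC shift)`,
  so HC stays at base and disease groups shift. The default couples FAZ
  area with a negative slope: a lower latent (more disease-like) enlarges
  the FAZ.

Default slopes (brain 0.45 amplitude-units/latent, BDST 1.0 point/latent,
FAZ −0.05 mm²/latent against noise SDs 1.0 / 1.0 / 0.012) were fixed once
by a design power simulation at the default cohort size so that stage 1
detects the blob in ≳90% and stage 2 in ≳80% of replicates — the regime
the recovery studies are meant to probe.

fMRI volumes are generated *post-realignment* on a common grid; the default
grid is deliberately small (20×20×12 at 3 mm, 185 frames, TR 2 s) so full
pipelines run in minutes. Gray matter is an ellipsoid probability map
(≥ 0.5 inside); motion parameters are smooth random walks far below the
3 mm/3° exclusion bounds (the emulated study excluded nobody). Retinal
images are 3×3-mm en-face canvases: the FAZ is a filled near-circular
ellipse whose pixel area matches the subject's target; vessels radiate from
outside the FAZ to the canvas edge with a sinusoidal perpendicular
perturbation (wavelength 60 px) carrying any tortuosity effect; angular
jitter is bounded to a fraction of the inter-vessel spacing and the start
radius floored at 0.16 × image size, so adjacent vessels cannot merge at
their origin on small canvases. One eye is modelled per subject (whether
eye substitution alters biometric distributions is unknown; the pipeline
takes one image set per subject). Layer maps are constant-plus-noise
fields whose mean equals the subject's target.

Passing tests on this generator demonstrate that the *pipeline* recovers
plantings and controls its error rates under the stated noise model. They
do not show robustness to hemodynamic response shape, scanner artifacts,
physiological noise spectra, realistic fundus optics, segmentation error,
or spatial misregistration — none of which the generator emulates.

## Simulation scales and numerical choices

Calibration and recovery studies run the full 76-subject cohort on a
compact 10×10×6 grid (`synthetic.compact_cohort_config`), which keeps the
per-voxel statistics — 175 retained frames, n = 76, default effect sizes —
at study scale while letting hundreds of replicate cohorts finish in
minutes on one CPU: 200 null replicates for the family-wise error check
(bound: 0.05 + 2·binomial SE) and 100 replicates for stage-2 recovery
(≥ 80% with the planted sign), at 500 permutations per replicate.

Tolerances: detrend/projection identities at 1e-10…1e-8 relative;
standardized map means at 1e-12; smoothing vs. dense convolution at 1e-8;
χ² uses no continuity correction (this reproduces the published 2×4-table
statistics); ANOVA-from-summary is algebraically identical to the raw-data
form and matches the published age F within the rounding of the published
summaries (±0.01). Degenerate inputs never produce NaN: constant series,
single-pixel regions and empty selections give 0 or an empty result with a
warning, and empty masks or invalid bands are errors.

All randomness flows from named integer seeds through per-subject,
per-channel `numpy` SeedSequences; identical configs give byte-identical
cohorts, metric maps and reports.

## Known limitations

* The FWE mechanism, FALFF phrasing ambiguity and RBVC
  aggregation/parameterization had to be fixed by choice (documented
  above); other choices would change absolute values.
* Chain-code perimeter has a ~5% positive bias on smooth curves and does
  not converge to the true circumference with resolution.
* Skeleton-based curvature is scale-limited: features with radius of
  curvature below ~10 px are attenuated by the coordinate smoothing.
* The ROI stage treats thickness values as given; no surface-based
  smoothing or vertex-level inference is provided.
* Stage-2 conditioning on a data-selected mask is inherited from the
  emulated design; selection effects on stage-2 coefficients are not
  corrected beyond the reduced-domain FWE.
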