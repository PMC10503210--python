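# Methods

This note records the models implemented in `wbatlas`, the defaults that
matter, what the synthetic phantom does and does not emulate, and the
design choices made where the design was genuinely open.

## Signal model and ADC fitting

Diffusion-weighted signal is modelled per voxel as the mono-exponential
S(b) = S0 · exp(−b · ADC), with ADC in mm²/s (reports print ×10⁻³ mm²/s).
`dwi.fit_adc` performs unweighted ordinary least squares of ln S(b) on b —
slope = −ADC, intercept = ln S0 — over a configurable b-value subset
(default: all; the pipeline convention is b = 50/400/900 s/mm², leaving
b = 0 out of the fit). Two deliberate conventions:

- Voxels with any non-positive signal among the fit b-values are marked
  invalid rather than clamped: the logarithm is undefined there and an
  explicit validity mask keeps downstream statistics honest.
- Negative fitted slopes (signal increasing with b, possible under noise)
  are clamped to ADC = 0 and flagged in a separate `clamped_mask`,
  matching the physical non-negativity of reported ADC.

With two b-values the fit reduces to the closed form
ln(S(b1)/S(b2))/(b2−b1); the test suite checks this equivalence, the
scale equivariance of the fit (ADC invariant, S0 ∝ c under S → cS), and
exact recovery of configured tissue ADC from noiseless signals.

## Computed DWI

`compute_cdwi` extrapolates a measured image to a higher b-value:
cDWI(b_t) = S(b_s) · exp(−(b_t − b_s) · ADC). The voxel-wise variant
`compute_vcdwi` evaluates each voxel at its own computed b-value
b_vox = min(b_cap, 1/ADC) and rescales by e¹, so every voxel with
ADC ≥ 1/b_cap sits at its fitted S0 — low-ADC, high-S0 (lesion-like)
voxels are then at least as bright as the measured b = 900 image. Above a
free-fluid cutoff (default 2.0 × 10⁻³ mm²/s) an exponential rolloff
0.1 · exp(−(ADC − cutoff) · 2000) suppresses T2 shine-through strictly
below the measured b = 900 intensity. The exact published formula for
voxel-wise computed DWI is not reproduced in the source this pipeline
follows, so the function is pluggable; the defaults (b_cap = 3000 s/mm²,
rolloff constants above) were chosen analytically so that the
brighter-than-measured property holds for *every* sub-cutoff ADC and the
suppression property for every supra-cutoff ADC under the noiseless
forward model. They are implementation defaults, not published values.

## Station composition and intensity harmonisation

Stations are slabs along z sharing `overlap_slices` slices. Composition
removes an equal number of overlapping slices from adjacent stations —
ceil(overlap/2) trailing slices from the superior station and
floor(overlap/2) leading slices from the inferior one (the parity split
is a convention; "superior"/"inferior" keep-rules are available) — and
copies retained slices verbatim, never blending. Head-to-neck gain
differences are removed by `histogram_match_overlap`: a monotone
quantile mapping (501 quantiles, linear interpolation) estimated between
the two stations' overlap slices and applied to the whole head station;
monotonicity preserves within-station intensity ranks exactly.
Whole-body intensity normalisation divides by the in-mask 75th
percentile, then maps [min, p99.99] → [0, 1] with clipping, so a single
extreme outlier cannot set the scale. Percentiles use linear
interpolation between order statistics for bit-reproducibility.

## Masks and regularisation weights

The body mask thresholds W+F (default: Otsu computed on log intensities
of non-zero voxels, which separates the noise floor from tissue even when
tissue classes span an order of magnitude), then applies morphological
closing (5 mm ball, array padded to avoid border clipping), slice-wise
hole filling, and largest-component selection. Arm removal, when enabled,
drops in-plane components whose centroid lies laterally outside a
configurable fraction (default 0.40) of the torso half-width — the
published pipeline removed arms but not by a stated method.

The inside-SAT mask replaces a trained interactive segmentation with a
deterministic rule: within the requested slice range, high-FF voxels
(FF > 0.5) 26-connected to the body boundary form the subcutaneous shell
and are peeled off; high-FF islands with no boundary path (visceral fat)
are retained. An externally produced SAT mask can be substituted wherever
a `MaskSet` is consumed.

Regularisation weights blend linearly, w = (w_fat·FF + w_lean·WF)/(WF+FF)
(background w_lean; defaults w_lean = 1.0, w_fat = 0.2). The underlying
requirement is only that weights follow voxel-wise water/fat content
monotonically; linear blending is the minimal such choice and is isolated
behind the `WeightMap` type. The magnitudes are not published values.

## Deformable registration backend

The two-step pipeline (mask pre-registration seeding a water/fat main
registration, cost restricted to the dilated body mask) is backend-
agnostic. The reference backend is a multi-resolution (4×, 2×, 1×)
diffusion-regularised demons optimiser: Thirion forces on jointly
normalised channels, fluid smoothing of the update (σ_fluid), diffusion
smoothing of the accumulated field (σ_diffusion), per-iteration step
capping at 2× mean voxel spacing. The weight map scales the diffusion
smoothing per voxel, σ(x) = σ_diffusion · w(x), realised as a blend of two
Gaussian-smoothed fields (at σ·w_fat and σ·w_lean) — lean tissue is
regularised harder, and raising w_lean demonstrably reduces displacement
divergence in lean tissue. The backend is deterministic (no sampling) and
swappable via the `backend` argument.

Defaults σ_fluid = 6 mm, σ_diffusion = 5 mm, step_scale = 2 and
iterations (80, 60, 30) were tuned on phantom benchmarks — self-
registration stays below one voxel of spurious displacement with zero
folds, a 10 mm translation is recovered within one voxel, and a smooth
6 mm-RMS synthetic warp is recovered with ≥ 60% residual reduction on a
textured phantom. Fields are stored in mm on the fixed grid in pull-back
convention (warped(x) = moving(x + u(x))), which composes stably:
compose(f, g)(x) = g(x) + f(x + g(x)), with edge-value extension when
sampling displacements outside the grid.

QC follows the pipeline's reporting surface: Dice between fixed and
warped moving body masks; "discontinuities in the Jacobian determinant
map" operationalised as the count of voxels with det J ≤ 0 (fold-overs,
finite differences with physical spacing); inverse consistency as the
mean magnitude of forward∘backward composition over the fixed body.

## Atlas construction

Atlas channels store the voxel-wise mean, sample SD (n − 1 denominator;
population SD available by flag) and %CV = 100·SD/mean of registered
components, with %CV flagged undefined (NaN) where the mean is not
positive — this keeps non-finite values out of downstream t-maps. Sample
SD is the conservative choice for the small strata this design produces
(cohort strata of 6–11 subjects). Stratification is sex × BMI class with
BMI = 25 kg/m² assigned to the ≥ 25 class. Transport to a patient's
native space registers the atlas reference channels to the patient
(patient fixed), resamples mean and SD linearly, carries n as metadata
and recomputes %CV from the transported moments.

## Precision statistics

- %RC = 2.77 · wCV · 100 with wCV² = mean over subjects of d²/(2m²)
  (d = test − retest, m = pair mean), computed on raw (not log) ADC
  differences; the absolute RC (2.77 · within-subject SD) is also
  emitted. 2.77 = 1.96·√2 is the 95% smallest-detectable-change factor.
- Bland-Altman: bias = mean(a − b), limits of agreement bias ± 1.96 ·
  sample SD of the differences.
- Sex comparisons use Welch's unequal-variance t-test (group sizes are
  unequal by design and no pooled-variance assumption is published).
- Multiple regression ADC = β0 + β_age·age + β_sex·sex (female = 0,
  male = 1) via OLS with coefficient/model p-values, R² and 95% CIs.
- Voxel-wise Pearson r-maps use the exact t transform with n − 2 df;
  p-values are uncorrected by design (an optional Benjamini-Hochberg
  flag exists but is off by default). Constant covariates or
  zero-variance voxels yield flagged-undefined maps rather than errors.

## Anomaly detection

Patient images are smoothed with a Gaussian of σ = 1.7 mm (physical
units, converted per axis) before scoring. The "one-sided t-test" of one
patient observation against a normative sample is implemented as the
single-case (Crawford–Howell) t with df = n − 1 — the standard
single-subject-versus-normative form, degenerating to the z-score as
n → ∞. The smoothed patient voxel is treated as a single observation.

Candidate rules run sequentially with voxel-exact accounting: (i)
p < 0.001 within the body; (ii) opening with a 1-voxel-radius ball (the
published rule removes "small" clusters without quantifying the element;
radius and removal counts are exposed); (iii) removal of clusters whose
maximum normalised intensity is below the 95th in-body percentile;
optional removal of FF > 50% voxels. Lesions are 26-connected components
strictly above 0.5 ml (volume = voxel count × voxel volume). A predicted
lesion is a TP when its Dice against the reference foreground exceeds
10⁻⁴ (0.01% on the percentage scale); reference lesions missing from the
predicted foreground at the same threshold are FNs; sensitivity =
TP/(TP+FN), precision = TP/(TP+FP). Channel preparation for a downstream
segmentation network maps t-maps from [0, 200] and t × DWI products from
[0, 30] to [0, 1] with clipping; network training itself is out of scope.

## The phantom: what it emulates, what it does not

The generator emulates the statistical structure the analysis assumes:
multi-tissue anatomy (procedural ellipsoids/tubes: body outline, SAT
shell, brain, liver, spleen, kidneys, spine, psoas and thigh muscles);
per-tissue ADC with between-subject spread (default tables carry the
healthy-cohort 1.5T and 3T tissue means and SDs, e.g. kidney
1.91 ± 0.19 × 10⁻³ mm²/s at 1.5T); additive age/sex effects on tissue
ADC centred on the cohort mean age of 45.3 years (defaults zero — no
published slope table exists — and injected explicitly in study designs);
multi-station acquisition with 40 slices/station, 3 overlapping slices,
6 mm slices and a default head-station gain of +20% to exercise overlap
histogram matching; Rician magnitude noise (σ in signal units, constant
across stations unless overridden); smooth random inter-subject
deformations (Gaussian-filtered white noise at 30 mm correlation length,
RMS amplitude 5 mm by default, ground truth recorded); test-retest
replicates whose per-tissue ADC is scaled by independent N(1, wCV)
factors; and spherical low-ADC, boosted-S0 lesions constrained to lie
inside the body, with ground-truth masks. Default in-plane grids are
deliberately small (tests use 16–48 voxels per axis) so every stage runs
in seconds; all sizes are configurable.

It does **not** emulate k-space acquisition, EPI geometric distortion
(distortion correction is outside this package), coil sensitivity
profiles, partial-volume mixing at tissue borders, perfusion/IVIM
effects at low b, respiratory motion, or radiologically realistic organ
shapes. Passing tests therefore demonstrate the correctness and internal
consistency of the analysis chain under its stated model — not clinical
performance on scanner data. Phantom lesion size/contrast settings are
free configuration, not calibrated claims about any patient population.

## Numerical conventions

Volumes are (x, y, z) arrays with positive spacing in mm; slices along
z. Percentiles interpolate linearly. Connected components default to
26-connectivity (6-connectivity by flag). Dice of two empty masks is an
error in QC (undefined) and 0 in lesion matching. All randomness flows
through explicit integer seeds into `numpy.random.default_rng`; repeated
calls with identical inputs and seeds are bit-identical, including after
NIfTI serialisation (nibabel, diagonal RAS affine).

## Known limitations

- The demons backend is a reference implementation tuned for smooth
  phantom deformations; it does not implement the patch-based graph-cut
  optimisation of large whole-body registration frameworks and its
  capture range for large, sharp deformations is limited accordingly.
- Field recovery benchmarks require image texture; in homogeneous
  regions the aperture problem leaves the tangential field component
  determined only by regularisation.
- %RC is computed on raw ADC differences; a log-domain variant would be
  preferable for strongly heteroscedastic data and is noted as future
  work.
- The SAT peel assumes the subcutaneous shell is boundary-connected in
  the FF image; severe FF artefacts would break that assumption.
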