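# Methods

This note documents the models, numerical choices and limitations behind
`serialbsi`, in the order a study runs: phantom and cohort simulation, BSI
measurement, mixed-model inference, paired statistics, and sample size.

## Synthetic phantoms

The phantom is a three-tissue sphere: a brain of radius 25 mm (default) on a
64³ grid of 1 mm isotropic voxels, with a 4 mm cortical GM shell under the
surface, a concentric ventricular CSF sphere (radius 8 mm), and two
ellipsoidal GM "hippocampi" (semiaxes 5 × 3.5 × 3 mm) embedded in the
white-matter core, placed so that neither plausible ventricular growth nor
the inward-moving cortical shell can reach their boundary shells. Tissue
intensities are piecewise constant (CSF 20, GM 70, WM 120 by default), so
every noiseless tissue-interior voxel carries its tissue mean exactly.

**Voxel-exact boundary shifts.** A requested volume change (brain loss,
ventricular growth, hippocampal loss, in ml) is realized by an
order-statistic threshold: all voxel distances to the structure center are
sorted and the radius is chosen whose inclusive voxel count equals the
baseline count minus the requested change in voxels. A fixed sub-voxel
offset of the structure centers breaks lattice-distance ties, so counts can
be hit to the nearest voxel and the recorded truth (the realized
voxel-count difference × voxel volume) is within half a voxel of the
request. This gives analytic, discretization-free oracles for every BSI
test.

**Acquisition noise.** Noise is added with local SD = local signal / local
SNR. The SNR field is radial: `snr_center` at the grid center, increasing
outward by `snr_gradient` per mm — accelerated (parallel-imaging)
acquisitions lose SNR with distance from the receive coils at the head
surface, so their profile must be non-decreasing outward; non-accelerated
scans default to a uniform profile. Rician noise (magnitude MRI) is the
default; Gaussian is available for analytic moment checks. `snr_center =
inf` flags a noiseless acquisition. Rician magnitude bias affects both
timepoints equally and cancels in the BSI difference.

**Motion.** Patient motion is modelled as 1-D Gaussian blurring along one
axis (the phase-encode direction), kernel SD up to 3 voxels at severity 1,
plus a faint rolled ghost replica (amplitude 0.15 × severity); the output
is rescaled to conserve the total image sum. This is deliberately the
simplest mechanism that blurs boundary voxels — the failure mode that makes
raters reject scans — not a k-space-accurate motion simulation.

**Cohort simulator.** `simulate_cohort` draws direct-change tables exactly
from the generative mixed model below. Defaults are the study-scale
conditions: rates β = (5.8, 0.05, 0.5, 3.5, 7.5) ml/yr (control accelerated
rate; non-accelerated, EMCI, LMCI, AD offsets), slope SDs (2.5, 3.0, 3.5,
4.0) ml/yr by diagnosis, visit SD 1.5 ml, residual SDs 1.0 (accelerated)
vs 2.0 (non-accelerated) ml, visits at 0, 0.5 and 1.0 years, 75 subjects
per diagnosis. Both scan types of a session share the subject's slope and
visit effects, because the two acquisitions are back-to-back measurements
of the same anatomy; only the residual differs by scan type.

**QC simulator.** Paired pass/fail labels are drawn from a 2×2 distribution
with specified marginal failure probabilities per scan type and a
within-subject odds ratio; the joint cell is the root of the standard
quadratic linking the odds ratio to fixed margins. Defaults (7% vs 14%
failures, OR 2) mirror the observed asymmetry between protocols at 6
months.

**What the simulators do not emulate.** Cortical folding, partial-volume
tissue mixtures, registration error, scanner/manufacturer contrast
differences, spatially structured (coil-geometry) noise, and rater
behaviour. Passing tests therefore demonstrate correctness of the
algorithms under known truth — not performance on real ADNI-like data.

## Boundary shift integral

All variants share the clipped integral

    BSI = v/(I₂−I₁) · Σ_R [clip(B, I₁, I₂) − clip(F, I₁, I₂)],

which is antisymmetric in the timepoints and bounded by v·|R|. The boundary
shell R is the 1-voxel-dilated union minus the 1-voxel-eroded intersection
of the two structure masks (6-connected morphology); grids must match
exactly — no silent resampling.

**Normalization and windows.** KN-BSI clusters the union-brain-mask
intensities with k-means (k = 3), maps the CSF and WM centroids of each
timepoint onto (0, 1) by a per-volume affine map, and clips within a window
centered midway between the normalized CSF and GM centroids with half-width
0.25·(c_GM − c_CSF). The exact window conventions of in-house BSI
implementations are not published; these defaults are declared and
configurable (`window_fraction`, `target_means`), and the ventricular
fixed window defaults to (0.25, 0.75) in normalized units.

**k-means initialization.** Lloyd iterations with a deterministic,
seed-free start: centroids evenly spaced between the 1st and 99th
percentile of the masked intensities, ties assigned to the lower cluster,
convergence at relative centroid change < 1e-6. Quantile-based starts
(e.g. 10/50/90) were rejected: with CSF at only a few percent of a tight
brain mask the lowest quantile falls inside GM and the CSF cluster is lost,
which collapses the window. Degenerate (delta-like) histograms fall back to
quantiles of the distinct values, and an emptied cluster is re-seeded on
the value farthest from the surviving centroids.

**Double-window orientation.** A GM structure loses volume to CSF at dark
boundaries and to WM at bright boundaries, and the raw clipped integral has
opposite signs in the two windows. The double-window hippocampal BSI is
therefore a *signed* sum — +1 for the CSF/GM window, −1 for the GM/WM
window (`window_signs`) — so that structure loss reports positive at both
boundary types; a plain unsigned sum would cancel the two contributions.
Sign conventions overall: brain and hippocampal results are loss-positive,
ventricular results growth-positive.

**Differential bias correction** estimates the smooth multiplicative field
between the scans as the Gaussian-smoothed (normalized convolution within
the mask, FWHM default 15 mm) log-ratio F/B, and divides half of it out of
each volume. An identical pair is an exact fixed point. The correction is
only approximately idempotent: Gaussian smoothing is not a projector, and
mask-edge asymmetry leaves a residual that grows with kernel width (RMS
≈ 1e-3 of intensity at FWHM 8 mm on the phantom, a few 1e-3 at 15 mm).

**Accuracy regime.** At SNR ≥ 20 and piecewise-constant tissue, the noise
SD is a small fraction of the window width, so essentially only fully
transited boundary voxels contribute: brain and ventricular BSI recover the
voxel-quantized truth almost exactly. The hippocampal double-window variant
carries a small negative bias (≈ −10% at SNR 25) because the GM centroid
sits exactly on the window edges and noise half-clips asymmetrically on
transited voxels; this is inherent to the clipping geometry, documented
rather than corrected, and well inside the 20% accuracy band targeted for
a 0.05 ml change.

## Direct-change mixed model

Records are y_ijk (ml change between visits j < k), with interval t_ijk,
scan type (accelerated = 0), and diagnosis. Fixed effects multiply t:
columns (t, scantype·t, dx·t for each non-reference diagnosis present;
reference is the first diagnosis present, CN when available — absent
diagnoses drop their offset and slope variance). Random structure per
subject: slope b_i with diagnosis-specific variance loading t, and visit
effects entering as −u_ij + u_ik (the signed incidence rows of each record
sum to zero, so a subject's direct changes telescope).

**Estimation.** The marginal covariance per subject is
V_i = σ²_b,dx t t′ + σ²_u W W′ + diag(σ²_ε by scan type). Variances are
log-parametrized (unconstrained, positivity enforced); for each candidate
θ the fixed effects are profiled out by GLS and the Gaussian log-likelihood
is maximized by L-BFGS-B with three starts (method-of-moments, ×0.3, ×3).
Subjects with identical record patterns share one Cholesky factorization,
which makes balanced simulated cohorts (4 patterns) fast. β standard errors
come from (Σ X′V⁻¹X)⁻¹ at the optimum. ML (not REML) is used because the
residual-variance LRT compares models with identical fixed effects; the SE
convention for the adjusted rates is the GLS/observed-information one —
published tables do not state theirs, so small differences are expected.

**LRT.** The common- vs separate-residual-variance models differ by 1 df;
the null (equal variances) is interior under the log parametrization, so
the statistic is referred to χ²₁ without boundary correction. The separate
fit is additionally started at the common optimum, making the nesting
inequality hold by construction; a violation beyond 1e-6 raises an
optimizer-failure error instead of reporting a negative statistic. Type-I
error is verified at 200 null simulations (n = 150) to lie in [0.02, 0.09].

**Flags.** `diagnosis_specific_slopes=False` pools the slope variance;
`share_random_effects=False` treats each (subject, scan type) as its own
grouping unit for sensitivity analysis — the default shares b_i and u_ij
across scan types, the reading consistent with the model's indexing and
with back-to-back acquisition.

## Paired statistics

Standard definitions throughout: paired t on d = x − y with exact-constant
guards; Pitman–Morgan via the correlation of x + y and x − y referred to
t(n−2); Bland–Altman limits mean ± 1.96·SD(d); McNemar exact (two-sided
binomial tail of b out of b + c, capped at 1; the default, safe at any
count) and chi-square variants; Cohen's kappa from marginal-product chance
agreement, NaN when both raters are constant. The covariate-adjusted group
difference is the group coefficient of a least-squares fit (log odds ratio
from a logistic fit for binary outcomes), with a BCa bootstrap CI:
resampling unit = subject, bias correction from the bootstrap position of
the point estimate, acceleration from jackknife skewness. Two-sided tests,
α = 0.05, no multiplicity correction.

The exact McNemar test is discrete and conservative by construction, so
its calibration is checked through the chi-square variant at large
discordant counts and through the binomial oracle for the exact p-value.

## Sample size

n per arm = (u + v)²·(σ₁² + σ₂²)/(μ₁ − μ₂)² with σ₁ = σ₂ = the observed SD
and μ₁ − μ₂ = reduction × observed mean, rounded up to the next whole
subject — the only rounding consistent with the published table values
given the printed means/SDs. u and v are stored at printed precision
(0.84, 1.96) to reproduce printed arithmetic; a high-precision mode
(0.8416, 1.9600) is available. CIs are percentile bootstrap over subjects
(BCa is reserved for the covariate-adjusted comparisons, where it is the
named method); protocol comparisons resample subjects jointly and difference
the per-replicate rounded sample sizes.

Some published table entries are not exactly reproducible from rounded
printed inputs (the original analyses used unrounded internal values); the
reproduction targets here are the entries that do follow from the printed
summaries.

## Pipeline and problem sizes

`run_synthetic_study` chains: demo phantom (all three structures measured),
an image-based cohort (default 40 subjects × 3 visits × 2 scan types,
whole-brain KN-BSI on every visit pair; per-visit volume perturbations
realize the visit effects, and a floor at half the baseline volume guards
the rare negative-volume draw), a generative cohort (300 subjects), the
mixed-model fits and LRT, QC and agreement reports, and the sample-size
table. Every stage's seed derives from the single config seed via
`SeedSequence`; tables are written with a fixed float format, so reruns are
byte-identical (wall times go to `run.log`, which is excluded from the
manifest). The default study runs in well under a minute on one CPU; test
and acceptance problem sizes (50 phantom replicates, 10 × n = 300
recovery fits, 200 null LRT cohorts, 2000 calibration replicates) were
chosen to keep Monte-Carlo error comfortably inside the asserted bands at
desk scale.

## Known limitations

- Registration, segmentation, and non-uniformity correction are out of
  scope; pairs must arrive co-registered on identical grids with masks.
- The phantom's piecewise-constant tissue makes BSI recovery easier than on
  real scans (no partial volume, no texture); accuracy numbers here are
  upper bounds on real-data performance.
- The motion model is phenomenological; severities are not calibrated to
  any scanner protocol, and the two protocols' SNR/motion defaults are
  placeholders rather than estimates of real acquisition physics.
- The LMM optimizer handles the variance-component scales tested (ml-scale
  outcomes); extremely ill-scaled data should be rescaled before fitting.
- The logistic variant of the adjusted group difference is a thin
  statsmodels fit; separation at small n is not specially handled.
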