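# Methods

`subqmri` implements a complete quantitative-MRI analysis of aging effects
in subcortical gray-matter nuclei — striatum (STR), external and internal
globus pallidus (GPe, GPi), red nucleus (RN), subthalamic nucleus (STN),
substantia nigra (SN), and periaqueductal grey (PAG) — together with a
synthetic phantom cohort that provides ground truth for every stage. This
note documents the models, the defaults and why they were chosen, and what
the phantom does and does not establish about real data.

## T2* relaxometry

Multi-echo gradient-echo magnitude data are fitted voxelwise with the
single-component decay model

    S(TE) = S0 · exp(−TE / T2*).

The fit minimizes the sum of squared residuals over echoes by damped
Gauss–Newton iteration on (S0, R2* = 1/T2*), initialized from the
log-linear closed form (computed over echoes with magnitude above 1e−9 of
the voxel maximum, to avoid log of zero). T2* is constrained to
[0.1, 500] ms; convergence requires a relative parameter change below
1e−8 within 100 iterations. Voxels pinned at a bound, with degenerate
signal (all zero, or fewer than two usable echoes), or failing the
tolerance are flagged rather than silently filled. On noiseless data the
log-linear initialization is already exact, so the fit recovers T2* and S0
to solver precision; with magnitude noise the estimator inherits a small
Rician-type bias that is negligible at the SNR regimes simulated here
(≈50).

Only the single-component model is provided; multi-exponential decay and
noise-floor correction are out of scope.

## QSM reconstruction

The susceptibility pipeline is the classic single-orientation chain,
with all operators sharing one k-space convention (B0 along the grid's
third axis; the dipole kernel D(k) = 1/3 − kz²/|k|² with D(0) = 0), so the
forward model used by the phantom is the exact grid adjoint of the
inversion.

1. **Field estimation.** The phase of a single echo (the first, which has
   the highest SNR) is unwrapped and scaled to ppm:
   field = φ_unwrapped / (2π · TE · f0), with f0 = 297.2 MHz at 7 T.
   Two unwrappers are available: a reliability-sorted region method
   (scikit-image), exact up to one global 2π multiple, which is anchored by
   the masked median; and an FFT Laplacian (Poisson) solver, faster but
   only approximate near the mask edge. The region method is the default
   because it meets a wrap-free oracle to machine precision wherever the
   true inter-voxel phase step stays below π — the sampling limit beyond
   which no unwrapper can succeed. A single echo cannot determine the
   absolute 2π branch of a large uniform field offset; the median anchor
   assumes most of the mask is unwrapped, which holds after any reasonable
   shim.
2. **Background removal (SHARP/SMV).** Harmonic background fields satisfy
   the spherical-mean-value property, so the high-pass operator (1 − S),
   with S the spectrum of a normalized sphere (default radius 4 mm), anni-
   hilates them; the internal field is then recovered by truncated k-space
   deconvolution of the same operator (default truncation 0.05). The
   result is valid only on the brain mask eroded by the kernel radius.
   The truncation trades fidelity for noise robustness: on small noiseless
   grids a finer truncation (0.02) reproduces an internal dipole field
   essentially exactly, while 0.05 is the conventional operating point for
   noisy data.
3. **Dipole inversion (TKD/SDI).** Thresholded k-space division by D(k),
   flooring the divisor at δ·sign(D) on the kernel's zero cone; default
   δ = 0.1. The source publication's exact SHARP modification and
   threshold are not public, so both parameters are exposed in the
   configuration rather than asserted as equivalent. TKD systematically
   underestimates susceptibility by roughly 10–15% at δ = 0.1; this
   attenuation is nearly uniform across structures, so between-structure
   contrasts and rank orders survive (measured contrast correlation with
   ground truth r ≈ 0.999 on the noiseless phantom).
4. **Ventricle normalization.** Because single-echo QSM has an arbitrary
   offset, the map is referenced to CSF: the lateral-ventricle conjunction
   mask is eroded and the mean susceptibility over the eroded mask is
   subtracted (offset recorded; the operation is idempotent). The "2 mm
   Gaussian kernel" erosion is implemented as smooth-and-threshold —
   Gaussian smoothing of the binary mask with σ = kernel/2 and
   re-thresholding at Φ(2) ≈ 0.977, the smoothed value found exactly one
   kernel-width inside a flat boundary — so a flat face recedes by
   precisely 2 mm; on a 10³ voxel cube this matches euclidean
   distance-transform erosion exactly. The interpretation is recorded in
   the output metadata.

## Segmentation metrics and ROI extraction

Two raters' masks are compared with the Dice coefficient
2|A∩B|/(|A|+|B|) (undefined for two empty masks) and combined by voxelwise
intersection; the conjunction mask is the ROI for all extraction. ROIs
bordering CSF (striatum/lateral ventricle, PAG/cerebral aqueduct) contain
partial-volume voxels with CSF-like values; the mean T1 or T2* of the CSF
reference compartment therefore serves as an upper threshold — ROI voxels
with values at or above it are excluded (strict ≥ exclusion) — and both
thresholded and unthresholded means are reported. The rule applies to T1
and T2* (CSF susceptibility is the zero reference, so no threshold is
meaningful there); which compartment serves as the PAG reference is a
configuration choice (default: cerebral aqueduct).

## Location analysis

Each structure's unweighted mask centroid is mapped through the subject
affine to template millimeters. For the location-shift analysis, negative
X coordinates (left hemisphere in a right-positive template) are converted
to positive so both hemispheres enter a single per-structure PCA — making
the analysis invariant to hemisphere labeling. PCA is computed on the
covariance of (X, Y, Z) (the coordinates share units); the first
component's scores are the latent location variable correlated with age.
Eigenvector signs are fixed (largest-magnitude loading positive) so the
sign of the score–age correlation is reproducible. Probabilistic atlases
report 100 × (subjects containing a voxel)/n on the union support, with
maximum and mean percentage overlap summarizing consistency; the mean is
computed over the support because the map is undefined off it.

## Statistics

All aging effects are two-sided Pearson correlations against continuous
age at α = 0.05. Covariates (inter-rater Dice everywhere; total ventricle
volume additionally for location scores) are handled by double
residualization — residualizing both the outcome and age on the covariate
block — which is algebraically equivalent to the precision-matrix partial
correlation; the degrees of freedom are df = n − 2 − k for k covariates.
Bilateral structures contribute one observation per hemisphere (106
observations for 53 subjects), midline structures one per subject. Note
that published analyses of this design sometimes print df = 104 for one
covariate on 106 observations, i.e. do not subtract the covariate; this
package always emits df = n − 2 − k (103 in that case). Bonferroni
corrections use declared families — 11 structures for the Dice–age and
volume–age analyses (seven nuclei plus lateral/third/fourth ventricle and
aqueduct), seven nuclei for the quantitative-MRI and location families —
never a size inferred from whatever tests happened to run. Correlations
obtained with different rater pairs are compared with the two-sample
Fisher r-to-z statistic Z = (atanh r1 − atanh r2)/√(1/(n1−3) + 1/(n2−3)),
treating the two correlations as independent samples; dependent-correlation
variants are out of scope. Confidence bands for scatter plots use the OLS
conditional-mean CI from the t distribution and hat-matrix leverage.

## The synthetic cohort

The phantom emulates the cross-sectional study design: three age groups
(30 young / 14 middle-aged / 9 elderly; ages drawn uniformly within
19–29, 40–60, 60–75 — the within-group distribution is not specified by
the study design and uniform is an assumption, documented rather than
asserted). Structures are ellipsoids in a common template frame
(64×64×48 voxels at 1.5 mm isotropic); ellipsoids were chosen for their
closed-form volumes and centroids. Each nucleus carries linear age models
for T1, T2* and susceptibility anchored so that the group means at the
young and elderly mean ages (23.8 and 69.6 years) equal the published
group means, with between-subject SDs equal to the published young-group
SDs (shared across hemispheres, plus a smaller independent hemisphere
effect at 0.3 of the subject SD). CSF compartments (lateral, third and
fourth ventricles, cerebral aqueduct) carry CSF-like values (T1 4000 ms,
T2* 150 ms, χ 0) and grow linearly with age (0.6%/year by volume) on top
of a subject-level lognormal size factor (log-SD 0.15). That factor is
essential: without it ventricle volume is a deterministic function of age,
and partialling it out (as the analysis does) would absorb all age
variance; with it the phantom's ventricle-volume–age correlation is
r ≈ 0.45–0.6, matching observed cohorts.

Positional variability has three parts: per-structure age drift (default
0.017 mm/year along z for STR, GPe, STN, RN, PAG; zero for GPi and SN),
one rigid random shift per hemisphere per subject (SD 0.35 mm; midline
structures take the hemisphere average), and a small independent
per-structure jitter (SD 0.08 mm). Per-hemisphere (rather than
per-subject) shifts keep left and right observations statistically
independent — the analysis treats hemispheres as observations, and a
shared shift would inflate the type-I rate of the location test to ~12%.
The 0.35 mm magnitude is the generator's sensitivity design point: it
yields α-level false positives at zero drift and ≥90% detection of a
0.02 mm/year drift, the calibration targets the analysis is specified to
meet. Pairwise ellipsoid margins were verified ≥ 0.8 mm at ages 18 and 80,
so the jitter distributions cannot produce colliding nuclei (collisions
raise an error naming the pair). CSF is painted first and carves
partial-volume voxels out of abutting nuclei (the PAG surrounds the
aqueduct), which is what exercises the CSF-threshold extraction rule.

The forward signal model matches the analysis exactly: magnitude decays
mono-exponentially from S0 = 100; phase accrues linearly in TE from the
dipole-convolved susceptibility map plus a smooth quadratic polynomial
background field (amplitudes up to ~0.2 ppm, enough to wrap the phase at
the acquisition TEs of 11.22/20.39/29.57 ms); complex Gaussian noise is
added to the real and imaginary channels at 2% of the mean first-echo
brain magnitude (SNR 50). Raters are simulated by independently flipping
boundary voxels of the truth mask (drop inner-shell, add outer-shell) with
probability 0.3 per rater (capped at 0.15 for CSF), so expected Dice is
controllable and mask differences are confined to the boundary. All
randomness flows from one cohort seed through spawned per-subject
sequences; identical seeds give voxel-identical cohorts. Per-subject
affines are small known rigid perturbations stored with their exact
inverses — registration estimation is explicitly out of scope.

### What the phantom does not emulate

Realistic nucleus shapes and brain geometry; B1/transmit bias in the T1
map; multi-compartment T2* decay; Rician noise-floor effects at low SNR;
air–tissue interface fields beyond a smooth polynomial; oblique
acquisitions (B0 is always the grid's third axis); rater biases that are
spatially structured rather than boundary-random. Passing the phantom
checks therefore establishes the internal consistency and statistical
calibration of the pipeline — forward/inverse agreement, parameter
recovery, type-I/power behavior — not the accuracy of any particular real
acquisition.

## Problem sizes and numerical choices

The validation studies use a 53-subject cohort on the 64×64×48 grid
(the full published design), 20 replicate cohorts for the aging-power
study, 100 zero-drift and 20 drifted cohorts (compact striatum-only
phantom, 48×48×32) for the location calibration, and 10,000 simulations at
n = 106 for the type-I check — sizes chosen so the whole battery runs in a
few minutes on one CPU while keeping binomial uncertainty on the measured
rates well below the decision margins. Intermediate volumes are float32;
statistics are computed in double precision. Degenerate inputs raise
informative errors rather than propagating silently: empty masks, all-zero
voxels, zero-variance variables, erosions that empty a mask, TKD
thresholds outside (0, 2/3), and masks thinner than the SMV kernel are all
rejected explicitly.
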