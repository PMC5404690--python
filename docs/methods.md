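# Methods

This note documents the models, numerical conventions and design choices
behind `liverkbp`, and what the synthetic phantoms do and do not establish
about clinical data.

## Geometry

**Signed distance fields.** The target boundary is the set of target voxels
with at least one face-adjacent non-target neighbour (grid edges count as
outside). Distances are Euclidean, voxel-centre to voxel-centre, with
anisotropic spacing respected; they are negative strictly inside the target,
zero on boundary voxels and positive outside. The field is computed with a
single Euclidean distance transform to the boundary-voxel set
(`scipy.ndimage.distance_transform_edt` with the spacing as sampling), which
reproduces an exhaustive pairwise-minimum oracle exactly; the brute-force
oracle is kept in the package (`geometry.brute_force_signed_distances`) for
testing only. Internally distances are mm; the OVH axis is exposed in cm.

**OVH sampling.** OVH(r) is the fraction of liver voxels with signed
distance ≤ r. The curve is sampled on a uniform grid at one-voxel
resolution (0.25 cm at the default 2.5 mm spacing), extended one step below
the minimum distance and up to the maximum so every curve spans fractions 0
to 1 — including the "contracted target" branch when liver and target
overlap. r_v lookup is the smallest sampled r with OVH(r) ≥ v, linearly
interpolated between samples; the regression needs a continuous r_10, and
the curve is piecewise-smooth at this resolution. Fractional volumes are
voxel-count ratios (uniform grids only; voxel volume dx·dy·dz).

## OVH regression

The regression target is the *normalized* V_<15Gy (% of liver volume);
absolute cc follows by multiplying with the liver volume. The V_<15Gy
fraction counts voxels strictly below the threshold. Fitting is ordinary
least squares via `scipy.stats.linregress`; candidate overlap fractions
v ∈ {5, 10, 15, 20, 30}% are screened by |Pearson r|, ties broken toward the
smallest v for determinism, zero-variance candidates skipped with a warning.
Predictions are clipped to [0, 100]% (physical bound). At least 3 patients
are required; a constant r_v column is a degenerate fit and raises.

## SVDL

**Binning.** Signed distances are used for binning so liver voxels inside
the target form their own bins. Bin edges are aligned at 0 with default
width 2.5 mm (one voxel). Query distances outside the populated range, or
falling in an empty bin, snap to the nearest populated bin — an explicit
clamping rule rather than silent extrapolation.

**Bin summaries.**

- *median / mean / mode*: the mode is the midpoint of the most populated
  0.5 Gy histogram cell.
- *skew-normal*: maximum likelihood via `scipy.stats.skewnorm.fit`,
  reported as (ξ location, ω scale, α shape). The skew-normal likelihood
  has singular Fisher information at α = 0, which inflates α̂ and biases ξ̂
  on symmetric data; the fitter therefore compares the skewed fit against
  the nested normal submodel and reports the normal MLE (mean, sd, α = 0)
  unless the likelihood ratio clears the one-sided 5% χ² point
  (2·ΔLL ≥ 2.71). At α = 5 and n = 10,000 the MLE is unbiased with
  sampling sd ≈ 0.2 — parameter-recovery checks therefore average
  replicate fits rather than judging a single draw.
- *non-parametric*: per-bin kernel-density resampling — draw with
  replacement, add Gaussian noise at Silverman's rule-of-thumb bandwidth,
  reflect at 0 to keep doses physical — to exactly 10,000 points per bin
  (seedable), equalizing the statistical weight of sparsely populated bins
  near the target. The resample's variance exceeds the bin's by the squared
  bandwidth, the usual KDE inflation.
- Bins with fewer than 5 samples fall back to the median under either
  fitting method; the fallback is logged and flagged on the estimator.

**Prediction.** Scalar methods assign each query voxel its bin's summary
dose, which supports V_<15Gy, an empirical DVH and a full 3D dose grid
(NaN outside the liver — the model only ever sees liver voxels). Fitting
methods keep a distribution per bin; their DVH is the voxel-average
survival function, DVH(D) = meanᵥ P(doseᵥ ≥ D), a mixture model that
reduces to the scalar case for point masses. This is why fitting methods
cannot emit a unique 3D dose: requesting one raises `CapabilityError`.
V_<15Gy = 100·(1 − DVH(15 Gy)) on an axis containing the threshold exactly;
for scalar methods this equals the direct fraction of predicted voxel doses
below threshold. The DVH dose step defaults to 0.1 Gy and is recorded in
evaluation metadata, since RSS_DVH scales with the step.

## Evaluation

Leave-one-out cross validation refits everything per fold — the OVH
regression, or the distance-dose table and bin estimators — on the n−1
training patients; per-case distance fields and OVH curves are cached and
reused across folds (pure per-case geometry; no dose information crosses
folds). Metrics a method cannot produce are recorded as NaN
(not-applicable), never zero. The paired one-tailed t-test uses the
alternative "first sample smaller"; all-zero differences give the t = 0
convention p = 0.5, while constant non-zero differences (zero variance) are
flagged degenerate with p = NaN. Boxplot statistics (median, quartiles,
1.5·IQR whiskers, outliers) are computed on every evaluation; PNG rendering
is optional.

## Synthetic phantoms

Each phantom is an ellipsoidal liver with a spherical target and dose

    dose(p) = Rx · s(m_a(p) / λ) · (1 + ε_p),   ε_p ~ N(0, σ²),

where m_a is the signed distance computed with per-axis spacing multipliers,
λ the per-patient fall-off scale, and s(x) = σ(k(x₀ − x))/σ(k·x₀) a
normalized logistic with s(x ≤ 0) = 1 (defaults k = 4, x₀ = 1: dose ≈ 50% of
prescription at distance λ, ≈ 2% at 2λ). Target voxels are floored at the
prescription; dose is clipped at 0. Phantom grids are sized per patient to
the anatomy plus margin.

Population defaults emulate the clinical cohort ranges: liver volumes
uniform over 550–3346 cc with mild axis-ratio variation, target volumes
log-uniform over 2–222 cc (clinical target volumes skew small), prescriptions
uniform over 30–60 Gy, fall-off scales uniform over 8–12 mm, voxel noise sd
0.05. Inter-patient fall-off variability is what makes cross-validation
errors non-zero. Anisotropic ("coplanar-like") mode draws a
superior/inferior multiplier from U(1.6, 2.4) and in-plane multipliers from
U(0.9, 1.1), steepening one axis systematically.

Each patient draws from its own child generator, with the anisotropy
multipliers drawn last and unconditionally: isotropic and anisotropic
cohorts from the same seed are matched pairs — identical anatomy,
prescriptions, fall-off scales and noise — so mode comparisons are paired
comparisons at equal noise. Cohort manifests embed the full per-patient
specs for exact replay.

**What the phantoms show, and what they don't.** They reproduce the
features the models actually consume: a smooth monotone dose-vs-distance
relationship, per-distance-bin dose spread that widens under directional
fall-off, realistic organ/target volume and prescription ranges, and
patient-to-patient fall-off variability. They do not model beam divergence,
discrete-beam low-dose structure, intensity modulation, neighbouring-OAR
sparing trade-offs or non-ellipsoidal anatomy. Passing tests on phantoms
therefore validate the estimators, the capability contracts and the
cross-validation harness — they calibrate expectations for, but do not
certify, accuracy on clinical cohorts.

## Problem sizes and numerical choices

Verification runs use sizes chosen to exercise the full pipeline at
clinical voxel counts while staying quick on one CPU: the headline
predictability check uses 21 phantoms at full clinical volumes
(≈ 10⁵–10⁶ liver voxels each) with 2.5 mm bins; the exact-recovery check
uses 6 phantoms sharing one dose law (zero noise, shared λ and
prescription) and probes the fine-bin limit at 0.25 mm bins, where
within-bin dose-gradient quantization (the dominant error term, gradient ×
bin width) becomes negligible; the isotropy contrast uses 8-phantom matched
cohorts over 5 seeds. Distance transforms are exact (no sampling);
the only stochastic components are phantom noise and the non-parametric
resampler, both seeded. Degenerate inputs (empty/full masks, constant
regressors, sub-minimal cohorts, zero-variance differences) raise typed
errors rather than returning silent defaults.

## Known limitations

- Distance-based prediction is direction-blind by design; directional dose
  structure appears as irreducible per-bin spread (this is the mechanism
  behind the isotropic-vs-coplanar predictability gap, and the package
  deliberately does not add directional features).
- Uniform, axis-aligned grids only; volumes must arrive pre-voxelized on a
  common per-patient grid (no DICOM-RT reconstruction or resampling).
- One OAR per run; other organs at risk are planning constraints, not
  prediction targets.
- The skew-normal α = 0 guard trades a small loss of power against skewness
  for unbiased symmetric-bin fits.
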