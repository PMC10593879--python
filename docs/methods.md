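# Methods

This note documents the statistical models, the synthetic-data design, the
numerical choices, and the limitations of `polycortex`. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Vertexwise general linear model

Each morphometric measure is regressed at every vertex on a common design:
intercept, polygenic score, centered age, centered age², score-by-age and
score-by-age² interactions, sex (treatment-coded), ten genetic principal
components, scanner (treatment-coded), and total brain volume. Categorical
factors drop to zero columns when single-level; an actually rank-deficient
design raises an error rather than silently pseudo-inverting.

Choices worth knowing:

- **Age centering.** Without interactions, centering is cosmetic. With
  them, the score main effect is the effect *at the centering age*; the
  default center is the sample mean age, since an uncentered model would
  report the effect at age 0, outside any developmental cohort. Age-group
  fits center at the group mean; the 1-year centering sweep refits the full
  cohort at each integer center. The sweep is algebraically a
  reparameterization: β1(c) = β1 + β4(c−c0) + β5(c−c0)², verified to 1e-6
  in the tests.
- **Age-group bounds** are in completed years (floor of age), so the
  default 3–9 / 10–15 / 16–21 bounds partition a continuous-age 3–21
  cohort.
- **Standardization.** The score, the PCs and brain volume are z-scored by
  default (configurable, logged in the fit report); age is centered but
  never rescaled, keeping centers in years. t statistics are invariant to
  these scalings.
- **Estimation** is a single QR decomposition shared across vertices;
  SEs come from the triangular inverse. The independent test oracle solves
  the normal equations per vertex, keeping the two routes distinct.
  Numerically perfect fits (residual sum of squares below float precision
  relative to the response) return NaN t with a logged warning so that
  downstream random-field machinery only ever sees finite fields.
- **Collinearity note.** With uniform ages, score×age_c² is substantially
  correlated with the score column (population correlation
  E[a²]/√E[a⁴] ≈ 0.75 for a uniform), inflating the main-effect SE by
  roughly 1.6. This is a property of the model, not a defect; planted-truth
  expectations in the tests account for it.
- An AIC utility compares age polynomial degree 0–2 across vertices; it is
  reported, never used to switch models automatically.

## Random field theory cluster correction

- **Smoothness.** Residual maps are normalized to unit sum of squares per
  vertex; for each mesh edge of length l the mean squared difference s of
  the normalized field estimates 2(1 − ρ(l)). We invert the full Gaussian
  autocorrelation model ρ(l) = exp(−λ l²/2) (λ = −2 ln ρ / l², pooled over
  edges; FWHM = √(4 ln 2 / λ)) rather than the small-distance expansion
  2(1−ρ) ≈ λ l²: at FWHM ≈ 3 edge lengths the expansion overestimates FWHM
  by ~4% and hence underestimates resels by ~8%, which is material for
  calibration. ρ is clipped below at 1e-3; fields rougher than that are at
  the mesh resolution limit and their nominal FWHM is not meaningful.
- **Resels.** R2 = area/FWHM², R1 = boundary-perimeter/(2·FWHM), R0 = the
  Euler characteristic of the subcomplex of fully valid faces (the medial
  wall is excluded, so the search region has boundary). Smoothness is
  global (stationary); a resel-per-vertex non-stationary correction is out
  of scope and listed under limitations.
- **Clusters** are edge-connected components of suprathreshold vertices
  (union-find over the adjacency graph; NaN vertices never join). Extent
  uses one third of incident face areas per vertex, in mm² and resels.
- **Cluster p.** Expected cluster count E[m] = Σ_d R_d ρ_d(t) from the
  t-field Euler-characteristic densities; expected suprathreshold volume
  E[N] = R2·P(T>t); extents are modeled exponential with mean E[N]/E[m]
  (the two-dimensional Poisson-clumping form), giving the family-wise
  p = 1 − exp(−E[m]·exp(−k·E[m]/E[N])) for extent k. As k → 0 this tends
  to 1 − exp(−E[m]), the probability of observing any cluster — the correct
  ceiling for a family-wise cluster p. Two-sided analyses double E[m] and
  E[N]. Thresholds below t = 2 log a validity warning (the theory assumes
  high thresholds). The headline property — family-wise error within the
  95% binomial band of the nominal 0.05 over 1000 simulated null smooth t
  fields — is asserted by the acceptance suite and recomputed by the
  acceptance script.
- Default primary threshold: vertexwise p < .001 at the model df
  (configurable); default cluster alpha .01; default one-sided positive,
  two-sided available.

## Spin and reassignment nulls

- Rotations are drawn from the exact Haar measure (normalized Gaussian
  quaternions). The left-hemisphere rotation is reflected through the
  x = 0 plane for the right hemisphere, preserving bilateral homology.
- Resampling takes, for each position, the value of the nearest original
  vertex on the rotated sphere (k-d tree, lowest-index tie-break:
  deterministic). Nearest-neighbor resampling duplicates some source
  vertices and drops others; it is not a bijection, and no values are ever
  invented. Spun maps preserve the Moran-type edge autocorrelation of the
  original to within ~10% on the meshes used here, while unrestricted
  shuffles destroy it — this is the entire reason the spin null exists, and
  the test suite demonstrates the anti-conservatism of naive reassignment
  on smooth maps (rejection ≫ nominal).
- Class enrichment compares the observed within-class median (mean
  available) against the same statistic on spun maps; the reported
  format is the statistic plus within-class SD plus two-tailed add-one p,
  with no cross-class multiplicity correction.
- Parcel-level spins rotate parcel centroids and reassign by nearest
  original centroid; NaN parcels travel with the spin and are excluded
  pairwise from every correlation.
- The add-one rule p = (1 + #{|null| ≥ |obs|})/(n_perm + 1) keeps p > 0.
  A Monte-Carlo permutation p can match an exhaustive-enumeration p only to
  its binomial standard error ~√(p/n_perm) — the relevant test asserts
  agreement at that precision.
- Where units have no spherical geometry (the 11 expression areas),
  significance comes from uniform random reassignment permutations,
  with the same p-value rule. Default n_perm is 10,000 everywhere.

## Comparing correlations

Fisher's independent r-to-z is the default for age-group map comparisons
(matching the printed z/p reporting style of such analyses), with the
dependent alternatives — Steiger's z with pooled-correlation covariance and
Zou's CI via Fisher back-transform — available because group maps share
parcels and are not strictly independent; the report logs which was used
and the unit count n (pairwise-complete parcels). Zou CI coverage is
verified by simulation (93–97% band at n = 64 over 2000 trivariate-normal
replicates). The consistency of a dependent correlation triple is checked
by positive semidefiniteness of the implied 3×3 matrix. FDR is
Benjamini–Hochberg, delegated to `statsmodels` and cross-checked against a
brute-force step-up enumeration in the tests.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the statistical structure the analysis assumes,
at desk scale:

- **Mesh:** an icosphere (10·4^s + 2 vertices; default s = 3, 642 vertices,
  radius 50 mm) stands in for a registered cortical surface of ~82k
  vertices. Hemispheres split at x = 0; a contiguous cap of 5% of each
  hemisphere's vertices is flagged medial wall, exercising every NaN path.
- **Cohort:** n = 390, ages uniform on 3–21 (sample mean ≈ 12), 46.8%
  female, three scanners, ten standard-normal PCs, standard-normal score
  drawn independently of age, Gaussian brain volume. Uniform age reflects
  the roughly flat age distribution of such cohorts; the score distribution
  is a convention (the real PRS distribution is not public).
- **Morphometry:** linear predictor plus white noise smoothed to a target
  FWHM by mass-conserving heat steps and standardized per vertex, so the
  planted signal-to-noise ratio |β1|·SD(score)/noise_sd is exact. The
  generator/estimator round trip (planted 20 mm recovered within 15%) is a
  test.
- **Atlases:** farthest-point Voronoi patches on the sphere with seeds
  mirrored across the midline. Cytoarchitectural types (6) and functional
  networks (7) are *distributed* classes — three separated patches per
  hemisphere sharing one label — emulating the multi-patch layout of the
  real atlases; the 64- and 200-parcel decompositions are hemisphere-split
  with one contiguous cell per label. The distributed layout matters
  statistically: a compact single-patch class has an irreducible spin-p
  floor of several percent (rotations whose axis passes near the patch keep
  it self-aligned at any angle), whereas no single axis preserves several
  separated patches, so planted enrichment in a distributed class is
  reliably detectable.
- **Expression:** gene blocks per component track planted area gradients
  (orthogonal sine/cosine harmonics over the 11 areas by default) on a log
  scale with additive specimen noise; specificity weights load only on
  their cell type's block (the fully concentrated limit), and marker lists
  partition the compartment blocks, so noiseless recovery is exact (r = 1).
- **Disorder maps:** an independent smooth field is parcellated,
  Gram–Schmidt-orthogonalized against the reference over finite parcels,
  and mixed as r·ref + √(1−r²)·residual — the *sample* correlation equals
  the requested r exactly, so recovery tests are sharp.

What passing these tests does **not** show about real data: cortical
geometry (folding, true area gradients, non-spherical distortions),
non-stationary smoothness, site/scanner confounding structure, realistic
LD-driven PRS distributions, non-Gaussian morphometry noise, and
within-network heterogeneity are all absent from the generator. The
calibration results transfer to the extent that real residual fields are
approximately stationary Gaussian after model fitting — the same assumption
the corrected inferences themselves make.

## Numerical choices

- **Smoothing** is explicit heat diffusion x ← x − τLx with the
  combinatorial Laplacian of the valid-vertex subgraph: symmetric, hence
  exactly mass-conserving, and positivity-preserving for τ·deg ≤ 1. Step
  count and τ are calibrated from the mean squared edge length so that k
  steps give the target kernel variance (FWHM/2.355)²; the semigroup
  property (f then g ≈ √(f²+g²)) holds within 5% on the meshes used.
  NaN vertices are excluded from every kernel and preserved.
- **Area-to-parcel assignment** is nearest parcel centroid in great-circle
  distance on the registration sphere, ties to the lowest parcel id. The
  original workflow this mirrors used visual matching, which has no
  algorithmic definition; nearest-centroid is the documented surrogate and
  assignments can be supplied explicitly to override it.
- **Averaging order** in expression scoring is: weighted mean over genes
  within (area, specimen), then unweighted mean over specimens. For
  complete panels the order is immaterial; it is fixed and documented
  because incomplete panels would make it matter.
- **Determinism.** Every stochastic routine takes a seed; pipeline stages
  derive child seeds from the master seed by a fixed affine map, so stage
  reruns from saved intermediates reproduce the full run byte-for-byte.

## Problem sizes

Defaults used by the test and acceptance suites, chosen as the smallest
sizes at which each property is meaningfully testable: icosphere
subdivision 3 (642 vertices) for pipeline and spin experiments,
subdivision 4 (2562 vertices) with df = 300 and 1000 simulations for RFT
calibration, 500 pairs × 500 permutations for spin calibration, 50 seeds
for end-to-end recovery, 100 replicates (×6 maps) for disorder recovery,
2000 replicates for Zou coverage.

## Known limitations

- Stationary (global) smoothness only; no non-stationary resel correction.
- No peak-level RFT p-values and no permutation-based cluster-mass
  inference (spin and reassignment nulls cover map-level questions only).
- Nearest-neighbor spin resampling is not a bijection (standard for the
  method); exact value-multiset preservation would require an assignment
  solver and is not implemented.
- Mixed-effects/longitudinal models, surface registration, exact polyhedral
  geodesics, and cell-type deconvolution are out of scope.
- Hemispheres are fit jointly and treated as one RFT search region.
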