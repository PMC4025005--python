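# Methods

This note documents the models and procedures implemented in `soilsom`,
the defaults chosen where the method leaves room, and what the synthetic
testbed does and does not establish.

## Risk indices

For metal *i* in a sample, the contamination factor is
C_r^i = C^i / C_ref^i and the ecological risk is E_r^i = T_r^i · C_r^i
with toxic-response factors T_r = {Hg 40, Cd 30, As 10, Cu 5, Pb 5, Ni 5,
Cr 2, Zn 1} (dimensionless). The aggregate index RI = Σ_i E_r^i is the
standard Hakanson sum; it is additive and monotone in every E_r, and with
all C_r = 1 it equals Σ T_r = 98.

Grades for E_r use the conventional breaks: [0, 40) low, [40, 80)
moderate, [80, 160) considerable, [160, 320) high, [320, ∞) very high.
The boundary value 320 itself is assigned to *very high* (the strict
inequalities usually quoted leave it unassigned; a choice had to be made
and the upper class is the conservative one). No grade scale is defined
for RI because published RI breaks depend on how many metals enter the
sum.

Reference concentrations are deliberately **required configuration**:
regulatory soil standards are jurisdiction-specific and frequently
revised, so the package hard-codes none. Concentrations below detection
limits are accepted as the nonnegative numbers given; no imputation is
performed.

## Kriging and zonal aggregation

Point indices are interpolated by ordinary kriging: at each grid node the
predictor Σ w_j v_j solves the semivariance system with the unbiasedness
constraint Σ w_j = 1. Defaults, chosen as ordinary geostatistical
practice where the method itself is silent:

- empirical variogram on 12 lags up to half the bounding-box diagonal;
- spherical model (exponential selectable), fitted by pair-count-weighted
  least squares with a deterministic three-start range initialization;
- grid resolution 0.01° (configurable; the bundled validation runs use
  0.02° to keep the 10-seed recovery loop fast);
- coordinates kept in geographic degrees — anisotropy and the lon/lat
  metric distortion are ignored, which is acceptable at city scale
  (≈ 1° extent) and documented as a non-goal;
- duplicate sample locations are averaged before the system is built
  (exact duplicates make it singular);
- zonal aggregation uses the cell-center point-in-polygon rule, no
  partial-area weighting. Consequence: unit means conserve the grid mean
  exactly on tessellations (tested), and a unit covering no cell center
  yields a missing value rather than a guess.

With a zero nugget, prediction at a sampled location reproduces the
observation; kriging weights sum to 1 to 1e-8 at every node (both
tested).

## Batch self-organizing map

Training is the deterministic batch rule on z-scored data: per epoch,
cases are assigned to their BMU and each unit becomes the Gaussian-kernel
weighted mean of the assigned data, the kernel acting on lattice
distance. Defaults:

- hexagonal lattice (six neighbors at distance 1), rectangular
  selectable; units indexed row-major from the top-left;
- linear (principal-plane) initialization for bit-reproducibility —
  the codebook spans ±1 SD along the first two principal axes; random
  init is available behind the seed;
- two-phase radius schedule: rough phase max(rows, cols)/4 → 1 over 10
  epochs, fine-tuning 1 → 0.5 over 20 epochs (linear in both phases);
- constant columns z-score to zero, are flagged, and therefore drop out
  of all distances;
- BMU ties break to the lowest unit index.

QE is the mean case-to-BMU distance and TE the fraction of cases whose
two best units are not lattice-adjacent; both are checked against
brute-force oracles to 1e-12. Map-size scans train one SOM per candidate
shape from a shared seed and select argmin QE with ties broken by TE.
QE decreases with map capacity, so the scan is a resolution/topology
trade-off screen rather than a single-number optimum; the 12×7 (84-unit)
shape used in the bundled runs is the conventional choice for ~250 cases.

A structural property worth knowing: translating all inputs shifts the
denormalized codebook by the same vector (the z-scoring absorbs it), so
conclusions are invariant to units/offsets of the covariates.

## Codebook clustering

k-means (Lloyd's algorithm, greedy k-means++ seeding with 2+⌊ln k⌋
candidates per step, best of 10 restarts by inertia, farthest-point
reseeding of empty clusters) runs on the **codebook vectors**, not the
raw cases; cases inherit their BMU's cluster. The number of clusters
minimizes the Davies-Bouldin index

    DBI = (1/k) Σ_i max_{j≠i} (S_i + S_j) / M_ij

with S the mean member-centroid distance and M the centroid separation,
computed on the normalized scale; ties in the argmin go to the smaller k
(parsimony). Coincident centroids make the ratio undefined and raise an
error rather than returning infinity. The U-matrix (codebook distance
along lattice edges) is emitted alongside so the k-means partition can be
checked visually; on planted data the mean between-cluster edge exceeds
the mean within-cluster edge (tested).

## Cluster statistics

- Spearman's rho is Pearson on midranks. p-values: exact permutation for
  n ≤ 9, two-tailed t approximation with n−2 df otherwise; flags at 0.05
  and 0.01. A constant variable (or a cluster with < 3 cases) produces an
  explicit "not computable" marker instead of a number.
- One-way ANOVA is the classical between/within mean-square F with
  (k−1, N−k) df; groups with < 2 observations are dropped with a warning.
- Post-hoc letters: all-pairs comparisons (Tukey HSD / Tukey-Kramer by
  default; Duncan's multiple range test with protection level
  (1−α)^(p−1) as an option, since both conventions circulate for this
  kind of table) summarized by the insert-absorb compact letter display.
  Groups sharing a letter are not significantly different at α = 0.05;
  the letter/significance correspondence is verified against brute-force
  clique covers in the tests.
- Summary tables report mean (SD); SD, not standard error, is what the
  cell magnitudes of typical published tables of this kind correspond
  to, and it is labelled as SD here.

## Synthetic testbed

The generator emulates the structure the analysis assumes, not any real
geography:

- **Towns**: a jittered rectangular tessellation (shared vertices, so
  cells tile exactly) of a ≈ 1.15° × 0.55° box; default 253 towns.
- **Archetypes**: nine covariate profiles (means and SDs over the 19
  covariates, plus per-metal geometric means) patterned on published
  city-scale cluster profiles; towns are allocated to archetypes by
  largest-remainder shares and placed in contiguous serpentine bands,
  emulating spatially coherent ecoregions. Covariates are independent
  truncated normals within archetype (an exchangeable-correlation knob
  exists); percent-scaled variables are clipped to their range.
- **Separation**: within-archetype SDs are the profile SDs times
  `sd_scale` (default 0.4). The default was fixed analytically from the
  profile table alone: it is the scale at which the closest pair of
  archetype mean vectors sits six pooled per-dimension within-SDs apart
  in z-space — the cleanly separated regime the recovery validation
  assumes. At `sd_scale = 1` the profiles describe a spatial continuum
  with heavy overlap, and recovery of the planted k is *not* expected.
- **Samples**: default 1,018, allocated to towns proportional to area,
  uniform within polygon; concentrations are lognormal with geometric
  SD 1.5 (typical right-skew for trace metals). The archetype with no
  published metal profile defaults to the mean of its two risk
  neighbors; a `sample_free_archetypes` option leaves chosen archetypes
  without samples to exercise the empty-cluster code paths.
- **Reference panel**: reference concentrations are calibrated by
  nonnegative least squares so that Σ_m T_r^m · gm_am / ref_m matches
  each archetype's target RI, planting a town-RI range of roughly
  160-600 without per-metal hand tuning. A side effect of the NNLS is
  that the RI signal concentrates on the few metals (Hg, Cu, Cd) whose
  profiles vary most across archetypes; the other references come out
  large and contribute weakly.

What passing the planted-recovery suite shows: the full chain (risk →
kriging → zonal means → SOM → DBI-selected k-means → BMU projection)
identifies nine well-separated archetypes from 253 cases in ≥ 8/10 seeds
with median adjusted Rand index ≈ 0.99, and the planted
urbanization-risk gradient (population density vs RI) surfaces as a
significant positive Spearman correlation. What it does not show:
performance on real data, where clusters are not well separated,
covariates are cross-correlated, sampling is preferential, and the
kriging assumptions (stationarity, isotropy) are violated to unknown
degrees.

## Problem sizes in the bundled runs

The validation suite runs the default scene (253 towns, 1,018 samples)
with a 0.02° analysis grid, kriging RI only for the recovery loop, and a
fixed 12×7 map; the map-size scan is exercised separately over the nine
candidate shapes. These sizes were chosen so the whole suite completes in
a few minutes on one core while still using the full default scene.

## Known limitations

- Geographic degrees are treated as a Euclidean plane; no projections.
- Online/sequential SOM training, growing maps, universal/co-kriging,
  anisotropic variograms, and U-matrix watershed segmentation are out of
  scope.
- Duncan's test is provided for compatibility with older tables, but
  Tukey HSD is the default and the two can disagree; the package never
  asserts one as "the" method.
- The exact-permutation Spearman p is O(n!) and capped at n = 9 by
  design.
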