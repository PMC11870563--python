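# Methods

`petica` builds replicable spatial-network templates from amyloid-PET
cohorts and extracts subject-specific network loadings on new cohorts.
This note records the models, the estimators, the synthetic phantom, and
the numerical choices a maintainer would want to know about.

## The mixing model and SUVR

A cohort of N masked, voxelwise-aligned volumes is flattened to a subject
matrix and modelled as a linear spatial mixture,

    X (N x V)  =  A (N x C) · S (C x V),

where the rows of S are spatial components ("networks") and A holds the
per-subject loading coefficients.  SUVR normalisation divides each
subject's volume by its mean intensity over a reference region (cerebellar
cortex in amyloid imaging); it is the left-multiplication of X by a
diagonal matrix B of positive subject scales.  Substituting BX in the
mixing model shows BX = (BA)S: the source maps are invariant to SUVR
scaling, and scaling acts on the loadings alone, row i being multiplied by
b_i.  The package exploits this: loadings are defined as the least-squares
projection of the *raw* data onto the maps, so SUVR correction can be
applied to a fitted mixing matrix after the fact (`rescale_loadings`)
without re-estimating anything.  Group ICA results also expose a centered
projection (`loadings_centered`), whose reconstruction residual of the
centered data equals the PCA-discarded variance exactly; the raw
projection is the one used downstream because it is exactly equivariant
under per-subject rescaling.

## Template construction (split-half group ICA)

1. **QC.** Subjects whose spatial correlation with the cohort mean pattern
   falls more than 3 SD below the mean correlation are excluded.  The mean
   includes the subject under test; the rule is applied once, not
   iterated.  Screening operates on unsmoothed SUVR data.
2. **Smoothing.** Gaussian kernel, sigma = FWHM/(2·sqrt(2 ln 2)) per axis,
   converted through the affine's voxel sizes.  The real-data default is
   10 mm FWHM; analyses of the synthetic phantom use 4 mm because the
   phantom's features (blob sigma 3–5 mm) are smaller than human networks
   and a 10 mm kernel blurs away the planted structure.
3. **Split.** The cohort is split into two disjoint halves, stratified on
   age (sort by age, assign consecutive pairs randomly one to each half).
4. **Group ICA per half.** Voxelwise centering across subjects, PCA
   whitening to the model order C (one-stage, one volume per subject —
   source-based-morphometry style), then Infomax ICA: logistic
   nonlinearity, natural-gradient updates on blocks of size
   ceil(sqrt(V/3)), initial learning rate 0.01, annealed by 0.9 whenever
   the update direction turns by more than 60°, tolerance 1e-6 on the
   weight-change norm, at most 512 sweeps.  Non-convergence is reported in
   the results, never raised.  The unmixing matrix starts at a seeded
   random rotation; with a Gaussian (non-identifiable) input, different
   seeds therefore land in visibly different rotations, which is the
   documented behaviour rather than a defect.  Components are stored
   unscaled; z-scored maps are a reporting view.  Sign and permutation are
   resolved only at matching time.
5. **Matching.** Components are paired across halves by optimal bipartite
   assignment (Hungarian algorithm) on the absolute spatial-correlation
   matrix, then sign-aligned so each pair's r >= 0.
6. **Classification.** A component is assigned a confound category
   (white matter, ventricle, brain edge, reference region) when more than
   half of its top-5% |z| voxels fall inside that category's mask;
   otherwise it is a candidate network.  Manual overrides take precedence;
   confound exclusion requires both halves to agree, disagreement demotes
   to candidate with a warning.
7. **Template.** Pairs with r below the replication threshold (default
   0.4, applied to the signed post-alignment correlation) are dropped;
   surviving confound pairs are excluded from the template but kept as
   labelled *nuisance maps*; each retained pair is averaged after
   z-scoring both parents and re-z-scored.

## Constrained extraction (reference-guided ICA)

For a new cohort, each template network is adapted by a one-unit
fixed-point iteration over a PCA-whitened search space whose dimension is
the template's total component count (networks + nuisance maps).  The
whitened rows are voxel-centered and re-whitened so that the spatial
correlation objective lives in the same centered space where it is
evaluated.  The update combines two unit-normalized directions,

    w  <-  normalize( (1 - λ) · ŵ_negentropy  +  λ · ŵ_reference ),

where ŵ_negentropy is the one-unit log-cosh FastICA step (oriented along
the current iterate, since the one-unit fixed point is sign-symmetric) and
ŵ_reference is the whitened projection of the reference.  Normalizing both
directions makes λ a scale-free trade-off; the default λ = 0.7 favours
correspondence with the reference while the negentropy term still adapts
the map to the cohort.  Deflation against already-extracted components
uses *partial* Gram–Schmidt: projections are shrunk only down to a pairwise
correlation cap of 0.25, not to zero, because genuinely overlapping brain
sources are not orthogonal and forcing orthogonality distorts them.
Iterations stop when the weight direction changes by less than 1e-5 (max
200); a component whose final reference correlation is below 0.1 is
flagged `non_adapted` (a status, not an exception).  Output signs follow
each reference's own peak-voxel orientation, so flipping a reference's
sign does not change the result.  Initialization at the reference
projection makes the whole procedure deterministic.

Loadings are the least-squares coefficients of the raw data on the adapted
network maps *plus* the template's nuisance maps (non-orthogonalized) and
an intercept.  Covarying out the white-matter/ventricular/edge patterns
matters: without them, their subject-varying signal leaks into the network
loadings (on the synthetic fixture, truth-loading recovery drops from
~0.96–0.99 to ~0.77–0.94).  The cited reference-constrained algorithm is
published without update equations; the scheme above is this package's
explicit, documented stand-in, with every constant exposed in the API.

## Age associations and screening

Every unit (network loading column, or ROI mean SUVR) is regressed on age
with simple linear regression; the standardized slope equals the Pearson
correlation and the two-sided p-value comes from the exact t distribution
with N-2 degrees of freedom.  Benjamini–Hochberg FDR correction is applied
per unit system (networks and ROIs separately) over all tested units of
that system, *before* screening; screening then labels negative
associations `x-neg` (likely off-target white-matter/CSF signal) and
metadata-flagged units `reference` / `x-non-gm`, and significance is
counted among retained units at q < 0.05.  Ranked comparisons report
-log10(q) per system with the q = 0.05 line at 1.301.

## The synthetic phantom

The generator emulates an amyloid-PET SUVR cohort as

    x_i = b_i · (baseline + Σ_c a_ic s_c + ε_i),   a_ic = μ_c + slope_c · z(age_i) + jitter,

on a brain-like ellipsoidal mask (default grid 30x36x30 at 2 mm, V ≈
12,000 in-mask voxels).  Sources are: bilateral (mirror-placed) Gaussian
blob networks with sigma 0.05–0.08 of the grid extent, placed in a
"gray-matter" band of normalized radius 0.40–0.62; a thin white-matter-like
shell at radius 0.85; a central ventricle-like blob; and a one-voxel
brain-edge rim.  All maps have unit peak.  Placement is rejection-sampled
so network–network correlation stays at or below max(0.12, overlap) and
network–confound correlation below 0.15 — comfortably inside the
documented contract bound (overlap + 0.2) — because spatial ICA can only
recover sources up to their mutual correlation: with looser placement the
recovery ceiling drops to ~0.97 regardless of optimizer (verified against
an independent FastICA implementation).

Defaults defining the standard study conditions: 120 subjects, 6 networks
+ 3 confounds, baseline 1 (keeps uptake and the reference-region mean
positive; a constant map with unit loading that centering removes), mean
loading 1.0 for networks (1.5 white matter, 0.8 ventricle, 0.5 edge),
loading jitter SD 0.3, age slopes 0 unless configured, voxel noise SD 0.1
(10% of peak — moderate for frame-averaged PET), subject scales
Uniform(0.9, 1.1) (±10% global scale, the size of cerebellar reference
variation), ages Uniform(55, 90).  A small reference sphere sits near the
inferior pole, and a 3x3x3-block integer "atlas" provides hard-border ROI
labels that fragment any bilateral blob across several labels.  All
randomness flows from one seed through independent substreams, so
regeneration is byte-identical and overriding one ingredient (e.g. the
subject scales) leaves the others untouched; if a placement round
dead-ends, the sampler restarts from a fresh seed-derived substream.

What the phantom does *not* emulate: tracer kinetics, scanner point-spread,
partial-volume effects, anatomical variability, registration error, or
non-Gaussian noise.  Passing tests therefore demonstrate the estimators'
correctness under the linear mixing model with known ground truth — not
performance on real cohort data, where registration, partial volume and
off-target binding add failure modes this phantom cannot probe.

## Numerical choices and degenerate inputs

* Model order must satisfy C <= min(N-1, V); an exactly low-rank cohort
  is accepted by the constrained model (the search space caps to the
  numerical rank) but rejected by blind group ICA with a clear error.
* When per-subject global scale varies, the cohort gains a rank-one
  global component; scaling-invariance analyses therefore use model order
  = source count + 1.
* SUVR requires a nonempty reference region with positive mean; QC
  requires at least 3 subjects and warns (excluding nobody) when the
  correlation spread is zero; splitting requires at least 4 subjects.
* BH-FDR is delegated to statsmodels and cross-checked in the tests
  against the brute-force min-over-tail definition; Hungarian matching is
  delegated to scipy and cross-checked against exhaustive enumeration.
* An empty template (nothing replicates) is a valid, warned outcome with
  status `"empty"`, not an exception.

## Problem sizes

The test-suite and acceptance analyses run at the fixture scale above
(V ≈ 12k voxels, N = 120, model order 9–10) and, for the sensitivity
comparison, 20 replicates at 20x24x20 / N = 80 / 4 networks.  These sizes
preserve the N << V regime of cohort PET while letting every decomposition
converge in seconds.
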