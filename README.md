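# petica

Replicable spatial-network templates for amyloid PET, built with split-half
group ICA, and subject-specific network loadings extracted on new cohorts
with reference-constrained ICA.

## The problem

PET analyses conventionally average tracer uptake inside anatomical
regions of interest (ROIs).  But molecular uptake patterns are spatially
varying densities that overlap and do not respect anatomical borders, and
off-target binding (amyloid tracers bind myelin in white matter) mixes
into neighbouring gray matter.  Spatial independent component analysis
decomposes a cohort of volumes into whole-brain covarying networks,

    X (N subjects x V voxels)  =  A (N x C) · S (C x V),

where each row of S is a spatial network and A holds per-subject loading
coefficients.  Because SUVR normalisation is a per-subject scale
(X → BX with B diagonal positive), the source maps are invariant to it and
the scaling transfers to the loadings alone — row i of A is multiplied by
b_i — so SUVR can be applied to fitted loadings post hoc.

`petica` implements the full workflow for anyone building or applying such
templates: SUVR normalisation and cohort QC, split-half Infomax group ICA
with Hungarian component matching, confound classification (white matter,
ventricles, brain-edge artifacts, reference region) and pair-averaged
template assembly, reference-constrained extraction of cohort-specific
maps and loadings, and age-association statistics comparing networks
against atlas ROIs under per-system FDR control.  A seeded synthetic-PET
generator with known ground truth makes every stage testable without any
data download.

## Worked example

Build a template on a synthetic cohort with one planted age effect, then
extract loadings and regress them on age:

```python
import numpy as np
from petica import (CohortConfig, generate_cohort, flatten_cohort, smooth,
                    fit_group_ica, match_components, split_half,
                    classify_components, build_template, ConstrainedICA,
                    AgeAssociation)
from petica.preprocess import suvr_cohort

cohort = generate_cohort(CohortConfig(seed=7, age_slopes=(0.4, 0, 0, 0, 0, 0)))
suvr, b = suvr_cohort(cohort.volumes, cohort.reference_mask)
smoothed = [smooth(v, 4.0) for v in suvr]

ids = list(cohort.covariates["subject_id"])
grp_a, grp_b = split_half(ids, seed=1, stratify_by=cohort.truth.ages)
pos = {s: i for i, s in enumerate(ids)}
res_a = fit_group_ica(flatten_cohort([smoothed[pos[s]] for s in grp_a], cohort.mask), 9, seed=2)
res_b = fit_group_ica(flatten_cohort([smoothed[pos[s]] for s in grp_b], cohort.mask), 9, seed=3)

pairs = match_components(res_a.maps, res_b.maps)
cats_a = classify_components(res_a.maps, cohort.confound_masks, analysis_mask=cohort.mask)
cats_b = classify_components(res_b.maps, cohort.confound_masks, analysis_mask=cohort.mask)
template = build_template(res_a.maps, res_b.maps, pairs, cats_a, cats_b, threshold=0.4)
print(f"retained {template.n_retained} networks; excluded {template.exclusions}")

X = flatten_cohort(smoothed, cohort.mask)
result = ConstrainedICA(X, template, subject_ids=ids).fit()
ages = cohort.covariates["age"].to_numpy()
assoc = AgeAssociation(result.loadings_frame(b=b).filter(like="_suvr"), ages).fit()
print(assoc.summary())
```

Output:

```
retained 6 networks; excluded {'white_matter': 1, 'edge': 1, 'ventricle': 1}
Age association (simple linear regression; standardized beta = Pearson r)
  units tested: 6   FDR alpha: 0.05
  retained after screening: 6
  significant (q < 0.05): 1

   unit    beta        p         q   status
N3_suvr  0.7534 3.18e-23 1.908e-22 retained
N4_suvr  0.1335   0.1462    0.2075 retained
N5_suvr  0.1252   0.1729    0.2075 retained
N7_suvr   0.186  0.04191   0.08383 retained
N8_suvr  0.1923  0.03535   0.08383 retained
N9_suvr 0.03177   0.7305    0.7305 retained
```

All six planted networks replicate across the halves and the three planted
confounds are excluded by category.  The single network carrying the
planted age effect (slope 0.4 loading-units per standardized year) is the
only one significant after BH-FDR, with standardized β = 0.75 — the
standardized slope of a simple regression is exactly the Pearson
correlation between loading and age.

The same workflow is available from the shell via the `petica` command
(`simulate`, `qc`, `build-template`, `extract`, `associate`, `report`,
`run`) driven by a YAML config whose analysis defaults are model order 40,
pair-correlation threshold 0.4, 10 mm smoothing, 3-SD QC and q < 0.05.

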