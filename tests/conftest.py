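"""Shared fixtures: synthetic cohorts and the expensive fitted objects.

Session scope keeps the ICA fits to one run each across the whole suite.
The "default fixture" is the standard study condition of the package:
30x36x30 grid at 2 mm, 120 subjects, 6 networks + 3 confounds, moderate
noise (SD 0.1), +/-10% subject scales.
"""

import numpy as np
import pytest

from petica import (
    ConstrainedICA,
    fit_group_ica,
    flatten_cohort,
    match_components,
    smooth,
    split_half,
)
from petica.preprocess import suvr_cohort
from petica.synthetic import CohortConfig, generate_cohort
from petica.template import build_template, classify_components

#: smoothing kernel used for synthetic-fixture analyses (mm); matched to the
#: phantom's blob scale (sigma ~3-5 mm), where the 10 mm real-data default
#: would blur the planted structure
FIXTURE_FWHM = 4.0


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(CohortConfig(seed=7))


@pytest.fixture(scope="session")
def unit_scale_cohort():
    """Same sources/loadings as the default cohort but all b_i = 1."""
    return generate_cohort(CohortConfig(seed=7, subject_scales=np.ones(120)))


@pytest.fixture(scope="session")
def noiseless_cohort():
    return generate_cohort(
        CohortConfig(seed=7, noise_sd=0.0, subject_scales=np.ones(120))
    )


@pytest.fixture(scope="session")
def noiseless_fit(noiseless_cohort):
    X = flatten_cohort(noiseless_cohort.volumes, noiseless_cohort.mask)
    return fit_group_ica(X, 9, seed=1)


def truth_maps(cohort, networks_only=False):
    stop = len(cohort.truth.network_indices) if networks_only else None
    return np.stack(
        [cohort.mask.flatten(m) for m in cohort.truth.true_maps[:stop]]
    )


@pytest.fixture(scope="session")
def suvr_smoothed(default_cohort):
    """(smoothed SUVR volumes, SUVR factors) for the default cohort."""
    suvr, b = suvr_cohort(default_cohort.volumes, default_cohort.reference_mask)
    return [smooth(v, FIXTURE_FWHM) for v in suvr], b


@pytest.fixture(scope="session")
def splithalf_bundle(default_cohort, suvr_smoothed):
    """Full split-half template build on the default fixture."""
    smoothed, _ = suvr_smoothed
    co = default_cohort
    ids = list(range(len(smoothed)))
    a_ids, b_ids = split_half(ids, seed=1, stratify_by=co.truth.ages)
    X_a = flatten_cohort([smoothed[i] for i in a_ids], co.mask)
    X_b = flatten_cohort([smoothed[i] for i in b_ids], co.mask)
    res_a = fit_group_ica(X_a, 9, seed=2)
    res_b = fit_group_ica(X_b, 9, seed=3)
    pairs = match_components(res_a.maps, res_b.maps)
    cats_a = classify_components(res_a.maps, co.confound_masks, analysis_mask=co.mask)
    cats_b = classify_components(res_b.maps, co.confound_masks, analysis_mask=co.mask)
    template = build_template(
        res_a.maps, res_b.maps, pairs, cats_a, cats_b, threshold=0.4
    )
    return {
        "cohort": co,
        "res_a": res_a,
        "res_b": res_b,
        "pairs": pairs,
        "cats_a": cats_a,
        "cats_b": cats_b,
        "template": template,
    }


@pytest.fixture(scope="session")
def constrained_fit(default_cohort, suvr_smoothed, splithalf_bundle):
    smoothed, _ = suvr_smoothed
    X = flatten_cohort(smoothed, default_cohort.mask)
    return ConstrainedICA(X, splithalf_bundle["template"]).fit()
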