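"""Stage orchestration over the on-disk cohort layout.

Stages run in order simulate -> qc -> template -> extract -> associate ->
report.  Every stage reads only the artifacts of earlier stages, writes its
outputs (NIfTI maps, delimited tables, JSON metadata) under the configured
output directory, and is deterministic given the configured per-stage seeds.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import AgeAssociation, rank_report, roi_means_cohort
from .config import RunConfig
from .constrained import ConstrainedICA
from .groupica import GroupICA
from .preprocess import flag_outliers, suvr_cohort
from .synthetic import CohortConfig, generate_cohort, write_cohort
from .template import Template, build_template, classify_components, match_components, split_half
from .volumes import BrainMask, Volume, flatten_cohort, smooth

__all__ = ["run_pipeline", "STAGES", "MissingInputError"]

log = logging.getLogger("petica")

STAGES = ("simulate", "qc", "template", "extract", "associate", "report")


class MissingInputError(FileNotFoundError):
    """A stage input is absent; the message names the missing path."""


def _require(path: Path, what: str) -> Path:
    if not Path(path).exists():
        raise MissingInputError(f"missing {what}: {path}")
    return Path(path)


def _load_cohort(config: RunConfig):
    cov = pd.read_csv(_require(config.covariates, "covariates table"), sep="\t")
    mask = BrainMask.from_nifti(_require(config.mask, "analysis mask"))
    vols = [
        Volume.from_nifti(
            _require(
                Path(config.cohort_dir) / "volumes" / f"{sid}_pet.nii.gz",
                f"volume for {sid}",
            )
        )
        for sid in cov["subject_id"]
    ]
    return cov, mask, vols


def _meta(config: RunConfig, stage: str, extra=None) -> dict:
    meta = {
        "stage": stage,
        "version": __version__,
        "seeds": dict(config.seeds),
        "parameters": {
            "model_order": config.model_order,
            "pair_threshold": config.pair_threshold,
            "smoothing_fwhm_mm": config.smoothing_fwhm_mm,
            "qc_sd": config.qc_sd,
            "fdr_alpha": config.fdr_alpha,
            "constraint_weight": config.constraint_weight,
        },
    }
    if extra:
        meta.update(extra)
    return meta


def _write_meta(outdir: Path, stage: str, config: RunConfig, extra=None):
    (outdir / f"{stage}_stage_meta.json").write_text(
        json.dumps(_meta(config, stage, extra), indent=2, default=str)
    )


def stage_simulate(config: RunConfig, cohort_config: CohortConfig = None):
    cc = cohort_config or CohortConfig(seed=config.seeds.get("simulate", 0))
    cohort = generate_cohort(cc)
    write_cohort(cohort, config.cohort_dir)
    log.info("simulate: wrote %d volumes to %s", len(cohort.volumes), config.cohort_dir)
    return cohort


def stage_qc(config: RunConfig):
    cov, mask, vols = _load_cohort(config)
    ref = BrainMask.from_nifti(_require(config.reference_mask, "reference mask"))
    suvr, b = suvr_cohort(vols, ref)
    X = flatten_cohort(suvr, mask)
    report = flag_outliers(X, n_sd=config.qc_sd, subject_ids=cov["subject_id"])
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    frame = report.to_frame()
    frame["suvr_factor"] = b
    frame.to_csv(outdir / "qc_report.tsv", sep="\t", index=False)
    _write_meta(outdir, "qc", config, {"n_excluded": int(len(report.excluded))})
    log.info("qc: %d/%d subjects kept", len(report.kept), len(vols))
    return report


def stage_template(config: RunConfig):
    cov, mask, vols = _load_cohort(config)
    ref = BrainMask.from_nifti(_require(config.reference_mask, "reference mask"))
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    qc_path = outdir / "qc_report.tsv"
    keep = set(cov["subject_id"])
    if qc_path.exists():
        qc = pd.read_csv(qc_path, sep="\t")
        keep = set(qc.loc[qc["status"] == "kept", "subject_id"])
    idx = [i for i, sid in enumerate(cov["subject_id"]) if sid in keep]

    suvr, _ = suvr_cohort([vols[i] for i in idx], ref)
    smoothed = [smooth(v, config.smoothing_fwhm_mm) for v in suvr]
    ids = [cov["subject_id"][i] for i in idx]
    ages = cov["age"].to_numpy()[idx]
    a_ids, b_ids = split_half(ids, seed=config.seeds.get("split", 1), stratify_by=ages)
    pos = {sid: i for i, sid in enumerate(ids)}
    X_a = flatten_cohort([smoothed[pos[s]] for s in a_ids], mask)
    X_b = flatten_cohort([smoothed[pos[s]] for s in b_ids], mask)

    order = min(config.model_order, min(len(a_ids), len(b_ids)) - 1)
    res_a = GroupICA(X_a, order, subject_ids=a_ids).fit(config.seeds.get("ica_a", 2))
    res_b = GroupICA(X_b, order, subject_ids=b_ids).fit(config.seeds.get("ica_b", 3))
    pairs = match_components(res_a.maps, res_b.maps)

    confound_masks = {}
    for cat in ("white_matter", "ventricle", "edge"):
        path = Path(config.cohort_dir) / f"confound_{cat}.nii.gz"
        if path.exists():
            confound_masks[cat] = BrainMask.from_nifti(path)
    confound_masks["reference_region"] = ref
    cats_a = classify_components(res_a.maps, confound_masks, analysis_mask=mask)
    cats_b = classify_components(res_b.maps, confound_masks, analysis_mask=mask)

    template = build_template(
        res_a.maps,
        res_b.maps,
        pairs,
        cats_a,
        cats_b,
        threshold=config.pair_threshold,
        provenance={
            "model_order": order,
            "seed_split": config.seeds.get("split", 1),
            "seeds_ica": [config.seeds.get("ica_a", 2), config.seeds.get("ica_b", 3)],
            "n_group_a": len(a_ids),
            "n_group_b": len(b_ids),
        },
    )
    template.save(outdir / "template", mask)
    _write_meta(
        outdir,
        "template",
        config,
        {"n_retained": template.n_retained, "exclusions": template.exclusions},
    )
    log.info(
        "template: retained %d of %d pairs", template.n_retained, len(pairs)
    )
    return template


def stage_extract(config: RunConfig):
    cov, mask, vols = _load_cohort(config)
    ref = BrainMask.from_nifti(_require(config.reference_mask, "reference mask"))
    outdir = Path(config.output_dir)
    _require(outdir / "template.nii.gz", "template maps")
    template = Template.load(outdir / "template", mask)
    smoothed = [smooth(v, config.smoothing_fwhm_mm) for v in vols]
    X = flatten_cohort(smoothed, mask)
    _, b = suvr_cohort(vols, ref)
    model = ConstrainedICA(
        X,
        template,
        lam=config.constraint_weight,
        subject_ids=list(cov["subject_id"]),
    )
    result = model.fit(seed=config.seeds.get("extract", 4))
    frame = result.loadings_frame(b=b)
    frame.to_csv(outdir / "loadings.tsv", sep="\t")
    _write_meta(
        outdir,
        "extract",
        config,
        {
            "reference_correlations": result.reference_correlations.tolist(),
            "statuses": list(result.statuses),
        },
    )
    log.info("extract: %d components adapted", result.n_components)
    return result


def stage_associate(config: RunConfig):
    cov, mask, vols = _load_cohort(config)
    ref = BrainMask.from_nifti(_require(config.reference_mask, "reference mask"))
    outdir = Path(config.output_dir)
    loadings_path = _require(outdir / "loadings.tsv", "loading table")
    loadings = pd.read_csv(loadings_path, sep="\t", index_col="subject_id")
    # SUVR-rescaled columns are the default inputs for statistics
    suvr_cols = [c for c in loadings.columns if c.endswith("_suvr")]
    measures = loadings[suvr_cols].rename(columns=lambda c: c[: -len("_suvr")])
    ages = cov.set_index("subject_id").loc[measures.index, "age"].to_numpy()
    net = AgeAssociation(measures, ages, alpha=config.fdr_alpha).fit()
    net.frame.to_csv(outdir / "associations_networks.tsv", sep="\t", index=False)

    atlas = Volume.from_nifti(_require(config.atlas, "atlas labels"))
    suvr, _ = suvr_cohort(vols, ref)
    roi = roi_means_cohort(suvr, atlas)
    roi_res = AgeAssociation(roi, cov["age"].to_numpy(), alpha=config.fdr_alpha).fit()
    roi_res.frame.to_csv(outdir / "associations_rois.tsv", sep="\t", index=False)
    _write_meta(
        outdir,
        "associate",
        config,
        {
            "networks_significant": net.n_significant(),
            "rois_significant": roi_res.n_significant(),
        },
    )
    log.info(
        "associate: %d/%d networks, %d/%d ROIs significant at q<%g",
        net.n_significant(),
        net.n_tested,
        roi_res.n_significant(),
        roi_res.n_tested,
        config.fdr_alpha,
    )
    return net, roi_res


def stage_report(config: RunConfig, make_plot: bool = True):
    outdir = Path(config.output_dir)
    frames = {}
    for system, fname in (
        ("networks", "associations_networks.tsv"),
        ("rois", "associations_rois.tsv"),
    ):
        path = _require(outdir / fname, f"{system} associations")
        frames[system] = pd.read_csv(path, sep="\t")
    table = rank_report(frames)
    table.to_csv(outdir / "rank_report.tsv", sep="\t", index=False)
    if make_plot and len(table):
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(7, 4))
        for system, sub in table.groupby("system"):
            finite = sub["neg_log10_q"].replace(np.inf, np.nan).dropna()
            ax.plot(
                sub["rank"][: len(finite)], finite, marker="o", label=system
            )
        ax.axhline(-np.log10(0.05), linestyle=":", color="gray", label="q = 0.05")
        ax.set_xlabel("rank (ascending q)")
        ax.set_ylabel("-log10(q)")
        ax.legend()
        fig.tight_layout()
        fig.savefig(outdir / "rank_report.png", dpi=120)
        plt.close(fig)
    _write_meta(outdir, "report", config)
    return table


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "qc": stage_qc,
    "template": stage_template,
    "extract": stage_extract,
    "associate": stage_associate,
    "report": stage_report,
}


def run_pipeline(config: RunConfig, stages=STAGES) -> dict:
    """Run the requested stages in canonical order; returns stage outputs."""
    config.validate()
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}")
    results = {}
    for stage in STAGES:
        if stage in stages:
            log.info("running stage %s", stage)
            results[stage] = _STAGE_FUNCS[stage](config)
    return results
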