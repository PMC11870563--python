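"""Run configuration: paths, printed-default parameters, per-stage seeds."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .volumes import ValidationError

__all__ = ["RunConfig"]


def _default_seeds() -> dict:
    return {"simulate": 0, "split": 1, "ica_a": 2, "ica_b": 3, "extract": 4}


@dataclass
class RunConfig:
    """Parameters and paths for a pipeline run.

    Analysis defaults follow the printed settings of the study design:
    model order 40, split-half pair-correlation threshold 0.4, 10 mm
    Gaussian smoothing, 3-SD QC cut, FDR alpha 0.05.
    """

    cohort_dir: str = "cohort"
    output_dir: str = "output"
    mask: str = "cohort/mask.nii.gz"
    reference_mask: str = "cohort/reference_mask.nii.gz"
    atlas: str = "cohort/atlas.nii.gz"
    covariates: str = "cohort/covariates.tsv"
    model_order: int = 40
    pair_threshold: float = 0.4
    smoothing_fwhm_mm: float = 10.0
    qc_sd: float = 3.0
    fdr_alpha: float = 0.05
    constraint_weight: float = 0.7
    seeds: dict = field(default_factory=_default_seeds)

    def validate(self) -> "RunConfig":
        if self.model_order < 1:
            raise ValidationError("model_order must be >= 1")
        if not 0.0 <= self.pair_threshold <= 1.0:
            raise ValidationError("pair_threshold must be in [0, 1]")
        if self.smoothing_fwhm_mm < 0:
            raise ValidationError("smoothing_fwhm_mm must be >= 0")
        if self.qc_sd <= 0:
            raise ValidationError("qc_sd must be > 0")
        if not 0.0 < self.fdr_alpha < 1.0:
            raise ValidationError("fdr_alpha must be in (0, 1)")
        if not 0.0 <= self.constraint_weight <= 1.0:
            raise ValidationError("constraint_weight must be in [0, 1]")
        return self

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data).validate()
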