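"""SUVR normalization and cohort-level spatial-correlation QC.

SUVR (standardized uptake value ratio) divides every voxel by the mean
intensity inside a reference region (cerebellar cortex in amyloid studies),
removing the per-subject global scale b_i of the mixing model.  The QC step
flags subjects whose spatial correlation with the cohort mean pattern falls
more than ``n_sd`` standard deviations below the mean correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .volumes import BrainMask, ValidationError, Volume

__all__ = ["compute_suvr", "flag_outliers", "QCReport", "NormalizationError"]


class NormalizationError(ValueError):
    """Reference region empty or with nonpositive mean intensity."""


def compute_suvr(volume: Volume, reference_mask: BrainMask):
    """Scale a volume to SUVR against a reference region.

    Returns ``(suvr_volume, b)`` where ``b = 1 / mean(reference voxels)`` and
    ``suvr_volume = b * volume``; the output's reference-region mean is 1.
    Idempotent: applying it twice equals applying it once.
    """
    ref_values = reference_mask.flatten(volume)
    if ref_values.size == 0:
        raise NormalizationError("reference mask is empty")
    ref_mean = float(ref_values.mean())
    if not np.isfinite(ref_mean) or ref_mean <= 0:
        raise NormalizationError(
            f"reference-region mean must be positive, got {ref_mean}"
        )
    b = 1.0 / ref_mean
    return volume.like(volume.data * b), b


def suvr_cohort(volumes, reference_mask: BrainMask):
    """Apply :func:`compute_suvr` to a cohort; returns (volumes, b vector)."""
    out, bs = [], []
    for v in volumes:
        s, b = compute_suvr(v, reference_mask)
        out.append(s)
        bs.append(b)
    return out, np.asarray(bs)


@dataclass(frozen=True)
class QCReport:
    """Per-subject correlation to the cohort mean and keep/exclude status."""

    correlations: np.ndarray
    status: np.ndarray           # "kept" / "excluded"
    cutoff: float                # mean(r) - n_sd * sd(r)
    n_sd: float
    subject_ids: tuple = ()

    @property
    def kept(self) -> np.ndarray:
        return np.where(self.status == "kept")[0]

    @property
    def excluded(self) -> np.ndarray:
        return np.where(self.status == "excluded")[0]

    def to_frame(self) -> pd.DataFrame:
        ids = (
            list(self.subject_ids)
            if len(self.subject_ids) == len(self.correlations)
            else list(range(len(self.correlations)))
        )
        return pd.DataFrame(
            {
                "subject_id": ids,
                "correlation": self.correlations,
                "status": self.status,
                "cutoff": self.cutoff,
            }
        )


def flag_outliers(X: np.ndarray, n_sd: float = 3.0, subject_ids=()) -> QCReport:
    """Flag subjects whose spatial correlation to the cohort mean is low.

    ``r_i`` is the Pearson correlation of row i with the columnwise cohort
    mean (the subject under test included; single pass, no iteration).
    Subjects with ``r_i < mean(r) - n_sd * sd(r)`` are excluded.  With zero
    spread in r no one is excluded and a warning is logged.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValidationError(
            f"outlier screening needs at least 3 subjects, got shape {X.shape}"
        )
    mean_pattern = X.mean(axis=0)
    mp = mean_pattern - mean_pattern.mean()
    mp_norm = np.linalg.norm(mp)
    rows = X - X.mean(axis=1, keepdims=True)
    denom = np.linalg.norm(rows, axis=1) * mp_norm
    if np.any(denom == 0):
        raise ValidationError("constant row or constant cohort mean")
    r = rows @ mp / denom
    sd = r.std(ddof=1)
    cutoff = float(r.mean() - n_sd * sd)
    if sd == 0:
        warnings.warn("zero spread in QC correlations; no exclusions")
        status = np.array(["kept"] * len(r))
    else:
        status = np.where(r < cutoff, "excluded", "kept")
    return QCReport(
        correlations=r,
        status=status,
        cutoff=cutoff,
        n_sd=float(n_sd),
        subject_ids=tuple(subject_ids),
    )
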