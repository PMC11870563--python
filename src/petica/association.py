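"""Age-association statistics for network loadings and atlas-ROI means.

Each unit (a network's loading column, or an anatomical ROI's mean SUVR) is
regressed on age with simple linear regression.  The standardized slope of
a simple regression is identical to the Pearson correlation, and its exact
two-sided p-value comes from the t distribution with N-2 degrees of
freedom.  Benjamini-Hochberg FDR correction is applied per unit system
(networks and ROIs separately, over all tested units) *before* screening;
screening then marks negatively-associated units ``x-neg`` (off-target
white-matter/CSF signal), plus metadata-flagged ``reference`` and
``x-non-gm`` units, leaving ``retained`` units for quantitative comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .volumes import ValidationError, Volume

__all__ = [
    "standardized_beta",
    "fdr_bh",
    "screen",
    "roi_means",
    "rank_report",
    "AgeAssociation",
    "AssociationResults",
    "REFERENCE_LINE",
]

#: -log10(0.05), the q = 0.05 reference line used in ranked plots
REFERENCE_LINE = -np.log10(0.05)

RETAINED = "retained"
X_NEG = "x-neg"
REFERENCE = "reference"
X_NON_GM = "x-non-gm"


def standardized_beta(values, ages):
    """Standardized slope (= Pearson r) and exact two-sided p-value.

    Requires N >= 3 and nonzero variance in both vectors.
    """
    values = np.asarray(values, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if values.shape != ages.shape or values.ndim != 1:
        raise ValidationError("values and ages must be 1D of equal length")
    if values.size < 3:
        raise ValidationError("need at least 3 observations")
    if values.std() == 0 or ages.std() == 0:
        raise ValidationError("zero variance: standardized beta undefined")
    res = stats.pearsonr(values, ages)
    return float(res.statistic), float(res.pvalue)


def fdr_bh(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    ``q_(i) = min_{j >= i}(p_(j) * m / j)`` capped at 1, mapped back to the
    input order.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def screen(frame: pd.DataFrame, flags: dict = None) -> pd.DataFrame:
    """Assign screening status to association results.

    ``frame`` needs columns ``unit`` and ``beta``.  ``flags`` maps unit name
    to ``"reference"`` or ``"x-non-gm"`` (for ROI systems); flagged units
    take that status, negative-beta units become ``x-neg``, everything else
    is ``retained``.  q-values are expected to have been computed over all
    tested units already; screening never recomputes them.
    """
    flags = flags or {}
    out = frame.copy()
    status = []
    for _, row in out.iterrows():
        flag = flags.get(row["unit"])
        if flag in (REFERENCE, X_NON_GM):
            status.append(flag)
        elif row["beta"] < 0:
            status.append(X_NEG)
        else:
            status.append(RETAINED)
    out["status"] = status
    return out


def roi_means(volume: Volume, labels: Volume, lut: dict = None) -> pd.Series:
    """Mean intensity per integer-labelled ROI.

    ``lut`` maps label id to ROI name; labels missing from the lut are
    reported under their integer id with a warning.  Labels absent from the
    volume grid are simply not reported.
    """
    if volume.data.shape != labels.data.shape:
        raise ValidationError("volume and label grids differ in shape")
    lab = np.round(labels.data).astype(int)
    ids = np.unique(lab)
    ids = ids[ids > 0]
    if ids.size == 0:
        return pd.Series(dtype=float)
    means = ndimage.mean(volume.data, labels=lab, index=ids)
    names = []
    for i in ids:
        if lut is not None and int(i) not in lut:
            import warnings

            warnings.warn(f"label {int(i)} missing from lookup table")
        names.append(lut.get(int(i), str(int(i))) if lut else f"roi-{int(i)}")
    return pd.Series(means, index=names, name="mean")


def roi_means_cohort(volumes, labels: Volume, lut: dict = None) -> pd.DataFrame:
    """Per-subject ROI means stacked into a subjects x ROI table."""
    return pd.DataFrame([roi_means(v, labels, lut) for v in volumes])


class AgeAssociation:
    """Age-association model for one unit system (networks or ROIs).

    Parameters
    ----------
    measures : DataFrame (subjects x units)
        Loading values or ROI mean SUVRs.
    ages : array
        Subject ages in years, aligned with the rows.
    flags : dict, optional
        Unit name -> "reference" / "x-non-gm" for screening.
    alpha : float
        FDR significance level used by the summary counts.
    """

    def __init__(self, measures: pd.DataFrame, ages, flags=None, alpha=0.05):
        measures = pd.DataFrame(measures)
        ages = np.asarray(ages, dtype=float)
        if len(measures) != len(ages):
            raise ValidationError("measures rows and ages length differ")
        self.measures = measures
        self.ages = ages
        self.flags = dict(flags or {})
        self.alpha = float(alpha)

    def fit(self) -> "AssociationResults":
        units, betas, ps = [], [], []
        for col in self.measures.columns:
            beta, p = standardized_beta(self.measures[col].to_numpy(), self.ages)
            units.append(col)
            betas.append(beta)
            ps.append(p)
        frame = pd.DataFrame({"unit": units, "beta": betas, "p": ps})
        frame["q"] = fdr_bh(frame["p"].to_numpy())
        frame = screen(frame, self.flags)
        return AssociationResults(model=self, frame=frame, alpha=self.alpha)


@dataclass
class AssociationResults:
    """Per-unit standardized beta, p, BH q and screening status."""

    model: AgeAssociation
    frame: pd.DataFrame
    alpha: float = 0.05

    @property
    def retained(self) -> pd.DataFrame:
        return self.frame[self.frame["status"] == RETAINED]

    @property
    def n_tested(self) -> int:
        return len(self.frame)

    def n_significant(self, alpha=None) -> int:
        """Retained units significant at q < alpha."""
        alpha = self.alpha if alpha is None else alpha
        return int((self.retained["q"] < alpha).sum())

    def summary(self) -> str:
        lines = [
            "Age association (simple linear regression; standardized beta = Pearson r)",
            f"  units tested: {self.n_tested}   FDR alpha: {self.alpha}",
            f"  retained after screening: {len(self.retained)}",
            f"  significant (q < {self.alpha}): {self.n_significant()}",
            "",
            self.frame.to_string(index=False, float_format=lambda x: f"{x:.4g}"),
        ]
        return "\n".join(lines)


def rank_report(results: dict) -> pd.DataFrame:
    """Ranked -log10(q) comparison table across unit systems.

    ``results`` maps a system name to a results frame (or
    :class:`AssociationResults`).  Retained units of each system are sorted
    by ascending q; the returned long table carries ``system``, ``rank``,
    ``unit``, ``q`` and ``neg_log10_q``.  The q = 0.05 reference line is the
    module constant :data:`REFERENCE_LINE` (~1.301).
    """
    rows = []
    for system, res in results.items():
        frame = res.frame if isinstance(res, AssociationResults) else res
        kept = frame[frame["status"] == RETAINED].sort_values(
            "q", kind="stable"
        )
        for rank, (_, row) in enumerate(kept.iterrows(), start=1):
            q = float(row["q"])
            rows.append(
                {
                    "system": system,
                    "rank": rank,
                    "unit": row["unit"],
                    "q": q,
                    "neg_log10_q": float(-np.log10(q)) if q > 0 else np.inf,
                }
            )
    return pd.DataFrame(rows, columns=["system", "rank", "unit", "q", "neg_log10_q"])
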