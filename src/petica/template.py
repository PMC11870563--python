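"""Split-half replication and template assembly.

The cohort is split into two independent halves, each decomposed by group
ICA, and components are matched one-to-one across halves by optimal
(Hungarian) assignment on the absolute spatial correlation matrix.  Pairs
below the replication threshold (default 0.4) are dropped; replicated pairs
matching a confound category (white matter, ventricles, brain-edge
artifacts, or the SUVR reference region) are excluded; the surviving pairs
are sign-aligned, z-scored, averaged and re-z-scored into the template used
as spatial priors for constrained ICA.
"""

from __future__ import annotations

import json
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .volumes import BrainMask, ValidationError

__all__ = [
    "ComponentPair",
    "Template",
    "split_half",
    "match_components",
    "classify_components",
    "build_template",
    "CANDIDATE",
]

CANDIDATE = "candidate"
CONFOUND_CATEGORIES = ("white_matter", "ventricle", "edge", "reference_region")


def split_half(subject_ids, seed: int = 0, stratify_by=None):
    """Split subjects into two disjoint, exhaustive halves (sizes differ <= 1).

    With ``stratify_by`` (a per-subject covariate such as age), subjects are
    sorted by the covariate and consecutive pairs are assigned randomly one
    to each half, which balances the covariate means between halves.
    """
    ids = list(subject_ids)
    n = len(ids)
    if n < 4:
        raise ValidationError(f"need at least 4 subjects to split, got {n}")
    rng = np.random.default_rng(seed)
    if stratify_by is None:
        order = rng.permutation(n)
    else:
        cov = np.asarray(stratify_by, dtype=float)
        if cov.shape != (n,):
            raise ValidationError("stratify_by must match subject_ids length")
        order = np.argsort(cov, kind="stable")
    group_a, group_b = [], []
    for start in range(0, n - 1, 2):
        i, j = order[start], order[start + 1]
        if rng.random() < 0.5:
            i, j = j, i
        group_a.append(ids[i])
        group_b.append(ids[j])
    if n % 2:
        (group_a if rng.random() < 0.5 else group_b).append(ids[order[-1]])
    return group_a, group_b


@dataclass(frozen=True)
class ComponentPair:
    """A matched component pair across halves, sign-aligned so r >= 0."""

    index_a: int
    index_b: int
    r: float          # |Pearson r| after sign alignment
    sign: int         # +/-1 applied to B's map

    def __post_init__(self):
        if not -1.0 - 1e-9 <= self.r <= 1.0 + 1e-9:
            raise ValidationError(f"correlation out of range: {self.r}")


def _row_corr(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix between rows of A and rows of B."""
    A = A - A.mean(axis=1, keepdims=True)
    B = B - B.mean(axis=1, keepdims=True)
    A = A / np.linalg.norm(A, axis=1, keepdims=True)
    B = B / np.linalg.norm(B, axis=1, keepdims=True)
    return A @ B.T


def match_components(S_A: np.ndarray, S_B: np.ndarray):
    """One-to-one matching of components across halves.

    Finds the assignment maximizing total absolute spatial correlation
    (optimal bipartite assignment) and sign-aligns each pair.  Rectangular
    inputs are allowed; unmatched components are simply absent from the
    returned pairs.  Returns pairs sorted by ``index_a``.
    """
    S_A = np.atleast_2d(np.asarray(S_A, dtype=float))
    S_B = np.atleast_2d(np.asarray(S_B, dtype=float))
    if S_A.shape[1] != S_B.shape[1]:
        raise ValidationError("component maps must share the voxel dimension")
    R = _row_corr(S_A, S_B)
    rows, cols = linear_sum_assignment(-np.abs(R))
    pairs = [
        ComponentPair(
            index_a=int(i),
            index_b=int(j),
            r=float(abs(R[i, j])),
            sign=int(np.sign(R[i, j]) or 1),
        )
        for i, j in zip(rows, cols)
    ]
    return sorted(pairs, key=lambda p: p.index_a)


def classify_components(
    S: np.ndarray,
    confound_masks: dict,
    analysis_mask: BrainMask = None,
    overrides: dict = None,
    top_fraction: float = 0.05,
    min_fraction: float = 0.5,
):
    """Assign a category to each component from confound-mask overlap.

    A component's top ``top_fraction`` voxels by |z| are located; the
    component is given the confound category whose mask contains the largest
    fraction of them, provided that fraction exceeds ``min_fraction``;
    otherwise it is a ``candidate`` network.  ``confound_masks`` maps
    category name to either a boolean grid / :class:`BrainMask` (flattened
    through ``analysis_mask``) or a boolean length-V vector.  Manual
    ``overrides`` (component index -> category) take precedence.
    """
    S = np.atleast_2d(np.asarray(S, dtype=float))
    C, V = S.shape
    flat_masks = {}
    for name, m in confound_masks.items():
        if isinstance(m, BrainMask):
            m = m.data
        m = np.asarray(m)
        if m.ndim == 3:
            if analysis_mask is None:
                raise ValidationError(
                    "3D confound masks require the analysis mask for flattening"
                )
            m = analysis_mask.flatten(m.astype(float)) > 0.5
        if m.shape != (V,):
            raise ValidationError(f"confound mask {name!r} has wrong size")
        flat_masks[name] = m.astype(bool)
    overrides = overrides or {}
    for idx, cat in overrides.items():
        if not 0 <= int(idx) < C:
            raise ValidationError(f"override index {idx} out of range")
        if cat not in CONFOUND_CATEGORIES + (CANDIDATE,):
            raise ValidationError(f"unknown category {cat!r}")

    n_top = max(1, int(round(top_fraction * V)))
    categories = []
    for k in range(C):
        if k in overrides:
            categories.append(overrides[k])
            continue
        z = S[k]
        z = (z - z.mean()) / (z.std() or 1.0)
        top = np.argsort(np.abs(z))[-n_top:]
        best_cat, best_frac = CANDIDATE, 0.0
        for name, m in flat_masks.items():
            frac = float(m[top].mean())
            if frac > best_frac:
                best_cat, best_frac = name, frac
        categories.append(best_cat if best_frac > min_fraction else CANDIDATE)
    return categories


@dataclass(frozen=True)
class Template:
    """Retained, labelled, pair-averaged network maps with provenance.

    Replicated pairs excluded by confound category are kept as labelled
    *nuisance maps*: constrained extraction adapts them alongside the
    networks so that white-matter/ventricular/edge signal is absorbed by
    its own components instead of leaking into network loadings.
    """

    maps: np.ndarray                 # (C_kept, V), z-scored
    labels: tuple                    # per retained map
    pair_correlations: np.ndarray    # per retained map
    exclusions: dict                 # reason -> count
    threshold: float
    provenance: dict = field(default_factory=dict)
    status: str = "ok"               # "ok" or "empty"
    nuisance_maps: np.ndarray = field(
        default_factory=lambda: np.empty((0, 0))
    )                                # (K, V), z-scored confound maps
    nuisance_labels: tuple = ()      # category per nuisance map

    @property
    def n_retained(self) -> int:
        return self.maps.shape[0]

    @property
    def n_excluded(self) -> int:
        return int(sum(self.exclusions.values()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": np.arange(self.n_retained),
                "label": self.labels,
                "pair_correlation": self.pair_correlations,
            }
        )

    def save(self, stem, mask: BrainMask) -> None:
        """Write 4D NIfTI maps plus sidecar metadata (TSV + JSON)."""
        stem = Path(stem)
        data = mask.unflatten_many(self.maps)
        nib.save(
            nib.Nifti1Image(data.astype(np.float32), mask.affine),
            str(stem.with_suffix(".nii.gz")),
        )
        if len(self.nuisance_maps):
            nui = mask.unflatten_many(self.nuisance_maps)
            nib.save(
                nib.Nifti1Image(nui.astype(np.float32), mask.affine),
                str(stem.parent / (stem.name + "_nuisance.nii.gz")),
            )
        self.to_frame().to_csv(
            stem.parent / (stem.name + "_components.tsv"), sep="\t", index=False
        )
        meta = {
            "threshold": self.threshold,
            "exclusions": self.exclusions,
            "status": self.status,
            "nuisance_labels": list(self.nuisance_labels),
            **self.provenance,
        }
        (stem.parent / (stem.name + "_meta.json")).write_text(
            json.dumps(meta, indent=2, default=str)
        )

    @classmethod
    def load(cls, stem, mask: BrainMask) -> "Template":
        stem = Path(stem)
        img = nib.load(str(stem.with_suffix(".nii.gz")))
        data = np.asarray(img.get_fdata())
        maps = np.stack([data[..., k][mask.data] for k in range(data.shape[-1])])
        frame = pd.read_csv(stem.parent / (stem.name + "_components.tsv"), sep="\t")
        meta = json.loads((stem.parent / (stem.name + "_meta.json")).read_text())
        nui_path = stem.parent / (stem.name + "_nuisance.nii.gz")
        nuisance = np.empty((0, 0))
        if nui_path.exists():
            nd = np.asarray(nib.load(str(nui_path)).get_fdata())
            nuisance = np.stack(
                [nd[..., k][mask.data] for k in range(nd.shape[-1])]
            )
        reserved = ("threshold", "exclusions", "status", "nuisance_labels")
        return cls(
            maps=maps,
            labels=tuple(frame["label"]),
            pair_correlations=frame["pair_correlation"].to_numpy(),
            exclusions={k: int(v) for k, v in meta["exclusions"].items()},
            threshold=float(meta["threshold"]),
            provenance={k: v for k, v in meta.items() if k not in reserved},
            status=meta.get("status", "ok"),
            nuisance_maps=nuisance,
            nuisance_labels=tuple(meta.get("nuisance_labels", ())),
        )


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / (sd if sd else 1.0)


def build_template(
    S_A: np.ndarray,
    S_B: np.ndarray,
    pairs,
    categories_a,
    categories_b=None,
    threshold: float = 0.4,
    labels=None,
    provenance=None,
) -> Template:
    """Assemble the replicated-network template from matched pairs.

    A pair is retained when its post-alignment correlation ``r`` is at least
    ``threshold`` and its category is ``candidate``.  Confound exclusion
    requires both halves to agree on the category; on disagreement the pair
    is kept as a candidate with a warning.  Each retained map is the mean of
    the two sign-aligned z-scored parent maps, re-z-scored.  The exclusion
    tally is reported by reason; an empty template is a valid, flagged
    outcome.
    """
    S_A = np.atleast_2d(np.asarray(S_A, dtype=float))
    S_B = np.atleast_2d(np.asarray(S_B, dtype=float))
    categories_a = list(categories_a)
    categories_b = list(categories_b) if categories_b is not None else None
    exclusions = Counter()
    retained_maps, retained_labels, retained_r = [], [], []
    nuisance_maps, nuisance_labels = [], []
    for pair in sorted(pairs, key=lambda p: -p.r):
        if pair.r < threshold:
            exclusions["below_threshold"] += 1
            continue
        cat_a = categories_a[pair.index_a]
        if categories_b is None:
            category = cat_a
        else:
            cat_b = categories_b[pair.index_b]
            if cat_a == cat_b:
                category = cat_a
            else:
                if CANDIDATE not in (cat_a, cat_b):
                    warnings.warn(
                        f"halves disagree on confound category for pair "
                        f"({pair.index_a}, {pair.index_b}): {cat_a} vs {cat_b}; "
                        "keeping as candidate"
                    )
                else:
                    warnings.warn(
                        f"halves disagree on category for pair "
                        f"({pair.index_a}, {pair.index_b}); keeping as candidate"
                    )
                category = CANDIDATE
        merged = _zscore(
            0.5 * (_zscore(S_A[pair.index_a]) + pair.sign * _zscore(S_B[pair.index_b]))
        )
        if category != CANDIDATE:
            exclusions[category] += 1
            nuisance_maps.append(merged)
            nuisance_labels.append(category)
            continue
        retained_maps.append(merged)
        retained_labels.append(
            labels[pair.index_a] if labels is not None else f"N{pair.index_a + 1}"
        )
        retained_r.append(pair.r)
    if retained_maps:
        maps = np.vstack(retained_maps)
        status = "ok"
    else:
        maps = np.empty((0, S_A.shape[1]))
        status = "empty"
        warnings.warn("no component pair survived replication and classification")
    return Template(
        maps=maps,
        labels=tuple(retained_labels),
        pair_correlations=np.asarray(retained_r, dtype=float),
        exclusions=dict(exclusions),
        threshold=float(threshold),
        provenance=provenance or {},
        status=status,
        nuisance_maps=(
            np.vstack(nuisance_maps)
            if nuisance_maps
            else np.empty((0, S_A.shape[1]))
        ),
        nuisance_labels=tuple(nuisance_labels),
    )
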