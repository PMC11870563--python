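"""Reference-constrained ICA: adapt template networks to a new cohort.

For each template (reference) network the estimator runs a one-unit
fixed-point optimization over the PCA-whitened cohort space that jointly
maximizes a log-cosh negentropy approximation of the candidate spatial
source and its correlation with the reference (weighted-sum scalarization,
weight ``lam``), with Gram-Schmidt decorrelation against already-extracted
sources.  The whitened search space has one dimension per template
component (networks plus nuisance maps), and the weight vector is
initialized at the whitened projection of the reference, so the procedure
is deterministic for a given cohort and template.  Signs follow each
reference's own peak-voxel orientation, making the output invariant to
flipping a reference's sign.

Subject loadings are the least-squares projection of the raw data onto the
adapted network maps together with the template's nuisance (confound) maps
and an intercept: covarying out the known white-matter/ventricular/edge
patterns keeps their subject-varying signal out of the network loadings.
Because the projection acts on the raw data, SUVR scaling transfers exactly
to the loadings post hoc — rescaling the data by diag(b) multiplies loading
row i by b_i without changing the maps (:func:`rescale_loadings`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .groupica import pca_reduce
from .template import Template
from .volumes import ValidationError

__all__ = [
    "ConstrainedICA",
    "ConstrainedICAResults",
    "extract_networks",
    "rescale_loadings",
]


def rescale_loadings(A: np.ndarray, b) -> np.ndarray:
    """Apply per-subject SUVR factors to a mixing matrix: row i -> b_i * row i."""
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float)
    if b.shape != (A.shape[0],):
        raise ValidationError(
            f"need one scale per subject: {b.shape} vs {A.shape[0]} rows"
        )
    if np.any(b <= 0) or not np.all(np.isfinite(b)):
        raise ValidationError("scaling factors must be strictly positive and finite")
    return A * b[:, None]


def _zscore_rows(M: np.ndarray) -> np.ndarray:
    M = M - M.mean(axis=1, keepdims=True)
    nrm = M.std(axis=1, keepdims=True)
    nrm[nrm == 0] = 1.0
    return M / nrm


class ConstrainedICA:
    """Constrained ICA model: cohort data plus reference maps.

    Parameters
    ----------
    X : array (N, V)
        Subject matrix on the same mask as the references.
    references : Template or array (C_kept, V)
        Network priors to adapt.  A :class:`~petica.template.Template` also
        supplies its nuisance (confound) maps.
    nuisance : array (K, V), optional
        Confound spatial patterns used as fixed regressors when computing
        loadings (overrides the template's nuisance maps if given).
    lam : float in [0, 1]
        Weight of the reference-correlation objective against negentropy.
    n_reduce : int, optional
        Dimension of the whitened search space; defaults to the total
        template component count (networks + nuisance), capped at N - 1.
    corr_floor : float
        Components whose optimum correlates with their reference below this
        value are flagged ``non_adapted`` (status, not an exception).
    max_mutual_corr : float
        Decorrelation cap between extracted components: Gram-Schmidt
        deflation shrinks the projection on earlier components only down to
        this correlation, not to zero.  Spatially overlapping brain sources
        are not exactly orthogonal, and forcing orthogonality distorts them;
        the cap keeps the independence pressure while tolerating the
        structural overlap.
    """

    def __init__(
        self,
        X,
        references,
        nuisance=None,
        lam: float = 0.7,
        n_reduce: int = None,
        tol: float = 1e-5,
        max_iter: int = 200,
        corr_floor: float = 0.1,
        max_mutual_corr: float = 0.25,
        subject_ids=None,
        labels=None,
    ):
        X = np.asarray(X, dtype=float)
        if isinstance(references, Template):
            if labels is None:
                labels = list(references.labels)
            if nuisance is None and len(references.nuisance_maps):
                nuisance = references.nuisance_maps
            references = references.maps
        R = np.atleast_2d(np.asarray(references, dtype=float))
        if R.shape[1] != X.shape[1]:
            raise ValidationError("references and data must share the voxel grid")
        if nuisance is not None and len(nuisance):
            nuisance = np.atleast_2d(np.asarray(nuisance, dtype=float))
            if nuisance.shape[1] != X.shape[1]:
                raise ValidationError("nuisance maps must share the voxel grid")
        else:
            nuisance = np.empty((0, X.shape[1]))
        C = R.shape[0]
        if C > min(X.shape[0] - 1, X.shape[1]):
            raise ValidationError("more references than min(N-1, V)")
        if not 0.0 <= lam <= 1.0:
            raise ValidationError("lam must be in [0, 1]")
        self.X = X
        self.references = R
        self.nuisance = nuisance
        self.lam = float(lam)
        self.n_reduce = (
            int(n_reduce)
            if n_reduce is not None
            else min(X.shape[0] - 1, C + nuisance.shape[0])
        )
        self.tol = tol
        self.max_iter = max_iter
        self.corr_floor = corr_floor
        self.max_mutual_corr = float(max_mutual_corr)
        self.subject_ids = (
            list(subject_ids) if subject_ids is not None else list(range(X.shape[0]))
        )
        self.labels = (
            list(labels) if labels is not None else [f"N{k + 1}" for k in range(C)]
        )

    def fit(self, seed: int = 0) -> "ConstrainedICAResults":
        """Adapt each reference to the cohort; ``seed`` is accepted for API
        symmetry (the initialization is the deterministic reference
        projection)."""
        X, R = self.X, self.references
        C, V = R.shape
        Z, reduction = pca_reduce(X, self.n_reduce, cap_to_rank=True)
        # voxel-center the whitened rows and re-whiten exactly: spatial
        # correlations (the reference objective) live in the centered space
        Z = Z - Z.mean(axis=1, keepdims=True)
        L = np.linalg.cholesky(Z @ Z.T / Z.shape[1])
        Z = np.linalg.solve(L, Z)
        # z-score references: correlation objective, scale-free.  Each
        # reference is oriented by the sign of its own peak-|value| voxel, so
        # the output convention is invariant to flipping a reference's sign.
        Rz = _zscore_rows(R)
        Rz = Rz / np.linalg.norm(Rz, axis=1, keepdims=True)
        peak_sign = np.sign(
            Rz[np.arange(C), np.argmax(np.abs(Rz), axis=1)]
        )
        peak_sign[peak_sign == 0] = 1.0
        Rz = Rz * peak_sign[:, None]
        lam = self.lam
        ws = []
        corrs = np.zeros(C)
        statuses = []
        n_iters = np.zeros(C, dtype=int)
        for k in range(C):
            ref = Rz[k]
            w = self._orthonormalize(Z @ ref, ws)
            w_ref = (Z @ ref) / V
            nrm = np.linalg.norm(w_ref)
            if nrm == 0:
                raise ValidationError(
                    "degenerate reference (zero whitened projection)"
                )
            w_ref = w_ref / nrm
            converged = False
            for it in range(self.max_iter):
                s = w @ Z
                g = np.tanh(s)
                w_ica = (Z @ g) / V - (1.0 - g**2).mean() * w
                # unit-normalize both objective directions and orient the
                # one-unit negentropy step along the current iterate (the
                # fixed point is sign-symmetric); this makes lam a
                # scale-free trade-off and keeps the combined ascent stable
                nrm = np.linalg.norm(w_ica)
                if nrm > 0:
                    w_ica = w_ica / nrm
                    if w_ica @ w < 0:
                        w_ica = -w_ica
                else:
                    w_ica = w
                w_new = (1.0 - lam) * w_ica + lam * w_ref
                w_new = self._orthonormalize(w_new, ws)
                if w_new @ w < 0:
                    w_new = -w_new
                delta = 1.0 - abs(float(w_new @ w))
                w = w_new
                n_iters[k] = it + 1
                if delta < self.tol:
                    converged = True
                    break
            s = w @ Z
            r = self._corr(s, ref)
            if r < 0:
                w, s, r = -w, -s, -r
            corrs[k] = r
            if r < self.corr_floor:
                statuses.append("non_adapted")
            elif converged:
                statuses.append("converged")
            else:
                statuses.append("max_iter")
            ws.append(w)
        Wmat = np.vstack(ws)
        maps = Wmat @ Z
        # mixing-model loadings: least squares of the raw data on the
        # adapted network maps together with the (non-orthogonalized)
        # nuisance confound patterns and an intercept; covarying out the
        # confounds keeps their subject-varying signal out of the network
        # loadings.  Under diag(b) rescaling of X the loading rows scale
        # exactly by b_i.
        design = [maps]
        if len(self.nuisance):
            design.append(_zscore_rows(self.nuisance))
        design.append(np.ones((1, V)))
        D = np.vstack(design)
        coef = np.linalg.lstsq(D.T, X.T, rcond=None)[0].T
        loadings = coef[:, :C]
        return ConstrainedICAResults(
            model=self,
            maps=maps,
            loadings=loadings,
            reference_correlations=corrs,
            statuses=tuple(statuses),
            n_iters=n_iters,
            seed=seed,
        )

    def _orthonormalize(self, w, previous):
        """Partial Gram-Schmidt: shrink correlations with already-extracted
        components down to ``max_mutual_corr`` (in the whitened space the
        correlation between extracted maps equals the dot product of their
        unit weight vectors)."""
        cap = self.max_mutual_corr
        nrm = np.linalg.norm(w)
        if nrm == 0:
            raise ValidationError("degenerate reference (zero whitened projection)")
        w = w / nrm
        for _ in range(3):
            adjusted = False
            for p in previous:
                c = w @ p
                if abs(c) > cap:
                    w = w - (c - np.sign(c) * cap) * p
                    adjusted = True
            nrm = np.linalg.norm(w)
            if nrm == 0:
                raise ValidationError(
                    "degenerate reference (zero whitened projection)"
                )
            w = w / nrm
            if not adjusted:
                break
        return w

    @staticmethod
    def _corr(a, b):
        a = a - a.mean()
        b = b - b.mean()
        return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))


@dataclass
class ConstrainedICAResults:
    """Cohort-adapted maps, subject loadings, and per-component diagnostics."""

    model: ConstrainedICA
    maps: np.ndarray                    # (C_kept, V)
    loadings: np.ndarray                # (N, C_kept), raw-data projection
    reference_correlations: np.ndarray  # per component, >= 0 by convention
    statuses: tuple
    n_iters: np.ndarray
    seed: int

    @property
    def n_components(self) -> int:
        return self.maps.shape[0]

    def rescaled_loadings(self, b) -> np.ndarray:
        """SUVR-rescaled loadings (row i multiplied by b_i)."""
        return rescale_loadings(self.loadings, b)

    def loadings_frame(self, b=None) -> pd.DataFrame:
        """Loading table (subject x component); raw, plus rescaled if ``b``."""
        labels = self.model.labels[: self.n_components]
        frame = pd.DataFrame(
            self.loadings, index=self.model.subject_ids, columns=labels
        )
        if b is not None:
            rescaled = self.rescaled_loadings(b)
            for j, lab in enumerate(labels):
                frame[f"{lab}_suvr"] = rescaled[:, j]
        frame.index.name = "subject_id"
        return frame

    def summary(self) -> str:
        lines = [
            "Constrained ICA (reference-guided extraction)",
            f"  subjects: {self.model.X.shape[0]}   voxels: {self.model.X.shape[1]}",
            f"  components: {self.n_components}   lambda: {self.model.lam}",
            f"  nuisance regressors: {self.model.nuisance.shape[0]}",
        ]
        for lab, r, st, it in zip(
            self.model.labels, self.reference_correlations, self.statuses, self.n_iters
        ):
            lines.append(f"  {lab}: ref corr {r:.3f}  [{st}, {it} iters]")
        return "\n".join(lines)


def extract_networks(
    X, template, lam: float = 0.7, seed: int = 0, **kwargs
) -> ConstrainedICAResults:
    """One-call wrapper: ``ConstrainedICA(X, template).fit(seed)``."""
    return ConstrainedICA(X, template, lam=lam, **kwargs).fit(seed=seed)
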