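"""Spatial group ICA: PCA whitening plus natural-gradient Infomax.

One-volume-per-subject PET data is decomposed source-based-morphometry
style: the N x V subject matrix X is voxelwise centered across subjects,
reduced to C whitened rows by PCA, and unmixed with Infomax ICA (logistic
nonlinearity, natural-gradient updates).  The result is the mixing model

    X  ~=  A_{N x C}  S_{C x V}

with S the spatial components and A the subject loading coefficients.
Components are stored raw ("no scaling of components"); z-scored maps are a
reporting view.  Sign/permutation indeterminacy is left to matching time.

Two loading conventions are exposed on the results object:

* ``loadings`` — least squares of the *raw* data on S.  This is the literal
  mixing-model definition and is exactly equivariant under per-subject
  rescaling (SUVR): decomposing diag(b) X multiplies row i by b_i.
* ``loadings_centered`` — least squares of the centered data on S; its
  reconstruction residual equals the PCA-discarded variance exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .volumes import ValidationError

__all__ = [
    "pca_reduce",
    "PCAReduction",
    "infomax",
    "GroupICA",
    "GroupICAResults",
    "fit_group_ica",
]


@dataclass(frozen=True)
class PCAReduction:
    """Whitening operator and bookkeeping from the PCA step."""

    mean: np.ndarray                 # (V,) voxelwise mean across subjects
    whitening: np.ndarray            # (C, N): Z = whitening @ (X - mean)
    explained_variance_: np.ndarray  # top-C eigenvalues of Xc Xc^T / (V - 1)
    total_variance: float            # sum of all eigenvalues
    discarded_ss: float              # ||Xc||_F^2 - ||retained||^2

    @property
    def retained_variance(self) -> float:
        return float(self.explained_variance_.sum())


def pca_reduce(X: np.ndarray, n_components: int, cap_to_rank: bool = False):
    """Center voxelwise and whiten the subject matrix to C rows.

    Returns ``(Z, reduction)`` with ``Z`` of shape (C, V) whose rows are
    uncorrelated with unit variance over voxels, and the stored reduction
    operator for back-projection.  ``n_components`` must satisfy
    ``C <= min(N - 1, V)``.  With ``cap_to_rank`` the order is silently
    reduced to the numerical rank of the centered data (useful when the
    cohort is exactly low-rank, e.g. noiseless mixtures).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValidationError("X must be 2D (subjects x voxels)")
    N, V = X.shape
    C = int(n_components)
    if not 1 <= C <= min(N - 1, V):
        raise ValidationError(
            f"model order {C} must be in [1, min(N-1, V)] = [1, {min(N - 1, V)}]"
        )
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int((s > 1e-10 * s[0]).sum())
    if rank < C:
        if cap_to_rank:
            C = rank
        else:
            raise ValidationError(
                f"data rank {rank} below requested model order {C}"
            )
    eigvals = s**2 / (V - 1)
    Z = np.sqrt(V) * Vt[:C]
    whitening = np.sqrt(V) * (U[:, :C] / s[:C]).T
    reduction = PCAReduction(
        mean=mean,
        whitening=whitening,
        explained_variance_=eigvals[:C],
        total_variance=float(eigvals.sum()),
        discarded_ss=float((s[C:] ** 2).sum()),
    )
    return Z, reduction


def infomax(
    Z: np.ndarray,
    seed: int = 0,
    learning_rate: float = 0.01,
    anneal_deg: float = 60.0,
    anneal_step: float = 0.9,
    tol: float = 1e-6,
    max_iter: int = 512,
):
    """Natural-gradient Infomax ICA on whitened data.

    Maximizes the Infomax objective with a logistic nonlinearity via
    block-stochastic natural-gradient ascent (block size ceil(sqrt(V/3)),
    sample order reshuffled each pass from ``seed``, learning rate annealed
    when the weight-update direction turns by more than ``anneal_deg``).
    The unmixing matrix is initialized at a seeded random rotation.

    Returns ``(W, info)`` with ``W`` the C x C unmixing transform and
    ``info`` reporting convergence (weight-change norm below ``tol``) or
    that the step budget was exhausted — non-convergence is a reported
    status, never an exception.
    """
    Z = np.asarray(Z, dtype=float)
    C, V = Z.shape
    rng = np.random.default_rng(seed)
    # random rotation start: seed-dependent basin, QR for orthogonality
    q, _ = np.linalg.qr(rng.standard_normal((C, C)))
    W = q
    block = int(np.ceil(np.sqrt(V / 3.0)))
    eye = np.eye(C)
    lrate = learning_rate
    delta_prev = None
    change = np.inf
    converged = False
    n_iter = 0
    for it in range(max_iter):
        n_iter = it + 1
        perm = rng.permutation(V)
        W_old = W.copy()
        for start in range(0, V - block + 1, block):
            u = W @ Z[:, perm[start : start + block]]
            y = expit(u)
            W = W + lrate * ((eye + (1.0 - 2.0 * y) @ u.T / block) @ W)
            if not np.all(np.isfinite(W)) or np.abs(W).max() > 1e8:
                # blowup: restart from a fresh rotation at half the rate
                lrate *= 0.5
                q, _ = np.linalg.qr(rng.standard_normal((C, C)))
                W = q
                W_old = W.copy()
                delta_prev = None
        delta = (W - W_old).ravel()
        change = float(np.linalg.norm(delta))
        if delta_prev is not None:
            denom = np.linalg.norm(delta) * np.linalg.norm(delta_prev)
            if denom > 0:
                cos = float(delta @ delta_prev / denom)
                if np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))) > anneal_deg:
                    lrate *= anneal_step
        delta_prev = delta
        if change < tol:
            converged = True
            break
    info = {
        "converged": converged,
        "n_iter": n_iter,
        "final_change": change,
        "final_lrate": lrate,
    }
    return W, info


def _zscore_rows(S: np.ndarray) -> np.ndarray:
    mu = S.mean(axis=1, keepdims=True)
    sd = S.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (S - mu) / sd


class GroupICA:
    """Group spatial ICA model for an N x V subject matrix.

    Parameters
    ----------
    X : array (N, V)
        Subject matrix (SUVR or raw uptake), no missing values.
    n_components : int
        ICA model order C, at most min(N-1, V).
    subject_ids : sequence, optional
        Carried through to the results for labelling.
    """

    def __init__(
        self,
        X,
        n_components,
        subject_ids=None,
        learning_rate=0.01,
        tol=1e-6,
        max_iter=512,
    ):
        X = np.asarray(X, dtype=float)
        if not np.all(np.isfinite(X)):
            raise ValidationError("X contains non-finite values")
        if X.shape[0] < 2:
            raise ValidationError("need at least 2 subjects")
        self.X = X
        self.n_components = int(n_components)
        self.subject_ids = (
            list(subject_ids)
            if subject_ids is not None
            else list(range(X.shape[0]))
        )
        self.learning_rate = learning_rate
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, seed: int = 0) -> "GroupICAResults":
        Z, reduction = pca_reduce(self.X, self.n_components)
        W, info = infomax(
            Z,
            seed=seed,
            learning_rate=self.learning_rate,
            tol=self.tol,
            max_iter=self.max_iter,
        )
        S = W @ Z
        Xc = self.X - reduction.mean
        # order components by the variance they carry in the data
        A_c = np.linalg.lstsq(S.T, Xc.T, rcond=None)[0].T
        power = (A_c**2).sum(axis=0) * (S**2).sum(axis=1)
        order = np.argsort(power)[::-1]
        S = S[order]
        A_c = A_c[:, order]
        A_raw = np.linalg.lstsq(S.T, self.X.T, rcond=None)[0].T
        resid = Xc - A_c @ S
        return GroupICAResults(
            model=self,
            maps_raw=S,
            loadings=A_raw,
            loadings_centered=A_c,
            unmixing=W[order],
            reduction=reduction,
            resid_ss=float((resid**2).sum()),
            converged=info["converged"],
            n_iter=info["n_iter"],
            seed=seed,
        )


@dataclass
class GroupICAResults:
    """Fitted spatial components and subject loadings.

    ``maps_raw`` keeps the estimator's unscaled components; ``maps`` is the
    z-scored reporting view (each row mean 0, SD 1 over the mask).
    """

    model: GroupICA
    maps_raw: np.ndarray         # (C, V)
    loadings: np.ndarray         # (N, C), raw-data projection (Eq-style A)
    loadings_centered: np.ndarray
    unmixing: np.ndarray
    reduction: PCAReduction
    resid_ss: float
    converged: bool
    n_iter: int
    seed: int

    @property
    def n_components(self) -> int:
        return self.maps_raw.shape[0]

    @property
    def maps(self) -> np.ndarray:
        """Z-scored spatial maps (reporting view)."""
        return _zscore_rows(self.maps_raw)

    def loadings_frame(self) -> pd.DataFrame:
        cols = [f"IC{k + 1}" for k in range(self.n_components)]
        return pd.DataFrame(
            self.loadings, index=self.model.subject_ids, columns=cols
        )

    def summary(self) -> str:
        ev = self.reduction.explained_variance_
        lines = [
            "Group spatial ICA (Infomax)",
            f"  subjects: {self.model.X.shape[0]}   voxels: {self.model.X.shape[1]}",
            f"  model order: {self.n_components}   seed: {self.seed}",
            f"  converged: {self.converged} after {self.n_iter} iterations",
            f"  PCA retained variance: {ev.sum() / self.reduction.total_variance:.1%}",
            f"  reconstruction residual SS: {self.resid_ss:.4g}",
        ]
        return "\n".join(lines)


def fit_group_ica(X, n_components, seed=0, **kwargs) -> GroupICAResults:
    """One-call convenience wrapper: ``GroupICA(X, C).fit(seed)``."""
    return GroupICA(X, n_components, **kwargs).fit(seed=seed)
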