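"""Seeded generator of PET-like cohorts with known ground truth.

The generator emulates the structure of amyloid-tracer SUVR cohorts as a
linear mixing model: subject i's volume is

    x_i = b_i * (baseline + sum_c a_ic * s_c + eps_i)

where the s_c are spatially sparse, partially overlapping network maps plus
three confound maps (a white-matter-like shell, a ventricle-like central
blob, and a brain-edge rim), a_ic are per-subject loadings with optional
linear age effects, eps_i is white Gaussian voxel noise, and b_i is a
positive per-subject global scale (the quantity SUVR normalisation removes).
Network maps are sums of bilateral (mirror-placed) 3D Gaussian blobs, which
gives smooth, compact, super-Gaussian spatial sources that ICA can recover.

Everything is driven by one integer seed through independent substreams, so
regenerating with the same configuration is byte-identical and overriding
one ingredient (e.g. the subject scales) does not perturb the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .volumes import BrainMask, ValidationError, Volume

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "SourceSet",
    "SyntheticCohort",
    "generate_sources",
    "generate_cohort",
    "write_cohort",
]

NETWORK = "network"
WHITE_MATTER = "white_matter"
VENTRICLE = "ventricle"
EDGE = "edge"

#: mean loading per category (unitless uptake); WM binding runs hot for
#: amyloid tracers, ventricles/CSF and edge artifacts sit below gray matter.
_CATEGORY_MEANS = {NETWORK: 1.0, WHITE_MATTER: 1.5, VENTRICLE: 0.8, EDGE: 0.5}


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults define the standard fixture: a 30x36x30 grid at 2 mm, 120
    subjects, 6 networks plus the three confounds, moderate noise
    (SD 0.1 relative to unit-peak maps), no age effects, and +/-10% global
    subject scales.
    """

    n_subjects: int = 120
    n_networks: int = 6
    grid_shape: tuple = (30, 36, 30)
    voxel_size_mm: float = 2.0
    overlap: float = 0.1
    baseline: float = 1.0
    loading_jitter_sd: float = 0.3
    age_range: tuple = (55.0, 90.0)
    age_slopes: Optional[Sequence[float]] = None  # per network, default all 0
    noise_sd: float = 0.1
    scale_range: tuple = (0.9, 1.1)
    subject_scales: Optional[Sequence[float]] = None  # overrides scale_range
    seed: int = 0

    def resolved_age_slopes(self) -> np.ndarray:
        if self.age_slopes is None:
            return np.zeros(self.n_networks)
        slopes = np.asarray(self.age_slopes, dtype=float)
        if slopes.shape != (self.n_networks,):
            raise ValidationError(
                f"age_slopes must have length {self.n_networks}, got {slopes.shape}"
            )
        return slopes


@dataclass(frozen=True)
class GroundTruth:
    """Everything the generator knows and downstream estimators must recover."""

    true_maps: np.ndarray          # (C_total, *grid), unit max |value| each
    categories: tuple              # per map: network/white_matter/ventricle/edge
    true_loadings: np.ndarray      # (N, C_total)
    ages: np.ndarray               # years
    age_slopes: np.ndarray         # per map, loading units per standardized year
    noise_sd: float
    subject_scales: np.ndarray     # b_i > 0
    seed: int

    @property
    def network_indices(self) -> np.ndarray:
        return np.array([i for i, c in enumerate(self.categories) if c == NETWORK])


@dataclass(frozen=True)
class SourceSet:
    """Ground-truth spatial maps plus the geometry they live on."""

    maps: np.ndarray               # (C_total, *grid)
    categories: tuple
    mask: BrainMask
    reference_mask: BrainMask      # disjoint cerebellum-like reference blob
    atlas: Volume                  # integer labels partitioning the mask
    confound_masks: dict           # category -> boolean grid


@dataclass(frozen=True)
class SyntheticCohort:
    """A generated cohort: volumes, geometry, covariates and ground truth."""

    volumes: list                  # list of Volume
    mask: BrainMask
    reference_mask: BrainMask
    atlas: Volume
    confound_masks: dict
    covariates: pd.DataFrame       # subject_id, age, group
    truth: GroundTruth


def _affine(voxel_size_mm: float) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_size_mm
    return aff


def _ellipsoid_rho(shape) -> np.ndarray:
    """Normalized elliptic radius: <=1 inside the brain-like mask."""
    center = (np.asarray(shape) - 1) / 2.0
    semi = 0.45 * np.asarray(shape)
    grids = np.ogrid[: shape[0], : shape[1], : shape[2]]
    rho2 = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, center, semi))
    return np.sqrt(rho2)


def _gaussian_blob(shape, center, sigma) -> np.ndarray:
    grids = np.ogrid[: shape[0], : shape[1], : shape[2]]
    d2 = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, center, np.atleast_1d(sigma) * np.ones(3)))
    return np.exp(-0.5 * d2)


def semi_z(shape) -> float:
    """z semi-axis (voxels) of the ellipsoidal analysis mask."""
    return 0.45 * shape[2]


def _unit_peak(m: np.ndarray) -> np.ndarray:
    peak = np.abs(m).max()
    if peak <= 0:
        raise ValidationError("degenerate (all-zero) map")
    return m / peak


def _place_networks(
    n_networks, rng, shape, center, semi, in_mask, flat,
    ref_center, ref_radius, cap_net, cap_conf, conf_flat, max_tries,
    overlap, max_restarts: int = 8,
):
    """Rejection-sample bilateral blob networks; restart the whole set from
    a fresh (seed-derived) substream when a placement round dead-ends."""
    for _restart in range(max_restarts):
        net_maps = []
        failed = False
        for _ in range(n_networks):
            placed = None
            for _try in range(max_tries):
                sigma = rng.uniform(0.05, 0.08) * min(shape)
                # lateral center in a gray-matter band: inside the shell,
                # outside the ventricle zone, off the midline (bilateral)
                c = np.array(
                    [
                        rng.uniform(0.15, 0.32) * shape[0],  # left of midplane
                        center[1] + rng.uniform(-0.55, 0.55) * semi[1],
                        center[2] + rng.uniform(-0.45, 0.55) * semi[2],
                    ]
                )
                c[0] = center[0] - abs(c[0] - center[0])
                rho_c = np.sqrt((((c - center) / semi) ** 2).sum())
                if not (0.40 <= rho_c <= 0.62):
                    continue
                if np.sqrt(((c - ref_center) ** 2).sum()) < ref_radius + 2 * sigma:
                    continue
                mirror = c.copy()
                mirror[0] = 2 * center[0] - c[0]
                m = (
                    _gaussian_blob(shape, c, sigma)
                    + _gaussian_blob(shape, mirror, sigma)
                ) * in_mask
                if np.abs(m).max() <= 0:
                    continue
                m = _unit_peak(m)
                v = flat(m)
                ok = all(
                    abs(np.corrcoef(v, flat(prev))[0, 1]) <= cap_net
                    for prev in net_maps
                ) and all(
                    abs(np.corrcoef(v, cf)[0, 1]) <= cap_conf for cf in conf_flat
                )
                if ok:
                    placed = m
                    break
            if placed is None:
                failed = True
                break
            net_maps.append(placed)
        if not failed:
            return net_maps
    raise ValidationError(
        f"grid {shape} too small to place {n_networks} networks "
        f"with overlap <= {overlap}"
    )


def generate_sources(
    n_networks: int,
    grid_shape=(30, 36, 30),
    overlap: float = 0.1,
    seed: int = 0,
    voxel_size_mm: float = 2.0,
    max_tries: int = 8000,
) -> SourceSet:
    """Build ground-truth spatial maps on a brain-like ellipsoidal mask.

    Returns ``n_networks`` bilateral Gaussian-blob network maps plus one
    white-matter-like shell, one ventricle-like central blob and one map
    that is nonzero only on the mask boundary.  All maps have unit maximum
    absolute value.  Network placement is rejection-sampled so that pairwise
    spatial correlation between network maps stays at or below
    ``overlap + 0.2`` (the sampler enforces ``overlap + 0.15`` to leave
    margin).

    Raises a sizing :class:`ValidationError` when the grid is too small to
    place the requested blobs.
    """
    if n_networks < 1:
        raise ValidationError("n_networks must be >= 1")
    shape = tuple(int(s) for s in grid_shape)
    if int(np.prod(shape)) < 1000:
        raise ValidationError(f"grid {shape} too small (< 1000 voxels)")

    rng = np.random.default_rng(seed)
    affine = _affine(voxel_size_mm)
    rho = _ellipsoid_rho(shape)
    mask_grid = rho <= 1.0
    mask = BrainMask(mask_grid, affine)

    # confounds -------------------------------------------------------------
    eroded = ndimage.binary_erosion(mask_grid)
    edge_map = (mask_grid & ~eroded).astype(float)  # boundary rim only
    wm_map = np.exp(-0.5 * ((rho - 0.85) / 0.04) ** 2) * mask_grid
    center = (np.asarray(shape) - 1) / 2.0
    vent_sigma = np.maximum(np.asarray(shape) * 0.09, 1.5)
    vent_map = _gaussian_blob(shape, center, vent_sigma) * mask_grid

    # cerebellum-like reference region: small sphere near the inferior pole,
    # kept clear of the network placement zone below.
    ref_center = center.copy()
    ref_center[2] = center[2] - 0.5 * semi_z(shape)  # halfway down the z semi-axis
    ref_radius = max(2.0, 0.09 * min(shape))
    grids = np.ogrid[: shape[0], : shape[1], : shape[2]]
    ref_d2 = sum((g - c) ** 2 for g, c in zip(grids, ref_center))
    ref_grid = (ref_d2 <= ref_radius**2) & mask_grid
    if not ref_grid.any():
        raise ValidationError("grid too small to place the reference region")
    reference_mask = BrainMask(ref_grid, affine)

    # networks --------------------------------------------------------------
    flat = mask.flatten
    in_mask = mask_grid
    semi = 0.45 * np.asarray(shape)
    net_maps = []
    # sampler targets: network-network overlap is kept comfortably inside the
    # contract bound overlap + 0.2, and blobs are also kept nearly orthogonal
    # to the confound maps so that the planted sources are ICA-identifiable
    cap_net = max(0.12, overlap)
    cap_conf = 0.15
    conf_flat = [flat(_unit_peak(wm_map)), flat(_unit_peak(vent_map))]
    net_maps = _place_networks(
        n_networks, rng, shape, center, semi, in_mask, flat,
        ref_center, ref_radius, cap_net, cap_conf, conf_flat, max_tries,
        overlap,
    )

    maps = np.stack(
        net_maps + [_unit_peak(wm_map), _unit_peak(vent_map), _unit_peak(edge_map)]
    )
    categories = tuple([NETWORK] * n_networks + [WHITE_MATTER, VENTRICLE, EDGE])

    # integer "atlas": 3x3x3 blocks intersected with the mask -> hard-border
    # labels that fragment any blob straddling block boundaries.
    blocks = np.zeros(shape, dtype=int)
    edges0 = [np.linspace(0, s, 4).astype(int) for s in shape]
    label = 1
    for i in range(3):
        for j in range(3):
            for k in range(3):
                sl = (
                    slice(edges0[0][i], edges0[0][i + 1]),
                    slice(edges0[1][j], edges0[1][j + 1]),
                    slice(edges0[2][k], edges0[2][k + 1]),
                )
                blocks[sl] = label
                label += 1
    atlas_data = np.where(mask_grid, blocks, 0)
    atlas = Volume(atlas_data.astype(float), affine)

    confound_masks = {
        WHITE_MATTER: wm_map > 0.15 * wm_map.max(),
        VENTRICLE: vent_map > 0.15 * vent_map.max(),
        # rim dilated by one voxel so smoothed edge components still land in it
        EDGE: ndimage.binary_dilation(edge_map > 0) & mask_grid,
        "reference_region": ref_grid,
    }
    return SourceSet(maps, categories, mask, reference_mask, atlas, confound_masks)


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a full cohort of volumes plus its :class:`GroundTruth`.

    Subject i's volume is ``b_i * (baseline + sum_c a_ic s_c + eps_i)`` with
    ``a_ic = mu_c + slope_c * z(age_i) + jitter`` and i.i.d. Gaussian voxel
    noise inside the mask.  Ages are uniform over ``config.age_range`` and
    z(age) is standardized by the cohort mean/SD.
    """
    if config.n_subjects < 4:
        raise ValidationError("n_subjects must be >= 4")
    if config.noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")

    # independent substreams: overriding one ingredient leaves others intact
    ss = np.random.SeedSequence(config.seed)
    s_sources, s_ages, s_jitter, s_noise, s_scales = ss.spawn(5)

    sources = generate_sources(
        config.n_networks,
        config.grid_shape,
        overlap=config.overlap,
        seed=s_sources,
        voxel_size_mm=config.voxel_size_mm,
    )
    C_total = sources.maps.shape[0]
    N = config.n_subjects

    rng_ages = np.random.default_rng(s_ages)
    ages = rng_ages.uniform(*config.age_range, size=N)
    z_age = (ages - ages.mean()) / ages.std()

    slopes = np.zeros(C_total)
    slopes[: config.n_networks] = config.resolved_age_slopes()
    means = np.array([_CATEGORY_MEANS[c] for c in sources.categories])

    rng_jitter = np.random.default_rng(s_jitter)
    loadings = (
        means[None, :]
        + slopes[None, :] * z_age[:, None]
        + rng_jitter.normal(0.0, config.loading_jitter_sd, size=(N, C_total))
    )

    rng_noise = np.random.default_rng(s_noise)
    if config.subject_scales is not None:
        scales = np.asarray(config.subject_scales, dtype=float)
        if scales.shape != (N,):
            raise ValidationError(f"subject_scales must have length {N}")
    else:
        rng_scales = np.random.default_rng(s_scales)
        scales = rng_scales.uniform(*config.scale_range, size=N)
    if np.any(scales <= 0) or not np.all(np.isfinite(scales)):
        raise ValidationError("subject scales must be strictly positive and finite")

    mask_grid = sources.mask.data.astype(float)
    flat_maps = sources.maps.reshape(C_total, -1)
    grid_size = flat_maps.shape[1]
    volumes = []
    for i in range(N):
        signal = loadings[i] @ flat_maps
        noise = rng_noise.normal(0.0, 1.0, size=grid_size) * config.noise_sd
        vol = (config.baseline + signal.reshape(config.grid_shape) + noise.reshape(config.grid_shape))
        vol = scales[i] * vol * mask_grid
        volumes.append(Volume(vol, sources.mask.affine))

    truth = GroundTruth(
        true_maps=sources.maps,
        categories=sources.categories,
        true_loadings=loadings,
        ages=ages,
        age_slopes=slopes,
        noise_sd=config.noise_sd,
        subject_scales=scales,
        seed=config.seed,
    )
    covariates = pd.DataFrame(
        {
            "subject_id": [f"sub-{i:04d}" for i in range(N)],
            "age": ages,
            "group": ["synthetic"] * N,
        }
    )
    return SyntheticCohort(
        volumes=volumes,
        mask=sources.mask,
        reference_mask=sources.reference_mask,
        atlas=sources.atlas,
        confound_masks=sources.confound_masks,
        covariates=covariates,
        truth=truth,
    )


def rescaled(cohort: SyntheticCohort, scales) -> list:
    """Volumes of ``cohort`` with subject scales replaced by ``scales``.

    Uses generator linearity: the cohort is elementwise b_i-linear, so
    rescaling divides out the old b_i and applies the new one.
    """
    scales = np.asarray(scales, dtype=float)
    old = cohort.truth.subject_scales
    return [
        v.like(v.data * (s / o))
        for v, s, o in zip(cohort.volumes, scales, old)
    ]


def write_cohort(cohort: SyntheticCohort, outdir) -> Path:
    """Write the cohort to disk in the pipeline's on-disk layout.

    Per-subject NIfTI volumes, the analysis mask, the reference-region mask,
    the integer label volume, per-category confound masks, and a tab-
    delimited covariates table.
    """
    outdir = Path(outdir)
    (outdir / "volumes").mkdir(parents=True, exist_ok=True)
    for sid, vol in zip(cohort.covariates["subject_id"], cohort.volumes):
        vol.to_nifti(outdir / "volumes" / f"{sid}_pet.nii.gz")
    cohort.mask.to_nifti(outdir / "mask.nii.gz")
    cohort.reference_mask.to_nifti(outdir / "reference_mask.nii.gz")
    cohort.atlas.to_nifti(outdir / "atlas.nii.gz")
    for name, grid in cohort.confound_masks.items():
        BrainMask(grid, cohort.mask.affine).to_nifti(
            outdir / f"confound_{name}.nii.gz"
        )
    cohort.covariates.to_csv(outdir / "covariates.tsv", sep="\t", index=False)
    return outdir
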