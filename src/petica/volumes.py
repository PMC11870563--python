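"""Volume containers, mask flattening, and Gaussian smoothing.

Every stage of the pipeline operates on 3D brain volumes that share a grid
and affine (voxelwise alignment is assumed; no resampling or registration is
performed here).  The canonical data layout is:

* a :class:`Volume` — a 3D intensity grid plus a 4x4 voxel-to-world affine;
* a :class:`BrainMask` — a boolean grid defining the V analysis voxels and a
  fixed row-major flattening order, so that a cohort of N volumes becomes an
  N x V subject matrix.

The flatten/unflatten round trip is exact inside the mask and zero outside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "Volume",
    "BrainMask",
    "AlignmentError",
    "ValidationError",
    "flatten_cohort",
    "smooth",
    "fwhm_to_sigma",
]

#: full width at half maximum of a Gaussian equals sigma * 2*sqrt(2*ln 2)
_FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


class AlignmentError(ValueError):
    """Volumes/masks do not share grid shape or affine."""


class ValidationError(ValueError):
    """Input violates a documented precondition."""


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValidationError(f"affine must be 4x4, got {affine.shape}")
    return affine


@dataclass(frozen=True)
class Volume:
    """A 3D intensity grid with its voxel-to-world affine (mm)."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 3:
            raise ValidationError(f"volume data must be 3D, got ndim={data.ndim}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "affine", _check_affine(self.affine))

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def voxel_sizes(self) -> np.ndarray:
        """Per-axis voxel edge lengths in mm, derived from the affine."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def like(self, data: np.ndarray) -> "Volume":
        """New Volume with the same affine."""
        return Volume(np.asarray(data, dtype=float), self.affine)

    @classmethod
    def from_nifti(cls, path) -> "Volume":
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata(), dtype=float)
        if not np.all(np.isfinite(data)):
            raise ValidationError(f"non-finite values in {path}")
        return cls(data, np.asarray(img.affine))

    def to_nifti(self, path) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), self.affine), str(path))


@dataclass(frozen=True)
class BrainMask:
    """Boolean analysis mask with a fixed row-major flattening convention.

    ``flatten`` traverses the True voxels in C (row-major) order over
    (x, y, z) indices; ``unflatten`` inverts it exactly, writing zeros
    outside the mask.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        data = np.asarray(self.data).astype(bool)
        if data.ndim != 3:
            raise ValidationError(f"mask must be 3D, got ndim={data.ndim}")
        if not data.any():
            raise ValidationError("mask is empty")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "affine", _check_affine(self.affine))

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def check_aligned(self, other) -> None:
        if other.data.shape != self.data.shape:
            raise AlignmentError(
                f"grid shape mismatch: {other.data.shape} vs {self.data.shape}"
            )
        if not np.allclose(other.affine, self.affine, atol=1e-4):
            raise AlignmentError("affine mismatch")

    def flatten(self, volume) -> np.ndarray:
        """In-mask voxel values of ``volume`` as a length-V vector."""
        if isinstance(volume, Volume):
            self.check_aligned(volume)
            data = volume.data
        else:
            data = np.asarray(volume, dtype=float)
            if data.shape != self.data.shape:
                raise AlignmentError(
                    f"grid shape mismatch: {data.shape} vs {self.data.shape}"
                )
        return data[self.data]

    def unflatten(self, values: np.ndarray) -> Volume:
        """Volume with ``values`` written at the mask voxels, zero elsewhere."""
        values = np.asarray(values, dtype=float)
        if values.shape != (self.n_voxels,):
            raise ValidationError(
                f"expected {self.n_voxels} values, got {values.shape}"
            )
        out = np.zeros(self.data.shape, dtype=float)
        out[self.data] = values
        return Volume(out, self.affine)

    def unflatten_many(self, rows: np.ndarray) -> np.ndarray:
        """C x V matrix -> 4D array (x, y, z, component)."""
        rows = np.atleast_2d(np.asarray(rows, dtype=float))
        out = np.zeros(self.data.shape + (rows.shape[0],), dtype=float)
        for k, row in enumerate(rows):
            out[..., k][self.data] = row
        return out

    @classmethod
    def from_nifti(cls, path) -> "BrainMask":
        img = nib.load(str(path))
        return cls(np.asarray(img.get_fdata()) > 0.5, np.asarray(img.affine))

    def to_nifti(self, path) -> None:
        nib.save(
            nib.Nifti1Image(self.data.astype(np.uint8), self.affine), str(path)
        )


def flatten_cohort(volumes, mask: BrainMask) -> np.ndarray:
    """Stack a cohort of aligned volumes into the N x V subject matrix.

    Row i holds subject i's in-mask voxels in the mask's flatten order.
    """
    rows = [mask.flatten(v) for v in volumes]
    if not rows:
        raise ValidationError("empty cohort")
    return np.vstack(rows)


def fwhm_to_sigma(fwhm_mm: float) -> float:
    """Convert a Gaussian kernel FWHM (mm) to its standard deviation (mm)."""
    return float(fwhm_mm) / _FWHM_PER_SIGMA


def smooth(volume: Volume, fwhm_mm: float) -> Volume:
    """Gaussian-smooth a volume with an isotropic kernel of given FWHM (mm).

    The per-axis sigma in voxels is fwhm/(2*sqrt(2 ln 2)) divided by the
    voxel size from the affine.  Total intensity is conserved up to boundary
    truncation (zero padding outside the grid).  ``fwhm_mm == 0`` is the
    identity.
    """
    if fwhm_mm < 0:
        raise ValidationError(f"fwhm must be >= 0, got {fwhm_mm}")
    if fwhm_mm == 0:
        return volume
    sigma_vox = fwhm_to_sigma(fwhm_mm) / volume.voxel_sizes
    out = ndimage.gaussian_filter(volume.data, sigma=sigma_vox, mode="constant")
    return volume.like(out)
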