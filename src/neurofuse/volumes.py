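"""Volume data model, NIfTI I/O, masking, normalization and smoothing.

All per-subject images in a study live on one shared spatial frame
(:class:`VolumeGrid`).  Operations here are deliberately voxel-wise or
separable so that nothing depends on array memory order; grids are never
resampled — inputs are assumed pre-aligned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "VolumeGrid",
    "Volume",
    "BinaryMask",
    "ComponentStack",
    "GridMismatchError",
    "EmptyMaskError",
    "fwhm_to_sigma",
    "read_volume",
    "write_volume",
    "write_mask",
    "compute_mask",
    "minmax_normalize",
    "gaussian_smooth",
]

#: strict-greater gray-matter density threshold used to build subject masks
DEFAULT_MASK_THRESHOLD = 0.03

#: tolerance for comparing voxel sizes / affine entries of two grids (mm)
GRID_TOL = 1e-4


class GridMismatchError(ValueError):
    """Two volumes that must share a spatial frame do not."""


class EmptyMaskError(ValueError):
    """A brain mask ended up with zero included voxels."""


@dataclass(frozen=True)
class VolumeGrid:
    """Shared spatial frame: dimensions, voxel size and voxel->world affine."""

    dims: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float]
    affine: np.ndarray

    def __post_init__(self) -> None:
        dims = tuple(int(d) for d in self.dims)
        vox = tuple(float(v) for v in self.voxel_size_mm)
        object.__setattr__(self, "dims", dims)
        object.__setattr__(self, "voxel_size_mm", vox)
        aff = np.array(self.affine, dtype=float)  # copy: frozen below, never the caller's
        if aff.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {aff.shape}")
        if any(d < 1 for d in dims):
            raise ValueError(f"dims must all be >= 1, got {dims}")
        if any(v <= 0 for v in vox):
            raise ValueError(f"voxel sizes must be > 0, got {vox}")
        if abs(np.linalg.det(aff)) < 1e-12:
            raise ValueError("affine is singular")
        aff.setflags(write=False)
        object.__setattr__(self, "affine", aff)

    @classmethod
    def isotropic(cls, dims: Sequence[int], voxel_mm: float = 3.0) -> "VolumeGrid":
        """Axis-aligned grid with equal voxel edge length (convenience)."""
        aff = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
        return cls(tuple(dims), (voxel_mm,) * 3, aff)

    def matches(self, other: "VolumeGrid", tol: float = GRID_TOL) -> bool:
        return (
            self.dims == other.dims
            and np.allclose(self.voxel_size_mm, other.voxel_size_mm, atol=tol)
            and np.allclose(self.affine, other.affine, atol=tol)
        )

    def require_match(self, other: "VolumeGrid") -> None:
        if not self.matches(other):
            raise GridMismatchError(
                f"grids differ: dims {self.dims} vs {other.dims}, "
                f"voxels {self.voxel_size_mm} vs {other.voxel_size_mm}"
            )


def _check_values(values: np.ndarray, grid: VolumeGrid, what: str) -> np.ndarray:
    values = np.asarray(values, dtype=np.float64)
    if values.shape != grid.dims:
        raise ValueError(f"{what} shape {values.shape} != grid dims {grid.dims}")
    n_bad = int(np.size(values) - np.isfinite(values).sum())
    if n_bad:
        raise ValueError(f"{what} contains {n_bad} non-finite voxel(s)")
    return values


@dataclass
class Volume:
    """A single 3D scalar map on a :class:`VolumeGrid`."""

    grid: VolumeGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = _check_values(self.values, self.grid, "volume values")

    def copy_with(self, values: np.ndarray) -> "Volume":
        return Volume(self.grid, values)


@dataclass
class BinaryMask:
    """Boolean inclusion map derived from a gray-matter volume threshold."""

    grid: VolumeGrid
    included: np.ndarray
    source_threshold: float = DEFAULT_MASK_THRESHOLD

    def __post_init__(self) -> None:
        inc = np.asarray(self.included, dtype=bool)
        if inc.shape != self.grid.dims:
            raise ValueError(f"mask shape {inc.shape} != grid dims {self.grid.dims}")
        if not inc.any():
            raise EmptyMaskError(
                f"mask is empty: no voxel exceeds threshold {self.source_threshold}"
            )
        self.included = inc

    @property
    def n_voxels(self) -> int:
        return int(self.included.sum())


@dataclass
class ComponentStack:
    """K aligned component spatial maps (ICNs) for one subject."""

    grid: VolumeGrid
    maps: list[Volume] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.maps) < 1:
            raise ValueError("component stack needs at least one map")
        for i, m in enumerate(self.maps):
            if not self.grid.matches(m.grid):
                raise GridMismatchError(f"component {i} is on a different grid")

    @property
    def k(self) -> int:
        return len(self.maps)

    def as_array(self) -> np.ndarray:
        """(K, x, y, z) array view of the stack."""
        return np.stack([m.values for m in self.maps], axis=0)

    @classmethod
    def from_array(cls, grid: VolumeGrid, arr: np.ndarray) -> "ComponentStack":
        arr = np.asarray(arr, dtype=np.float64)
        if arr.ndim != 4:
            raise ValueError("expected a (K, x, y, z) array")
        return cls(grid, [Volume(grid, arr[i]) for i in range(arr.shape[0])])


# ---------------------------------------------------------------------------
# I/O


def _grid_from_nifti(img: nib.Nifti1Image) -> VolumeGrid:
    dims = tuple(int(d) for d in img.shape[:3])
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VolumeGrid(dims, zooms, np.asarray(img.affine, dtype=float))


def read_volume(path: Union[str, Path]) -> Union[Volume, ComponentStack]:
    """Read a 3D NIfTI as a Volume, or a 4D NIfTI as a ComponentStack.

    Rejects non-finite voxels (with a count) and dimensionalities other
    than 3 or 4.
    """
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    grid = _grid_from_nifti(img)
    if data.ndim == 3:
        return Volume(grid, data)
    if data.ndim == 4:
        arr = np.moveaxis(data, -1, 0)  # frames-last on disk -> K-first
        return ComponentStack.from_array(grid, arr)
    raise ValueError(f"{path}: expected a 3D or 4D image, got {data.ndim}D")


def write_volume(vol: Union[Volume, ComponentStack], path: Union[str, Path]) -> None:
    """Write a Volume (3D) or ComponentStack (4D, frames last) as NIfTI-1."""
    if isinstance(vol, ComponentStack):
        data = np.moveaxis(vol.as_array(), 0, -1)
        grid = vol.grid
    else:
        data = vol.values
        grid = vol.grid
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), grid.affine)
    img.header.set_zooms(grid.voxel_size_mm + ((1.0,) if data.ndim == 4 else ()))
    nib.save(img, str(path))


def write_mask(mask: BinaryMask, path: Union[str, Path]) -> None:
    img = nib.Nifti1Image(mask.included.astype(np.uint8), mask.grid.affine)
    img.header.set_zooms(mask.grid.voxel_size_mm)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Operations


def compute_mask(smri: Volume, threshold: float = DEFAULT_MASK_THRESHOLD) -> BinaryMask:
    """Voxels with gray-matter density strictly greater than ``threshold``.

    The comparison is strict (">"), and one mask per subject is derived
    from that subject's gray-matter map and reused for every channel.
    """
    included = smri.values > threshold
    return BinaryMask(smri.grid, included, source_threshold=float(threshold))


def minmax_normalize(vol: Volume, mask: BinaryMask) -> Volume:
    """Rescale in-mask values to [0, 1]; out-of-mask voxels become 0.

    The min and max are taken within the mask only.  A constant in-mask
    volume (zero range) yields all zeros with a warning rather than an
    error, so batch pipelines survive pathological inputs.
    """
    vol.grid.require_match(mask.grid)
    out = np.zeros(vol.grid.dims, dtype=np.float64)
    x = vol.values[mask.included]
    lo, hi = x.min(), x.max()
    if hi - lo <= 0.0:
        warnings.warn(
            "min-max normalization of a constant in-mask volume -> all zeros",
            RuntimeWarning,
            stacklevel=2,
        )
        return Volume(vol.grid, out)
    out[mask.included] = (x - lo) / (hi - lo)
    return Volume(vol.grid, out)


def fwhm_to_sigma(fwhm: float) -> float:
    """Gaussian sigma for a given full width at half maximum."""
    return float(fwhm) / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def gaussian_smooth(vol: Volume, fwhm: float, units: str = "mm") -> Volume:
    """Separable Gaussian smoothing at the given FWHM.

    ``units="mm"`` converts to voxels through the grid's voxel size (the
    usual neuroimaging convention); ``units="voxels"`` uses the value
    directly.  Boundary handling is zero-padded ("constant") convolution —
    masked volumes are already zero outside the brain.  ``fwhm == 0`` is
    the identity.
    """
    if fwhm < 0:
        raise ValueError(f"fwhm must be >= 0, got {fwhm}")
    if fwhm == 0:
        return Volume(vol.grid, vol.values.copy())
    if units == "mm":
        sigmas = [fwhm_to_sigma(fwhm) / v for v in vol.grid.voxel_size_mm]
    elif units == "voxels":
        sigmas = [fwhm_to_sigma(fwhm)] * 3
    else:
        raise ValueError(f"units must be 'mm' or 'voxels', got {units!r}")
    # truncate at 6 sigma: keeps the discrete kernel accurate to ~1e-8
    smoothed = ndimage.gaussian_filter(vol.values, sigma=sigmas, mode="constant",
                                       cval=0.0, truncate=6.0)
    return Volume(vol.grid, smoothed)
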