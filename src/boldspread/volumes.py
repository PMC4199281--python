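"""NIfTI volume I/O and voxel <-> template-mm coordinate mapping.

All volumes in a study must share one axis-aligned grid: a 3-D array, a
strictly positive per-axis voxel size in mm, and the template-mm coordinate
of voxel (0, 0, 0).  Rotated or sheared affines are rejected rather than
resampled — resampling belongs to preprocessing, and the sphere geometry in
:mod:`boldspread.spread` assumes axis-aligned mm coordinates.  Voxel indices
are 0-based; mm coordinates refer to voxel centers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "StatVolume",
    "MaskVolume",
    "GeometryError",
    "GridMismatchError",
    "read_stat_volume",
    "write_stat_volume",
    "read_mask",
    "write_mask",
    "voxel_to_mm",
    "mm_to_voxel",
    "check_same_grid",
]

#: tolerance for deciding that an affine is axis-aligned (relative to the
#: voxel size) and that two grids share voxel size / origin
_GRID_ATOL = 1e-4


class GeometryError(ValueError):
    """Raised for unsupported (rotated, sheared, flipped or 4-D) geometry."""


class GridMismatchError(ValueError):
    """Raised when two volumes that must share a grid do not."""


@dataclass
class StatVolume:
    """A subject x run 3-D grid of signed percent-signal-change values.

    Parameters
    ----------
    data:
        3-D float array of signed percent signal change (unitless %).
        Non-finite entries are replaced by 0 on construction (masked out).
    voxel_size:
        Per-axis spacing in mm, strictly positive.
    origin:
        Template-mm coordinate of voxel ``(0, 0, 0)``.
    subject_id, run_id, contrast:
        Labels; ``contrast`` is ``"positive"`` or ``"negative"``.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    subject_id: str = ""
    run_id: str = ""
    contrast: str = "positive"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise GeometryError(f"expected a 3-D array, got {self.data.ndim}-D")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        self.origin = tuple(float(v) for v in self.origin)
        if len(self.voxel_size) != 3 or len(self.origin) != 3:
            raise GeometryError("voxel_size and origin must be length-3")
        if any(v <= 0 for v in self.voxel_size):
            raise GeometryError(f"voxel_size must be strictly positive, got {self.voxel_size}")
        if self.contrast not in ("positive", "negative"):
            raise ValueError(f"contrast must be 'positive' or 'negative', got {self.contrast!r}")
        bad = ~np.isfinite(self.data)
        if bad.any():
            warnings.warn(
                f"{bad.sum()} non-finite voxels set to 0 "
                f"(subject={self.subject_id!r}, run={self.run_id!r})",
                stacklevel=2,
            )
            self.data = np.where(bad, 0.0, self.data)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-to-mm affine (diagonal scale + translation)."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.voxel_size)
        aff[:3, 3] = self.origin
        return aff

    def axis_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis mm coordinates of voxel centers."""
        return tuple(
            self.origin[a] + np.arange(self.shape[a]) * self.voxel_size[a] for a in range(3)
        )  # type: ignore[return-value]


@dataclass
class MaskVolume:
    """A binary 3-D mask (ROI or brain) on the same grid as its StatVolumes."""

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    label: str = field(default="brain")

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data) > 0
        if self.data.ndim != 3:
            raise GeometryError(f"expected a 3-D mask, got {self.data.ndim}-D")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        self.origin = tuple(float(v) for v in self.origin)
        if any(v <= 0 for v in self.voxel_size):
            raise GeometryError(f"voxel_size must be strictly positive, got {self.voxel_size}")
        if not self.data.any():
            raise ValueError(f"mask {self.label!r} has no nonzero voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.voxel_size)
        aff[:3, 3] = self.origin
        return aff


def _grid_from_affine(affine: np.ndarray, path: str) -> tuple[tuple, tuple]:
    """Extract (voxel_size, origin) from an affine; reject non-axis-aligned ones."""
    affine = np.asarray(affine, dtype=float)
    scales = np.diag(affine)[:3]
    off_diag = affine[:3, :3] - np.diag(scales)
    tol = _GRID_ATOL * max(1.0, float(np.abs(scales).max()))
    if np.abs(off_diag).max() > tol:
        raise GeometryError(
            f"{path}: affine has rotation/shear components; only axis-aligned "
            "grids are supported (resample upstream)"
        )
    if (scales <= 0).any():
        raise GeometryError(
            f"{path}: affine has non-positive scales {tuple(scales)}; axis flips "
            "are not supported"
        )
    return tuple(scales), tuple(affine[:3, 3])


def read_stat_volume(
    path: str | Path,
    subject_id: str = "",
    run_id: str = "",
    contrast: str = "positive",
) -> StatVolume:
    """Read a 3-D statistical map from a NIfTI file.

    Raises
    ------
    FileNotFoundError
        If the file does not exist.
    GeometryError
        For 4-D images or rotated/sheared/flipped affines.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise GeometryError(f"{path}: expected a 3-D image, got shape {data.shape}")
    voxel_size, origin = _grid_from_affine(img.affine, str(path))
    return StatVolume(
        data=np.asarray(data, dtype=np.float64),
        voxel_size=voxel_size,
        origin=origin,
        subject_id=subject_id,
        run_id=run_id,
        contrast=contrast,
    )


def write_stat_volume(vol: StatVolume, path: str | Path) -> None:
    """Write a StatVolume as NIfTI-1, preserving data/voxel_size/origin exactly."""
    img = nib.Nifti1Image(vol.data.astype(np.float64), vol.affine)
    nib.save(img, str(path))


def read_mask(path: str | Path, label: str = "brain") -> MaskVolume:
    """Read a binary mask (any nonzero voxel is in-mask) from NIfTI."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise GeometryError(f"{path}: expected a 3-D mask, got shape {data.shape}")
    voxel_size, origin = _grid_from_affine(img.affine, str(path))
    return MaskVolume(data=data, voxel_size=voxel_size, origin=origin, label=label)


def write_mask(mask: MaskVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine)
    nib.save(img, str(path))


def voxel_to_mm(index, vol: StatVolume | MaskVolume) -> np.ndarray:
    """Template-mm coordinate of a voxel center: origin + index * voxel_size."""
    index = np.asarray(index)
    if index.shape[-1] != 3:
        raise ValueError("index must be a length-3 triple (or array of them)")
    shape = np.asarray(vol.shape)
    if np.any(index < 0) or np.any(index >= shape):
        raise IndexError(f"voxel index {index} outside grid of shape {vol.shape}")
    return np.asarray(vol.origin) + index * np.asarray(vol.voxel_size)


def mm_to_voxel(mm, vol: StatVolume | MaskVolume) -> tuple[int, int, int]:
    """Nearest-voxel-center index for a template-mm coordinate."""
    mm = np.asarray(mm, dtype=float)
    idx = np.rint((mm - np.asarray(vol.origin)) / np.asarray(vol.voxel_size)).astype(int)
    shape = np.asarray(vol.shape)
    if np.any(idx < 0) or np.any(idx >= shape):
        raise IndexError(f"mm coordinate {tuple(mm)} maps outside grid of shape {vol.shape}")
    return tuple(int(i) for i in idx)


def check_same_grid(a: StatVolume | MaskVolume, b: StatVolume | MaskVolume) -> None:
    """Raise GridMismatchError unless a and b share shape, voxel size, and origin."""
    if a.shape != b.shape:
        raise GridMismatchError(f"shape mismatch: {a.shape} vs {b.shape}")
    if not np.allclose(a.voxel_size, b.voxel_size, atol=_GRID_ATOL):
        raise GridMismatchError(f"voxel_size mismatch: {a.voxel_size} vs {b.voxel_size}")
    if not np.allclose(a.origin, b.origin, atol=_GRID_ATOL):
        raise GridMismatchError(f"origin mismatch: {a.origin} vs {b.origin}")
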