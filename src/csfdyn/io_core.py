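"""Shared volumetric data model and NIfTI / gradient-table I/O.

All volumes are represented by thin dataclasses wrapping a numpy array plus a
4x4 voxel-to-world affine in millimetres.  Voxel indices are 0-based; world
coordinates are obtained through the affine (RAS+ assumed; orientation is
always read from the affine, never from header flags).  Gradient tables use
the FSL dialect: whitespace-separated ``.bval`` (one row of b-values, s/mm^2)
and ``.bvec`` (3 rows x N columns of unit direction vectors).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import nibabel as nib
import numpy as np

from .errors import FormatError, InsufficientDataError, ParameterError, ValidationError

__all__ = [
    "VolumeGrid",
    "Series4D",
    "GradientTable",
    "MaskVolume",
    "read_dwi",
    "write_dwi",
    "read_series",
    "write_series",
    "read_mask",
    "write_mask",
    "select_shells",
    "mask_volume_ml",
    "normalized_cp_volume",
]

#: absolute tolerance (s/mm^2) used when matching nominal shell b-values
DEFAULT_SHELL_TOLERANCE = 50.0

#: unit-norm tolerance for nonzero gradient vectors
_BVEC_NORM_TOL = 1e-3


def _voxel_dims(affine: np.ndarray) -> np.ndarray:
    """Voxel edge lengths (mm) = column norms of the affine's linear part."""
    return np.linalg.norm(np.asarray(affine)[:3, :3], axis=0)


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValidationError(f"affine must be 4x4, got {affine.shape}")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValidationError("affine linear part is singular")
    return affine


@dataclass
class VolumeGrid:
    """A 3D scalar lattice with a voxel-to-world transform (mm)."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValidationError(f"VolumeGrid needs 3D data, got {self.data.ndim}D")
        self.affine = _check_affine(self.affine)

    @property
    def voxel_dims(self) -> np.ndarray:
        return _voxel_dims(self.affine)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape


@dataclass
class Series4D:
    """A 4D lattice (x, y, z, t).

    ``t_spacing`` is the repetition time TR in seconds for resting-state
    series, or ``None`` for diffusion series where the fourth axis is a
    plain volume index.
    """

    data: np.ndarray
    affine: np.ndarray
    t_spacing: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValidationError(f"Series4D needs 4D data, got {self.data.ndim}D")
        if self.data.shape[3] < 1:
            raise ValidationError("Series4D needs at least one volume")
        self.affine = _check_affine(self.affine)
        if self.t_spacing is not None:
            self.t_spacing = float(self.t_spacing)
            if self.t_spacing <= 0:
                raise ValidationError(f"TR must be positive, got {self.t_spacing}")

    @property
    def voxel_dims(self) -> np.ndarray:
        return _voxel_dims(self.affine)

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass
class GradientTable:
    """Diffusion b-values (s/mm^2) and unit gradient directions."""

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvecs.ndim != 2 or self.bvecs.shape[1] != 3:
            raise ValidationError(f"bvecs must be (N, 3), got {self.bvecs.shape}")
        if len(self.bvals) != len(self.bvecs):
            raise FormatError(
                f"gradient count mismatch: {len(self.bvals)} b-values vs "
                f"{len(self.bvecs)} b-vectors"
            )
        if np.any(self.bvals < 0):
            raise ValidationError("b-values must be non-negative")
        norms = np.linalg.norm(self.bvecs, axis=1)
        nz = self.bvals > 0
        if np.any(norms[nz] < _BVEC_NORM_TOL):
            bad = int(np.flatnonzero(nz & (norms < _BVEC_NORM_TOL))[0])
            raise ValidationError(
                f"zero gradient vector at volume {bad} with b={self.bvals[bad]:g}"
            )
        if np.any(np.abs(norms[nz] - 1.0) > _BVEC_NORM_TOL):
            # renormalize nominal-unit vectors on construction
            self.bvecs = self.bvecs.copy()
            self.bvecs[nz] = self.bvecs[nz] / norms[nz, None]
        zero = ~nz
        if np.any(norms[zero] > _BVEC_NORM_TOL):
            self.bvecs = self.bvecs.copy()
            self.bvecs[zero] = 0.0

    def __len__(self) -> int:
        return len(self.bvals)


@dataclass
class MaskVolume:
    """A binary 3D lattice with a voxel-to-world transform (mm)."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValidationError(f"MaskVolume needs 3D data, got {arr.ndim}D")
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValidationError(f"mask values must be in {{0,1}}, got {uniq[:5]}")
        self.data = arr.astype(bool)
        self.affine = _check_affine(self.affine)

    @property
    def voxel_dims(self) -> np.ndarray:
        return _voxel_dims(self.affine)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


# ---------------------------------------------------------------------------
# NIfTI + FSL gradient-table I/O
# ---------------------------------------------------------------------------

def _require_file(path: str | os.PathLike) -> str:
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such file: {path}")
    return path


def read_series(image_path, t_spacing: float | None = None) -> Series4D:
    """Read a 4D NIfTI-1 series; TR is supplied by the caller (seconds)."""
    img = nib.load(_require_file(image_path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise FormatError(f"{image_path}: expected a 4D image, got {data.ndim}D")
    return Series4D(data=data, affine=np.asarray(img.affine), t_spacing=t_spacing)


def write_series(series: Series4D, image_path) -> None:
    nib.save(nib.Nifti1Image(series.data.astype(np.float64), series.affine), os.fspath(image_path))


def read_mask(mask_path) -> MaskVolume:
    img = nib.load(_require_file(mask_path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{mask_path}: expected a 3D mask, got {data.ndim}D")
    return MaskVolume(data=data, affine=np.asarray(img.affine))


def write_mask(mask: MaskVolume, mask_path) -> None:
    nib.save(nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine), os.fspath(mask_path))


def read_dwi(image_path, bval_path, bvec_path) -> tuple[Series4D, GradientTable]:
    """Read a diffusion series plus its FSL-dialect gradient table.

    Gradient vectors with b>0 are renormalized to unit length; a zero vector
    paired with b>0 raises :class:`ValidationError`.  Volume and gradient
    counts must match.
    """
    series = read_series(image_path)
    try:
        bvals = np.loadtxt(_require_file(bval_path), dtype=float).ravel()
    except ValueError as exc:
        raise FormatError(f"{bval_path}: cannot parse b-values: {exc}") from exc
    try:
        bvecs = np.loadtxt(_require_file(bvec_path), dtype=float)
    except ValueError as exc:
        raise FormatError(f"{bvec_path}: cannot parse b-vectors: {exc}") from exc
    if bvecs.ndim != 2 or bvecs.shape[0] != 3:
        raise FormatError(
            f"{bvec_path}: FSL bvec must be 3 rows x N columns, got {bvecs.shape}"
        )
    if len(bvals) != series.n_volumes or bvecs.shape[1] != series.n_volumes:
        raise FormatError(
            f"gradient/volume count mismatch: image has {series.n_volumes} volumes, "
            f"{bval_path} has {len(bvals)} b-values, {bvec_path} has "
            f"{bvecs.shape[1]} directions"
        )
    return series, GradientTable(bvals=bvals, bvecs=bvecs.T)


def write_dwi(series: Series4D, grad: GradientTable, image_path, bval_path, bvec_path) -> None:
    """Write a diffusion series and its gradient table in the FSL dialect."""
    write_series(series, image_path)
    np.savetxt(os.fspath(bval_path), grad.bvals[None, :], fmt="%.6g")
    np.savetxt(os.fspath(bvec_path), grad.bvecs.T, fmt="%.17g")


# ---------------------------------------------------------------------------
# Shell selection and volume arithmetic
# ---------------------------------------------------------------------------

def select_shells(
    series: Series4D,
    grad: GradientTable,
    keep_bvals,
    tolerance: float = DEFAULT_SHELL_TOLERANCE,
) -> tuple[Series4D, GradientTable]:
    """Retain only volumes whose b-value is within ``tolerance`` of a kept shell.

    Scanners report nominal-adjacent b-values, hence the absolute tolerance
    window (default 50 s/mm^2).  Order of the retained volumes is preserved.
    A usable diffusion dataset must keep at least one b~0 volume and six
    distinct b>0 directions.
    """
    if tolerance < 0:
        raise ParameterError(f"tolerance must be >= 0, got {tolerance}")
    keep = np.asarray(sorted(set(float(b) for b in keep_bvals)))
    if keep.size == 0:
        raise ParameterError("keep_bvals must be non-empty")
    sel = np.any(np.abs(grad.bvals[:, None] - keep[None, :]) <= tolerance, axis=1)
    bvals = grad.bvals[sel]
    bvecs = grad.bvecs[sel]
    b0 = bvals <= tolerance
    if not np.any(b0):
        raise InsufficientDataError("no b~0 volume remains after shell selection")
    nz_dirs = np.unique(np.round(bvecs[~b0], 6), axis=0)
    if len(nz_dirs) < 6:
        raise InsufficientDataError(
            f"only {len(nz_dirs)} distinct diffusion directions remain; need >= 6"
        )
    out = Series4D(
        data=series.data[..., sel], affine=series.affine, t_spacing=series.t_spacing
    )
    return out, GradientTable(bvals=bvals, bvecs=bvecs)


def mask_volume_ml(mask: MaskVolume) -> float:
    """Mask volume in mL: voxel count x voxel volume (mm^3) / 1000.

    The voxel volume is |det| of the affine's linear part, so sheared or
    anisotropic grids are handled correctly.  An empty mask gives 0.0.
    """
    voxel_mm3 = abs(np.linalg.det(mask.affine[:3, :3]))
    return mask.n_voxels * voxel_mm3 / 1000.0


def normalized_cp_volume(left_ml: float, right_ml: float, brain_ml: float) -> float:
    """Choroid-plexus volume (left+right) as a fraction of total brain volume."""
    if brain_ml <= 0:
        raise ParameterError(f"brain volume must be positive, got {brain_ml}")
    if left_ml < 0 or right_ml < 0:
        raise ParameterError("hemisphere volumes must be non-negative")
    return (left_ml + right_ml) / brain_ml
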