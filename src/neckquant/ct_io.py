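"""CT volume and mask I/O with explicit HU calibration and axis convention.

All grids in this package share one convention: arrays are indexed
``(x, y, z)`` with axis 2 the cranio-caudal axis and *increasing* index =
cranial.  Physical coordinates are millimetres; the voxel at index
``(i, j, k)`` has its centre at ``origin + index * spacing``.  NIfTI files
are reoriented to closest-canonical (RAS+) on load, which places superior
(cranial) along axis 2 as required.

NIfTI-1 is the canonical interchange format; DICOM series are read-only.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import nibabel as nib

from .errors import (
    AlignmentError,
    CalibrationError,
    EmptySlabError,
    FormatError,
    InputError,
)

_TOL = 1e-9  # slack for closed-interval comparisons on physical coordinates


@dataclass(frozen=True)
class CTVolume:
    """A 3-D scalar grid of Hounsfield units with physical geometry.

    Parameters
    ----------
    voxels : ndarray, shape (nx, ny, nz)
        HU values; axis 2 is cranio-caudal, increasing index = cranial.
    spacing : tuple of float
        Per-axis physical voxel size in mm, all > 0.
    origin : tuple of float
        Physical position (mm) of the centre of voxel (0, 0, 0).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        vox = np.asarray(self.voxels)
        if vox.ndim != 3 or min(vox.shape) < 1:
            raise InputError("volume must be a 3-D grid with >= 1 voxel per axis")
        if not np.all(np.isfinite(vox)):
            raise InputError("HU values must be finite")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise InputError("spacing must have 3 positive components")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def axis_centers(self, axis: int) -> np.ndarray:
        """Physical centre coordinates (mm) of all voxels along one axis."""
        n = self.voxels.shape[axis]
        return self.origin[axis] + np.arange(n) * self.spacing[axis]

    @property
    def z_centers(self) -> np.ndarray:
        return self.axis_centers(2)

    @property
    def x_centers(self) -> np.ndarray:
        return self.axis_centers(0)

    def index_of(self, point_mm) -> tuple[int, int, int]:
        """Nearest voxel index to a physical point; raises if outside grid."""
        idx = []
        for ax in range(3):
            i = int(round((point_mm[ax] - self.origin[ax]) / self.spacing[ax]))
            if not 0 <= i < self.voxels.shape[ax]:
                raise InputError(f"point {tuple(point_mm)} lies outside the grid on axis {ax}")
            idx.append(i)
        return tuple(idx)


@dataclass(frozen=True)
class BinaryMask:
    """A boolean tissue mask on the same grid as its source CT volume."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        vox = np.asarray(self.voxels)
        if vox.dtype != bool:
            vox = vox.astype(bool)
        if vox.ndim != 3:
            raise InputError("mask must be 3-D")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self):
        return self.voxels.shape

    def check_aligned(self, other) -> None:
        if self.voxels.shape != other.voxels.shape or not np.allclose(
            self.spacing, other.spacing
        ):
            raise AlignmentError(
                f"grids misaligned: {self.voxels.shape}@{self.spacing} vs "
                f"{other.voxels.shape}@{other.spacing}"
            )


@dataclass(frozen=True)
class AxialSlab:
    """The set of axial slices whose centres fall inside a physical slab.

    The slab is the closed interval
    ``[center_z - thickness/2, center_z + thickness/2]``.
    """

    center_z: float
    thickness: float
    slice_indices: np.ndarray = field(repr=False)

    def __post_init__(self):
        if self.thickness <= 0:
            raise InputError("slab thickness must be > 0")
        if len(self.slice_indices) == 0:
            raise EmptySlabError(
                f"slab at z={self.center_z} mm (thickness {self.thickness} mm) "
                "contains no slice centres"
            )


def _affine(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    aff[:3, 3] = origin
    return aff


def load_volume(path, format: str | None = None) -> CTVolume:
    """Load a CT volume in HU from a NIfTI file or a DICOM series directory.

    ``format`` is ``"nifti"`` or ``"dicom_series"``; when omitted it is
    inferred (directory -> DICOM series, file -> NIfTI).  DICOM stored values
    are converted to HU via the mandatory RescaleSlope/RescaleIntercept tags;
    NIfTI data are assumed already calibrated (nibabel applies any scl slope
    exactly once, so reloading a saved volume applies no second rescale).
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise InputError(f"no such path: {path}")
    if format is None:
        format = "dicom_series" if os.path.isdir(path) else "nifti"
    if format == "nifti":
        return _load_nifti(path)
    if format == "dicom_series":
        return _load_dicom_series(path)
    raise InputError(f"unknown format {format!r}")


def _load_nifti(path) -> CTVolume:
    try:
        img = nib.load(path)
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"cannot read NIfTI {path}: {exc}") from exc
    img = nib.as_closest_canonical(img)  # RAS+: axis 2 = superior = cranial
    data = np.asarray(img.get_fdata())
    if data.ndim != 3:
        raise FormatError(f"expected a 3-D NIfTI, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(t) for t in img.affine[:3, 3])
    if not np.all(np.isfinite(data)):
        raise FormatError(f"non-finite voxel values in {path}")
    return CTVolume(voxels=data, spacing=spacing, origin=origin)


def _load_dicom_series(path) -> CTVolume:
    import pydicom

    files = sorted(
        os.path.join(path, f)
        for f in os.listdir(path)
        if not f.startswith(".")
    )
    if not files:
        raise InputError(f"empty DICOM directory: {path}")
    try:
        datasets = [pydicom.dcmread(f) for f in files]
    except Exception as exc:
        raise FormatError(f"cannot read DICOM series in {path}: {exc}") from exc

    uids = {getattr(ds, "SeriesInstanceUID", None) for ds in datasets}
    if len(uids) != 1:
        raise FormatError(f"directory {path} mixes {len(uids)} DICOM series")

    for ds in datasets:
        if "RescaleSlope" not in ds or "RescaleIntercept" not in ds:
            raise CalibrationError(
                "DICOM slice lacks RescaleSlope/RescaleIntercept; cannot calibrate HU"
            )
    datasets.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))

    slices = []
    for ds in datasets:
        # pixel_array is (row=y, col=x); transpose to our (x, y) order
        hu = float(ds.RescaleSlope) * ds.pixel_array.T.astype(np.float64) + float(
            ds.RescaleIntercept
        )
        slices.append(hu)
    data = np.stack(slices, axis=2)

    first = datasets[0]
    row_sp, col_sp = (float(v) for v in first.PixelSpacing)  # (y, x)
    if len(datasets) > 1:
        zs = [float(ds.ImagePositionPatient[2]) for ds in datasets]
        dz = float(np.mean(np.diff(zs)))
    else:
        dz = float(getattr(first, "SliceThickness", 1.0))
    origin = (
        float(first.ImagePositionPatient[0]),
        float(first.ImagePositionPatient[1]),
        float(first.ImagePositionPatient[2]),
    )
    return CTVolume(voxels=data, spacing=(col_sp, row_sp, dz), origin=origin)


def save_volume(volume: CTVolume, path) -> None:
    """Write a CTVolume as NIfTI-1; save->load is voxel-wise identity."""
    img = nib.Nifti1Image(
        np.asarray(volume.voxels, dtype=np.float64),
        _affine(volume.spacing, volume.origin),
    )
    img.header.set_zooms(volume.spacing)
    try:
        nib.save(img, os.fspath(path))
    except OSError as exc:
        raise InputError(f"cannot write {path}: {exc}") from exc


def save_mask(mask: BinaryMask, path) -> None:
    """Write a BinaryMask as a 0/1 uint8 NIfTI with its spacing preserved."""
    img = nib.Nifti1Image(
        mask.voxels.astype(np.uint8), _affine(mask.spacing, mask.origin)
    )
    img.header.set_zooms(mask.spacing)
    try:
        nib.save(img, os.fspath(path))
    except OSError as exc:
        raise InputError(f"cannot write {path}: {exc}") from exc


def load_mask(path) -> BinaryMask:
    vol = _load_nifti(os.fspath(path))
    return BinaryMask(voxels=vol.voxels > 0.5, spacing=vol.spacing, origin=vol.origin)


def slab_at(volume: CTVolume, center_z: float, thickness: float = 5.0) -> AxialSlab:
    """Slices whose centres lie in the closed slab interval around ``center_z``.

    Mirrors measuring on a "single thick slice": a 5 mm slab at 1 mm z-spacing
    centred on a slice centre selects 5 slices.
    """
    if thickness <= 0:
        raise InputError("slab thickness must be > 0")
    zc = volume.z_centers
    half = thickness / 2.0
    inside = (zc >= center_z - half - _TOL) & (zc <= center_z + half + _TOL)
    return AxialSlab(
        center_z=float(center_z),
        thickness=float(thickness),
        slice_indices=np.flatnonzero(inside),
    )
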