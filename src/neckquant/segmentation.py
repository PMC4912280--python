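"""Tissue segmentation: HU-window fat, seeded airway lumen, body contour.

Adipose tissue is defined as the closed HU interval [-150, -30] (centre
-90 HU), restricted to the anatomic crop box running from the roof of the
orbits cranially to the sternal angle caudally and between the
mid-clavicular lines laterally.  The airway lumen is the 26-connected
air-density component containing a seed point, clipped between the hard
palate and the first tracheal ring (inclusive).  The per-slice body contour
is the largest 8-connected soft-tissue component after hole filling, which
counts the airway lumen toward the neck area and drops small disconnected
satellites (the automated analogue of manually excluding ear cartilage).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field

import numpy as np
from scipy import ndimage

from .ct_io import BinaryMask, CTVolume, _TOL
from .errors import (
    AlignmentError,
    EmptyBodyError,
    InputError,
    LandmarkError,
    SchemaError,
    SeedError,
)

#: default HU threshold below which a voxel counts as airway lumen; the lumen
#: (~ -1000 HU) and all soft tissues (> -150 HU) are both far from it.
AIR_THRESHOLD_HU = -500.0

#: default HU threshold above which a voxel counts as (non-fat) soft tissue
#: when tracing the body contour; skin and muscle (~ +40 HU) sit well above,
#: fat (~ -90 HU) well below.
TISSUE_THRESHOLD_HU = -20.0

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)  # 3-D 26-connectivity
_STRUCT_8 = np.ones((3, 3), dtype=bool)  # 2-D 8-connectivity

COMPARTMENT_NAMES = {1: "subcutaneous", 2: "posterior", 3: "perivertebral"}
COMPARTMENT_IDS = {v: k for k, v in COMPARTMENT_NAMES.items()}


@dataclass(frozen=True)
class HUWindow:
    """Closed HU interval selecting adipose-density voxels."""

    low: float = -150.0
    high: float = -30.0

    def __post_init__(self):
        if not self.low < self.high:
            raise InputError(f"HU window requires low < high, got [{self.low}, {self.high}]")

    @property
    def center(self) -> float:
        return (self.low + self.high) / 2.0

    def contains(self, hu: np.ndarray) -> np.ndarray:
        return (hu >= self.low) & (hu <= self.high)


_LANDMARK_KEYS = (
    "z_orbit_roof",
    "z_sternal_angle",
    "x_left_midclavicle",
    "x_right_midclavicle",
    "z_hard_palate",
    "z_first_tracheal_ring",
    "z_soft_palate_tip",
    "z_thyroid_cartilage",
    "airway_seed",
)


@dataclass(frozen=True)
class LandmarkSet:
    """Physical (mm) axial levels of the anatomic margins plus an airway seed.

    Cranial = larger z.  ``z_orbit_roof``/``z_sternal_angle`` bound the fat
    crop cranio-caudally and the two mid-clavicular x values bound it
    laterally; ``z_hard_palate``/``z_first_tracheal_ring`` bound the airway;
    the two NCSA levels name where cross-sectional area is read.
    """

    z_orbit_roof: float
    z_sternal_angle: float
    x_left_midclavicle: float
    x_right_midclavicle: float
    z_hard_palate: float
    z_first_tracheal_ring: float
    z_soft_palate_tip: float
    z_thyroid_cartilage: float
    airway_seed: tuple[float, float, float]

    def __post_init__(self):
        if not self.z_orbit_roof > self.z_sternal_angle:
            raise LandmarkError("orbit roof must be cranial to (z >) the sternal angle")
        if not self.z_hard_palate > self.z_first_tracheal_ring:
            raise LandmarkError("hard palate must be cranial to the first tracheal ring")
        for name in ("z_soft_palate_tip", "z_thyroid_cartilage"):
            z = getattr(self, name)
            if not (self.z_sternal_angle <= z <= self.z_orbit_roof):
                raise LandmarkError(f"{name}={z} outside the crop z-interval")
        if self.x_left_midclavicle == self.x_right_midclavicle:
            raise LandmarkError("lateral bounds coincide")
        object.__setattr__(self, "airway_seed", tuple(float(v) for v in self.airway_seed))

    @property
    def x_bounds(self) -> tuple[float, float]:
        lo, hi = sorted((self.x_left_midclavicle, self.x_right_midclavicle))
        return lo, hi

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "LandmarkSet":
        missing = [k for k in _LANDMARK_KEYS if k not in d]
        if missing:
            raise SchemaError(missing, f"landmark JSON missing keys: {', '.join(missing)}")
        return cls(**{k: d[k] for k in _LANDMARK_KEYS})

    @classmethod
    def from_json(cls, path) -> "LandmarkSet":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


@dataclass(frozen=True)
class CompartmentLabels:
    """Voxel labels assigning fat to anatomic compartments.

    0 = none, 1 = subcutaneous, 2 = posterior, 3 = perivertebral.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise InputError("labels must be 3-D")
        object.__setattr__(self, "voxels", vox.astype(np.uint8))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))


def _crop_box(volume: CTVolume, landmarks: LandmarkSet) -> np.ndarray:
    """Boolean grid of voxels whose centres lie inside the anatomic crop."""
    zc = volume.z_centers
    xc = volume.x_centers
    z_ok = (zc >= landmarks.z_sternal_angle - _TOL) & (zc <= landmarks.z_orbit_roof + _TOL)
    xlo, xhi = landmarks.x_bounds
    x_ok = (xc >= xlo - _TOL) & (xc <= xhi + _TOL)
    return x_ok[:, None, None] & z_ok[None, None, :]


def fat_mask(
    volume: CTVolume,
    window: HUWindow | None = None,
    landmarks: LandmarkSet | None = None,
) -> BinaryMask:
    """Adipose voxels: HU inside the closed window AND centre inside the crop.

    Both window boundaries are inclusive, so a voxel at exactly -150 HU is
    fat and one at -151 HU is not.  With no landmarks the whole grid is kept.
    """
    window = window or HUWindow()
    inside = window.contains(volume.voxels)
    if landmarks is not None:
        box = _crop_box(volume, landmarks)
        if not box.any():
            raise LandmarkError("crop box contains no voxel centres")
        inside &= box
    return BinaryMask(voxels=inside, spacing=volume.spacing, origin=volume.origin)


def airway_mask(
    volume: CTVolume,
    landmarks: LandmarkSet,
    air_threshold: float = AIR_THRESHOLD_HU,
) -> BinaryMask:
    """Airway lumen: the seeded 26-connected air component, z-clipped.

    The clip keeps every slice whose centre lies in the closed interval
    [z_first_tracheal_ring, z_hard_palate], i.e. down to and including the
    first tracheal ring.  Ambient air not connected to the seed is excluded;
    the oropharynx and more-cranial airway are excluded purely by the clip.
    """
    seed_idx = volume.index_of(landmarks.airway_seed)
    air = volume.voxels <= air_threshold
    if not air[seed_idx]:
        raise SeedError(
            f"airway seed at {landmarks.airway_seed} has HU "
            f"{volume.voxels[seed_idx]:.0f} > threshold {air_threshold}"
        )
    labels, _ = ndimage.label(air, structure=_STRUCT_26)
    comp = labels == labels[seed_idx]

    zc = volume.z_centers
    keep = (zc >= landmarks.z_first_tracheal_ring - _TOL) & (
        zc <= landmarks.z_hard_palate + _TOL
    )
    comp &= keep[None, None, :]
    if not comp.any():
        raise LandmarkError("airway component is empty after the landmark z-clip")
    return BinaryMask(voxels=comp, spacing=volume.spacing, origin=volume.origin)


def body_mask_slice(
    volume: CTVolume,
    slice_index: int,
    tissue_threshold: float = TISSUE_THRESHOLD_HU,
) -> np.ndarray:
    """Filled body contour on one axial slice as a 2-D boolean grid.

    Thresholds at ``tissue_threshold``, fills interior holes (so the airway
    lumen and any fat enclosed by skin count toward neck area), then keeps
    the largest 8-connected component; smaller disconnected components such
    as ear-like satellites are discarded.
    """
    nz = volume.voxels.shape[2]
    if not 0 <= slice_index < nz:
        raise InputError(f"slice {slice_index} outside grid of {nz} slices")
    sl = volume.voxels[:, :, slice_index]
    binary = sl >= tissue_threshold
    if not binary.any():
        raise EmptyBodyError(f"no voxel >= {tissue_threshold} HU on slice {slice_index}")
    filled = ndimage.binary_fill_holes(binary)
    labels, nlab = ndimage.label(filled, structure=_STRUCT_8)
    if nlab == 1:
        return filled
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == int(np.argmax(counts))


def compartment_volumes(fat: BinaryMask, labels: CompartmentLabels) -> dict[str, float]:
    """Fat volume (cc) inside each labelled compartment.

    Only voxels that are both fat and labelled contribute, so the labelled
    volumes can never sum to more than the total fat volume.
    """
    if fat.voxels.shape != labels.voxels.shape or not np.allclose(
        fat.spacing, labels.spacing
    ):
        raise AlignmentError("fat mask and compartment labels are not aligned")
    voxel_cc = float(np.prod(fat.spacing)) / 1000.0
    out = {}
    for lab, name in COMPARTMENT_NAMES.items():
        out[name] = float(np.count_nonzero(fat.voxels & (labels.voxels == lab))) * voxel_cc
    return out
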