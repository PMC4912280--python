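"""Anthropometric quantities from masks: NATV, AWV, NAT:AWV, NCSA.

Volumes are reported in cc (1 cc = 1000 mm^3).  The neck cross-sectional
area (NCSA) on a thick slab is the *mean* per-slice filled body-contour
area, an areal quantity in mm^2, read by default on a 5 mm slab.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .ct_io import BinaryMask, CTVolume, slab_at
from .errors import EmptyBodyError, InputError, StageError
from .segmentation import (
    HUWindow,
    LandmarkSet,
    airway_mask,
    body_mask_slice,
    fat_mask,
)


@dataclass(frozen=True)
class VolumetricResult:
    """Per-scan measurement record."""

    patient_id: str
    natv_cc: float
    awv_cc: float
    ratio: float
    ncsa_upper_mm2: float
    ncsa_lower_mm2: float

    def __post_init__(self):
        for name in ("natv_cc", "awv_cc", "ratio", "ncsa_upper_mm2", "ncsa_lower_mm2"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    def to_row(self) -> dict:
        """Output-formatted row: volumes to 3 dp, areas 1 dp, ratio 1 dp."""
        return {
            "patient_id": self.patient_id,
            "natv_cc": round(self.natv_cc, 3),
            "awv_cc": round(self.awv_cc, 3),
            "ratio": round(self.ratio, 1),
            "ncsa_upper_mm2": round(self.ncsa_upper_mm2, 1),
            "ncsa_lower_mm2": round(self.ncsa_lower_mm2, 1),
        }


RESULT_COLUMNS = (
    "patient_id",
    "natv_cc",
    "awv_cc",
    "ratio",
    "ncsa_upper_mm2",
    "ncsa_lower_mm2",
)


def mask_volume_cc(mask: BinaryMask) -> float:
    """Volume of a mask in cc: true-voxel count times voxel volume."""
    return float(np.count_nonzero(mask.voxels)) * float(np.prod(mask.spacing)) / 1000.0


def natv_awv_ratio(natv_cc: float, awv_cc: float) -> float:
    if awv_cc <= 0:
        raise InputError("NAT:AWV undefined for airway volume <= 0 cc")
    return natv_cc / awv_cc


def ncsa(
    volume: CTVolume,
    level_z: float,
    tissue_threshold: float | None = None,
    slab_thickness: float = 5.0,
) -> float:
    """Neck cross-sectional area (mm^2) on a slab at an anatomic level.

    Mean over the slab's slices of (body-contour pixel count x in-plane pixel
    area).  Slices with no body above threshold are skipped; if every slice
    in the slab is empty the whole measurement fails.
    """
    from .segmentation import TISSUE_THRESHOLD_HU

    thr = TISSUE_THRESHOLD_HU if tissue_threshold is None else tissue_threshold
    slab = slab_at(volume, level_z, slab_thickness)
    pixel_mm2 = volume.spacing[0] * volume.spacing[1]
    areas = []
    for k in slab.slice_indices:
        try:
            body = body_mask_slice(volume, int(k), thr)
        except EmptyBodyError:
            continue
        areas.append(float(np.count_nonzero(body)) * pixel_mm2)
    if not areas:
        raise EmptyBodyError(f"no body contour on any slice of the slab at z={level_z} mm")
    return float(np.mean(areas))


def quantify_scan(
    volume: CTVolume,
    landmarks: LandmarkSet,
    config=None,
    patient_id: str = "scan",
) -> VolumetricResult:
    """Run the full per-scan measurement: fat, airway, ratio, both NCSAs.

    Deterministic; any stage failure raises :class:`StageError` naming the
    stage, and no partial result is returned.
    """
    from .config import RunConfig

    cfg = config or RunConfig()

    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise StageError(name, exc) from exc

    window = HUWindow(low=cfg.hu_low, high=cfg.hu_high)
    fat = _stage("fat", lambda: fat_mask(volume, window, landmarks))
    natv = mask_volume_cc(fat)
    aw = _stage("airway", lambda: airway_mask(volume, landmarks, cfg.air_threshold))
    awv = mask_volume_cc(aw)
    ratio = _stage("ratio", lambda: natv_awv_ratio(natv, awv))
    upper = _stage(
        "ncsa_upper",
        lambda: ncsa(volume, landmarks.z_soft_palate_tip, cfg.tissue_threshold,
                     cfg.slab_thickness_mm),
    )
    lower = _stage(
        "ncsa_lower",
        lambda: ncsa(volume, landmarks.z_thyroid_cartilage, cfg.tissue_threshold,
                     cfg.slab_thickness_mm),
    )
    return VolumetricResult(
        patient_id=patient_id,
        natv_cc=natv,
        awv_cc=awv,
        ratio=ratio,
        ncsa_upper_mm2=upper,
        ncsa_lower_mm2=lower,
    )
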