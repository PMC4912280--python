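"""Synthetic neck-like CT phantoms with analytically known geometry.

A phantom is a stack of simple solids painted into a -1000 HU (air)
background, innermost structure last: an elliptic-cylinder *body* of soft
tissue (+40 HU), parametric *fat* compartments (-90 HU) — a subcutaneous
shell plus posterior and perivertebral ellipsoids — an optional *bone*
cylinder (+700 HU), and a straight *airway* tube (-1000 HU) along the
cranio-caudal axis.  Voxel membership is by voxel-centre inclusion (no
partial-volume weighting), so the closed-form volumes (ellipsoid 4/3*pi*abc,
cylinder pi*a*b*h) are exact oracles up to a quantifiable surface term.
Gaussian noise, when requested, is added to the HU grid only; ground-truth
masks are geometric and therefore noise-free.  1 cc = 1000 mm^3 throughout.

The default cohort specs target the median fat volumes observed per WHO BMI
class in clinical neck CT (~444 / 689 / 864 cc for lean / overweight /
obese) and an airway of ~24 cc, with the cross-section of the body cylinder
near the reported mean upper-neck cross-sectional area (~2.2e4 mm^2).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .ct_io import BinaryMask, CTVolume
from .errors import InputError, SpecError
from .segmentation import COMPARTMENT_IDS, CompartmentLabels, LandmarkSet

HU_AIR = -1000.0
HU_FAT = -90.0
HU_SOFT_TISSUE = 40.0
HU_BONE = 700.0
HU_MIN, HU_MAX = -1024.0, 3071.0

#: median neck adipose tissue volume (cc) anchors per WHO BMI class
CLASS_FAT_CC = {"lean": 444.0, "overweight": 689.0, "obese": 864.0}


# ---------------------------------------------------------------------------
# geometric primitives
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Ellipsoid:
    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    hu: float = HU_FAT
    compartment: str | None = None

    def analytic_volume_mm3(self) -> float:
        a, b, c = self.semi_axes
        return 4.0 / 3.0 * math.pi * a * b * c

    def contains(self, X, Y, Z):
        cx, cy, cz = self.center
        a, b, c = self.semi_axes
        return ((X - cx) / a) ** 2 + ((Y - cy) / b) ** 2 + ((Z - cz) / c) ** 2 <= 1.0

    def bbox(self):
        c, s = np.asarray(self.center), np.asarray(self.semi_axes)
        return c - s, c + s


@dataclass(frozen=True)
class EllipticCylinder:
    """Solid elliptic cylinder along z, spanning the closed [z0, z1] range."""

    center_xy: tuple[float, float]
    semi_axes_xy: tuple[float, float]
    z_range: tuple[float, float]
    hu: float = HU_SOFT_TISSUE
    compartment: str | None = None

    def analytic_volume_mm3(self) -> float:
        a, b = self.semi_axes_xy
        return math.pi * a * b * (self.z_range[1] - self.z_range[0])

    def cross_section_mm2(self) -> float:
        a, b = self.semi_axes_xy
        return math.pi * a * b

    def contains(self, X, Y, Z):
        cx, cy = self.center_xy
        a, b = self.semi_axes_xy
        in_xy = ((X - cx) / a) ** 2 + ((Y - cy) / b) ** 2 <= 1.0
        return in_xy & (Z >= self.z_range[0]) & (Z <= self.z_range[1])

    def bbox(self):
        cx, cy = self.center_xy
        a, b = self.semi_axes_xy
        return (
            np.array([cx - a, cy - b, self.z_range[0]]),
            np.array([cx + a, cy + b, self.z_range[1]]),
        )


@dataclass(frozen=True)
class CylinderShell:
    """Annular shell between two concentric elliptic cylinders along z."""

    center_xy: tuple[float, float]
    outer_semi_axes: tuple[float, float]
    inner_semi_axes: tuple[float, float]
    z_range: tuple[float, float]
    hu: float = HU_FAT
    compartment: str | None = None

    def __post_init__(self):
        if not (
            self.inner_semi_axes[0] < self.outer_semi_axes[0]
            and self.inner_semi_axes[1] < self.outer_semi_axes[1]
        ):
            raise SpecError("shell inner semi-axes must be strictly inside the outer")

    def analytic_volume_mm3(self) -> float:
        ao, bo = self.outer_semi_axes
        ai, bi = self.inner_semi_axes
        return math.pi * (ao * bo - ai * bi) * (self.z_range[1] - self.z_range[0])

    def contains(self, X, Y, Z):
        cx, cy = self.center_xy
        ao, bo = self.outer_semi_axes
        ai, bi = self.inner_semi_axes
        dx, dy = X - cx, Y - cy
        in_outer = (dx / ao) ** 2 + (dy / bo) ** 2 <= 1.0
        in_inner = (dx / ai) ** 2 + (dy / bi) ** 2 <= 1.0
        return in_outer & ~in_inner & (Z >= self.z_range[0]) & (Z <= self.z_range[1])

    def bbox(self):
        cx, cy = self.center_xy
        ao, bo = self.outer_semi_axes
        return (
            np.array([cx - ao, cy - bo, self.z_range[0]]),
            np.array([cx + ao, cy + bo, self.z_range[1]]),
        )


@dataclass(frozen=True)
class Tube:
    """Straight circular tube along z (the airway lumen)."""

    center_xy: tuple[float, float]
    radius: float
    z_range: tuple[float, float]
    hu: float = HU_AIR

    def analytic_volume_mm3(self) -> float:
        return math.pi * self.radius**2 * (self.z_range[1] - self.z_range[0])

    def contains(self, X, Y, Z):
        cx, cy = self.center_xy
        in_xy = (X - cx) ** 2 + (Y - cy) ** 2 <= self.radius**2
        return in_xy & (Z >= self.z_range[0]) & (Z <= self.z_range[1])

    def bbox(self):
        cx, cy = self.center_xy
        r = self.radius
        return (
            np.array([cx - r, cy - r, self.z_range[0]]),
            np.array([cx + r, cy + r, self.z_range[1]]),
        )


_STRUCT_TYPES = {
    "ellipsoid": Ellipsoid,
    "elliptic_cylinder": EllipticCylinder,
    "cylinder_shell": CylinderShell,
    "tube": Tube,
}


def _struct_to_dict(s) -> dict:
    for name, cls in _STRUCT_TYPES.items():
        if isinstance(s, cls):
            d = {"type": name}
            d.update({k: v for k, v in s.__dict__.items()})
            return d
    raise SpecError(f"unknown structure type {type(s)!r}")


def _struct_from_dict(d: dict):
    d = dict(d)
    typ = d.pop("type", None)
    if typ not in _STRUCT_TYPES:
        raise SpecError(f"unknown structure type {typ!r}")
    d = {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}
    return _STRUCT_TYPES[typ](**d)


# ---------------------------------------------------------------------------
# specification and ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomSpec:
    grid_shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    body: EllipticCylinder
    fat_structures: tuple = ()
    airway: Tube | None = None
    bone: EllipticCylinder | None = None
    noise_sd: float = 0.0
    seed: int = 0
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    landmarks: LandmarkSet | None = None

    def __post_init__(self):
        if self.noise_sd < 0:
            raise SpecError("noise_sd must be >= 0")
        for s in self.fat_structures:
            if not (-150.0 <= s.hu <= -30.0):
                raise SpecError(f"fat structure HU {s.hu} outside [-150, -30]")
        if self.airway is not None and not self.airway.hu < -500.0:
            raise SpecError(f"airway HU {self.airway.hu} must be < -500")
        object.__setattr__(self, "fat_structures", tuple(self.fat_structures))

    def to_dict(self) -> dict:
        d = {
            "grid_shape": list(self.grid_shape),
            "spacing": list(self.spacing),
            "origin": list(self.origin),
            "body": _struct_to_dict(self.body),
            "fat_structures": [_struct_to_dict(s) for s in self.fat_structures],
            "airway": _struct_to_dict(self.airway) if self.airway else None,
            "bone": _struct_to_dict(self.bone) if self.bone else None,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
            "landmarks": self.landmarks.to_dict() if self.landmarks else None,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        try:
            return cls(
                grid_shape=tuple(d["grid_shape"]),
                spacing=tuple(d["spacing"]),
                origin=tuple(d.get("origin", (0.0, 0.0, 0.0))),
                body=_struct_from_dict(d["body"]),
                fat_structures=tuple(
                    _struct_from_dict(s) for s in d.get("fat_structures", ())
                ),
                airway=_struct_from_dict(d["airway"]) if d.get("airway") else None,
                bone=_struct_from_dict(d["bone"]) if d.get("bone") else None,
                noise_sd=float(d.get("noise_sd", 0.0)),
                seed=int(d.get("seed", 0)),
                landmarks=(
                    LandmarkSet.from_dict(d["landmarks"]) if d.get("landmarks") else None
                ),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise SpecError(f"invalid phantom spec: {exc}") from exc

    @classmethod
    def from_json(cls, path) -> "PhantomSpec":
        with open(path) as fh:
            try:
                payload = json.load(fh)
            except json.JSONDecodeError as exc:
                raise SpecError(f"malformed phantom spec JSON: {exc}") from exc
        return cls.from_dict(payload)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


@dataclass(frozen=True)
class PhantomGroundTruth:
    """Analytic oracle values plus the geometric (noise-free) masks."""

    fat_volume_cc: float
    airway_volume_cc: float
    fat_mask: BinaryMask
    airway_mask: BinaryMask
    body_mask: BinaryMask
    compartment_labels: CompartmentLabels
    landmark_set: LandmarkSet
    compartment_volumes_cc: dict
    body_cross_section_mm2: float = 0.0
    body_z_range: tuple[float, float] = (0.0, 0.0)

    def ncsa_mm2_at(self, z: float) -> float:
        """Analytic filled body cross-section (mm^2) at axial level z."""
        z0, z1 = self.body_z_range
        return self.body_cross_section_mm2 if z0 <= z <= z1 else 0.0

    def manifest(self) -> dict:
        return {
            "fat_volume_cc": self.fat_volume_cc,
            "airway_volume_cc": self.airway_volume_cc,
            "compartment_volumes_cc": self.compartment_volumes_cc,
            "body_cross_section_mm2": self.body_cross_section_mm2,
            "body_z_range": list(self.body_z_range),
            "ncsa_upper_mm2": self.ncsa_mm2_at(self.landmark_set.z_soft_palate_tip),
            "ncsa_lower_mm2": self.ncsa_mm2_at(self.landmark_set.z_thyroid_cartilage),
            "landmarks": self.landmark_set.to_dict(),
        }


def _grid_coords(spec: PhantomSpec):
    ox, oy, oz = spec.origin
    sx, sy, sz = spec.spacing
    nx, ny, nz = spec.grid_shape
    X = (ox + np.arange(nx) * sx)[:, None, None]
    Y = (oy + np.arange(ny) * sy)[None, :, None]
    Z = (oz + np.arange(nz) * sz)[None, None, :]
    return X, Y, Z


def _check_inside_grid(spec: PhantomSpec, struct, name: str) -> None:
    lo, hi = struct.bbox()
    g_lo = np.asarray(spec.origin) - np.asarray(spec.spacing) / 2.0
    g_hi = g_lo + np.asarray(spec.grid_shape) * np.asarray(spec.spacing)
    if np.any(lo < g_lo - 1e-9) or np.any(hi > g_hi + 1e-9):
        raise SpecError(f"structure '{name}' extends outside the grid extent")


def _default_landmarks(spec: PhantomSpec) -> LandmarkSet:
    body = spec.body
    z0, z1 = body.z_range
    span = z1 - z0
    if spec.airway is not None:
        aw_lo, aw_hi = spec.airway.z_range
        cx, cy = spec.airway.center_xy
        seed = (cx, cy, (aw_lo + aw_hi) / 2.0)
    else:
        aw_lo, aw_hi = z0 + 0.2 * span, z0 + 0.8 * span
        seed = (body.center_xy[0], body.center_xy[1], (aw_lo + aw_hi) / 2.0)
    a = body.semi_axes_xy[0]
    return LandmarkSet(
        z_orbit_roof=z1,
        z_sternal_angle=z0,
        x_left_midclavicle=body.center_xy[0] - a - spec.spacing[0],
        x_right_midclavicle=body.center_xy[0] + a + spec.spacing[0],
        z_hard_palate=aw_hi,
        z_first_tracheal_ring=aw_lo,
        z_soft_palate_tip=z0 + 0.7 * span,
        z_thyroid_cartilage=z0 + 0.3 * span,
        airway_seed=seed,
    )


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, PhantomGroundTruth]:
    """Voxelize a phantom spec into an HU volume plus its analytic oracle.

    Deterministic for a fixed spec (the seed drives only the noise draw, and
    with ``noise_sd == 0`` no random numbers are consumed at all).
    """
    _check_inside_grid(spec, spec.body, "body")
    for i, s in enumerate(spec.fat_structures):
        _check_inside_grid(spec, s, f"fat[{i}]")
    if spec.airway is not None:
        _check_inside_grid(spec, spec.airway, "airway")
    if spec.bone is not None:
        _check_inside_grid(spec, spec.bone, "bone")

    X, Y, Z = _grid_coords(spec)
    hu = np.full(spec.grid_shape, HU_AIR, dtype=np.float64)

    body_vox = spec.body.contains(X, Y, Z)
    hu[body_vox] = spec.body.hu

    if spec.bone is not None:
        hu[spec.bone.contains(X, Y, Z)] = spec.bone.hu

    fat_vox = np.zeros(spec.grid_shape, dtype=bool)
    labels = np.zeros(spec.grid_shape, dtype=np.uint8)
    comp_cc: dict[str, float] = {}
    voxel_cc = float(np.prod(spec.spacing)) / 1000.0
    for s in spec.fat_structures:
        m = s.contains(X, Y, Z)
        if np.any(m & fat_vox):
            raise SpecError("fat structures overlap; analytic volumes would double-count")
        fat_vox |= m
        hu[m] = s.hu
        if s.compartment:
            if s.compartment not in COMPARTMENT_IDS:
                raise SpecError(f"unknown compartment {s.compartment!r}")
            labels[m] = COMPARTMENT_IDS[s.compartment]
            comp_cc[s.compartment] = (
                comp_cc.get(s.compartment, 0.0) + s.analytic_volume_mm3() / 1000.0
            )

    airway_vox = np.zeros(spec.grid_shape, dtype=bool)
    airway_cc = 0.0
    if spec.airway is not None:
        airway_vox = spec.airway.contains(X, Y, Z)
        if np.any(airway_vox & fat_vox):
            raise SpecError("airway overlaps a fat structure")
        hu[airway_vox] = spec.airway.hu
        airway_cc = spec.airway.analytic_volume_mm3() / 1000.0

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        hu += rng.normal(0.0, spec.noise_sd, size=hu.shape)
        np.clip(hu, HU_MIN, HU_MAX, out=hu)

    volume = CTVolume(voxels=hu, spacing=spec.spacing, origin=spec.origin)
    mk = lambda v: BinaryMask(voxels=v, spacing=spec.spacing, origin=spec.origin)
    gt = PhantomGroundTruth(
        fat_volume_cc=sum(s.analytic_volume_mm3() for s in spec.fat_structures) / 1000.0,
        airway_volume_cc=airway_cc,
        fat_mask=mk(fat_vox),
        airway_mask=mk(airway_vox),
        body_mask=mk(body_vox),
        compartment_labels=CompartmentLabels(
            voxels=labels, spacing=spec.spacing, origin=spec.origin
        ),
        landmark_set=spec.landmarks or _default_landmarks(spec),
        compartment_volumes_cc=comp_cc,
        body_cross_section_mm2=spec.body.cross_section_mm2(),
        body_z_range=spec.body.z_range,
    )
    return volume, gt


# ---------------------------------------------------------------------------
# default cohort-like phantoms
# ---------------------------------------------------------------------------

def default_cohort_spec(
    size_class: str,
    seed: int = 0,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    noise_sd: float = 15.0,
) -> PhantomSpec:
    """A neck phantom whose analytic fat volume matches a WHO BMI class.

    The total fat volume is drawn within +/-5% of the class anchor
    (444 / 689 / 864 cc) and split 65% / 20% / 15% across the subcutaneous
    shell and the posterior and perivertebral ellipsoids, whose z-extents
    (and the shell's inner semi-axes) are solved in closed form so the
    analytic total is exact.  Reproducible for a fixed (class, seed).
    """
    if size_class not in CLASS_FAT_CC:
        raise InputError(
            f"unknown size class {size_class!r}; expected one of {sorted(CLASS_FAT_CC)}"
        )
    class_id = sorted(CLASS_FAT_CC).index(size_class)
    rng = np.random.default_rng([seed, class_id])
    target_cc = CLASS_FAT_CC[size_class] * float(rng.uniform(0.95, 1.05))
    target_mm3 = target_cc * 1000.0
    # mild per-subject anatomy: neck girth and airway calibre vary
    body_scale = float(rng.uniform(0.97, 1.05))
    airway_radius = float(rng.uniform(7.0, 9.0))

    # physical frame: x in [-99.5, 99.5], y in [-89.5, 89.5], z in [0, 219] mm
    sx, sy, sz = spacing
    nx = int(round(200.0 / sx))
    ny = int(round(180.0 / sy))
    nz = int(round(220.0 / sz))
    origin = (-(nx - 1) * sx / 2.0, -(ny - 1) * sy / 2.0, 0.0)
    z_top = origin[2] + (nz - 1) * sz

    body = EllipticCylinder(
        center_xy=(0.0, 0.0),
        semi_axes_xy=(90.0 * body_scale, 80.0 * body_scale),
        z_range=(2.0, z_top - 2.0),
    )

    # subcutaneous shell: outer ring fixed, inner solved for 65% of the target
    ao, bo = 78.0, 68.0
    shell_z = (30.0, 180.0)
    h = shell_z[1] - shell_z[0]
    kappa2 = 1.0 - 0.65 * target_mm3 / (math.pi * ao * bo * h)
    kappa = math.sqrt(kappa2)
    shell = CylinderShell(
        center_xy=(0.0, 0.0),
        outer_semi_axes=(ao, bo),
        inner_semi_axes=(kappa * ao, kappa * bo),
        z_range=shell_z,
        compartment="subcutaneous",
    )

    # posterior compartment: fixed xy footprint, z semi-axis solved for 20%
    post_ab = (36.0, 20.0)
    c_post = 0.20 * target_mm3 / (4.0 / 3.0 * math.pi * post_ab[0] * post_ab[1])
    posterior = Ellipsoid(
        center=(0.0, -38.0, 105.0),
        semi_axes=(post_ab[0], post_ab[1], c_post),
        compartment="posterior",
    )

    # perivertebral compartment: 15%
    peri_ab = (32.0, 15.0)
    c_peri = 0.15 * target_mm3 / (4.0 / 3.0 * math.pi * peri_ab[0] * peri_ab[1])
    perivertebral = Ellipsoid(
        center=(0.0, 42.0, 105.0),
        semi_axes=(peri_ab[0], peri_ab[1], c_peri),
        compartment="perivertebral",
    )

    airway = Tube(center_xy=(0.0, 15.0), radius=airway_radius, z_range=(40.0, 160.0))

    landmarks = LandmarkSet(
        z_orbit_roof=body.z_range[1],
        z_sternal_angle=body.z_range[0],
        x_left_midclavicle=-95.0,
        x_right_midclavicle=95.0,
        z_hard_palate=airway.z_range[1],
        z_first_tracheal_ring=airway.z_range[0],
        z_soft_palate_tip=140.0,
        z_thyroid_cartilage=70.0,
        airway_seed=(0.0, 15.0, 100.0),
    )

    return PhantomSpec(
        grid_shape=(nx, ny, nz),
        spacing=spacing,
        origin=origin,
        body=body,
        fat_structures=(shell, posterior, perivertebral),
        airway=airway,
        bone=EllipticCylinder(
            center_xy=(0.0, 62.0), semi_axes_xy=(10.0, 10.0),
            z_range=(30.0, 180.0), hu=HU_BONE,
        ),
        noise_sd=noise_sd,
        seed=seed,
        landmarks=landmarks,
    )


def validation_suite(
    n: int = 10, seed: int = 0, noise_sd: float = 0.0
) -> list[PhantomSpec]:
    """Phantoms for volume-recovery validation: 1 mm isotropic, radii >= 20 mm.

    Each phantom has a soft-tissue body cylinder, two to three solid fat
    ellipsoids with semi-axes in [20, 38] mm, and an airway tube with radius
    in [20, 24] mm whose z-range ends fall midway between slice centres so
    the analytic tube length is an exact number of slices.
    """
    rng = np.random.default_rng(seed)
    spacing = (1.0, 1.0, 1.0)
    nx, ny, nz = 180, 160, 180
    origin = (-(nx - 1) / 2.0, -(ny - 1) / 2.0, 0.0)
    specs = []
    for i in range(n):
        body = EllipticCylinder(
            center_xy=(0.0, 0.0), semi_axes_xy=(80.0, 70.0), z_range=(2.0, 177.0)
        )
        tube_r = float(rng.uniform(20.0, 24.0))
        airway = Tube(center_xy=(0.0, 0.0), radius=tube_r, z_range=(29.5, 149.5))
        fats = [
            Ellipsoid(
                center=(54.0 + rng.uniform(-2, 2), rng.uniform(-3, 3), 90.0 + rng.uniform(-8, 8)),
                semi_axes=(
                    float(rng.uniform(20.0, 22.0)),
                    float(rng.uniform(20.0, 21.0)),
                    float(rng.uniform(25.0, 38.0)),
                ),
                compartment="subcutaneous",
            ),
            Ellipsoid(
                center=(-54.0 + rng.uniform(-2, 2), rng.uniform(-3, 3), 90.0 + rng.uniform(-8, 8)),
                semi_axes=(
                    float(rng.uniform(20.0, 22.0)),
                    float(rng.uniform(20.0, 21.0)),
                    float(rng.uniform(25.0, 38.0)),
                ),
                compartment="posterior",
            ),
        ]
        landmarks = LandmarkSet(
            z_orbit_roof=body.z_range[1],
            z_sternal_angle=body.z_range[0],
            x_left_midclavicle=-85.0,
            x_right_midclavicle=85.0,
            z_hard_palate=airway.z_range[1],
            z_first_tracheal_ring=airway.z_range[0],
            z_soft_palate_tip=120.0,
            z_thyroid_cartilage=60.0,
            airway_seed=(0.0, 0.0, 90.0),
        )
        specs.append(
            PhantomSpec(
                grid_shape=(nx, ny, nz),
                spacing=spacing,
                origin=origin,
                body=body,
                fat_structures=tuple(fats),
                airway=airway,
                noise_sd=noise_sd,
                seed=int(rng.integers(2**31)),
                landmarks=landmarks,
            )
        )
    return specs
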