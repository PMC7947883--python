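"""Digital thorax phantom: paired CT/PET volumes with a cylindrical
oesophageal tumour, ground-truth masks, and perturbed contour variants.

The phantom is deliberately schematic.  A thoracic oesophagus is modelled as
a gas-filled tube running cranio-caudally through a mediastinal fat block in
lung-density background; the tumour is a wall-thickened segment of that tube
(an annular cylinder) at one of three stations — upper, middle or distal
thorax (cohort groups A, B, C).  The PET volume carries a uniform-uptake
plateau over the tumour wall with a short cosine taper to background, so
that fraction-of-maximum and absolute SUV thresholds select nested,
near-truth regions.  A cardiac uptake region (sub-threshold by default) is
present for middle/distal tumours.

Every shape is voxelised by the centre-in-shape rule: a voxel belongs to a
structure iff its centre satisfies the analytic inequality.  Sub-voxel
shifts move the analytic shape before voxelisation, never resample a mask,
so ground truth carries no interpolation artefacts.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .core import BinaryMask, Grid, GtvSet, VoxelVolume, xyz_to_zyx

LOCATIONS = ("upper", "middle", "distal")
LOCATION_TO_GROUP = {"upper": "A", "middle": "B", "distal": "C"}
GROUP_TO_LOCATION = {v: k for k, v in LOCATION_TO_GROUP.items()}

#: fraction of the CC extent at which each tumour station is centred
_LOCATION_CC_FRACTION = {"upper": 0.70, "middle": 0.50, "distal": 0.30}

_AIR_HU = -1000.0
_HEART_HU = 40.0


class PhantomSizingError(ValueError):
    """A requested structure does not fit inside the grid."""


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensity and noise parameters of one synthetic patient.

    Lengths are mm, CT intensities Hounsfield units, PET intensities SUV.
    ``wall_thickness`` is the tumour wall; the residual lumen inside the
    tumour has radius ``tumor_radius - wall_thickness``.  ``seed`` fully
    determines the generated volumes.
    """

    grid_shape: tuple[int, int, int] = (160, 128, 128)  # (CC, AP, LR)
    spacing: tuple[float, float, float] = (3.0, 1.0, 1.0)  # mm; CC = slice thickness
    tumor_location: str = "middle"
    tumor_length: float = 85.0
    tumor_radius: float = 15.0
    wall_thickness: float = 13.0
    lumen_radius: float = 2.0          # normal oesophageal lumen
    esophagus_wall: float = 2.5        # normal (non-tumour) wall
    background_hu: float = -700.0
    mediastinum_hu: float = -80.0
    wall_hu: float = 40.0
    tumor_hu: float = 60.0
    background_suv: float = 1.0
    tumor_suvmax: float = 12.95
    heart_suv: float = 1.8
    pet_taper: float = 1.0             # mm, cosine fall-off outside the wall
    suv_noise_sd: float = 0.2
    hu_noise_sd: float = 10.0
    suvmax_range: tuple[float, float] = (3.21, 49.50)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tumor_location not in LOCATIONS:
            raise ValueError(f"unknown tumor_location {self.tumor_location!r}")
        for name in ("tumor_length", "tumor_radius", "wall_thickness",
                     "lumen_radius", "esophagus_wall", "pet_taper"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.wall_thickness > self.tumor_radius:
            raise ValueError("wall_thickness cannot exceed tumor_radius")
        lo, hi = self.suvmax_range
        if not (lo <= self.tumor_suvmax <= hi):
            raise ValueError(
                f"tumor_suvmax {self.tumor_suvmax} outside allowed range [{lo}, {hi}]"
            )
        if self.suv_noise_sd < 0 or self.hu_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")

    @property
    def grid(self) -> Grid:
        return Grid(self.grid_shape, self.spacing)

    @property
    def group(self) -> str:
        return LOCATION_TO_GROUP[self.tumor_location]


@dataclass(frozen=True)
class PerturbationSpec:
    """Known geometric difference applied to one derived contour variant.

    ``com_shift`` is mm in reporting order (LR, AP, CC).  ``length_delta``
    and ``radius_delta`` grow/shrink the cylinder.  ``deformation_amplitude``
    bends the tumour axis sinusoidally in AP, standing in for the smooth
    residual misalignment left between a diagnostic and a planning frame.
    Zero everywhere reproduces the ground-truth mask exactly.
    """

    com_shift: tuple[float, float, float] = (0.0, 0.0, 0.0)
    length_delta: float = 0.0
    radius_delta: float = 0.0
    deformation_amplitude: float = 0.0
    deformation_wavelength: float = 120.0

    @property
    def is_identity(self) -> bool:
        return (
            all(s == 0 for s in self.com_shift)
            and self.length_delta == 0
            and self.radius_delta == 0
            and self.deformation_amplitude == 0
        )


@dataclass(frozen=True)
class TumorShape:
    """Analytic annular cylinder, CC-aligned, optionally bent in AP.

    Centre in (CC, AP, LR) mm; membership is ``r_in <= r <= r_out`` within
    ``|z - zc| <= half_length`` where r is in-plane distance to the (bent)
    axis.
    """

    center_zyx: tuple[float, float, float]
    r_in: float
    r_out: float
    half_length: float
    bend_amplitude: float = 0.0
    bend_wavelength: float = 120.0

    def _axis_offset_ap(self, z: np.ndarray) -> np.ndarray:
        if self.bend_amplitude == 0.0:
            return np.zeros_like(z)
        zc = self.center_zyx[0]
        return self.bend_amplitude * np.sin(
            2.0 * math.pi * (z - zc) / self.bend_wavelength
        )

    def membership(self, z, y, x) -> np.ndarray:
        zc, yc, xc = self.center_zyx
        r = np.hypot(y - (yc + self._axis_offset_ap(z)), x - xc)
        in_cc = np.abs(z - zc) <= self.half_length
        return in_cc & (r >= self.r_in) & (r <= self.r_out)

    def distance_mm(self, z, y, x) -> np.ndarray:
        """Euclidean distance to the solid (0 inside); exact for zero bend."""
        zc, yc, xc = self.center_zyx
        r = np.hypot(y - (yc + self._axis_offset_ap(z)), x - xc)
        dr = np.maximum(np.maximum(self.r_in - r, r - self.r_out), 0.0)
        dz = np.maximum(np.abs(z - zc) - self.half_length, 0.0)
        return np.hypot(dr, dz)

    def signed_distance_mm(self, z, y, x) -> np.ndarray:
        """Signed boundary distance: negative inside the solid, positive out."""
        zc, yc, xc = self.center_zyx
        r = np.hypot(y - (yc + self._axis_offset_ap(z)), x - xc)
        outside = self.distance_mm(z, y, x)
        depth = np.minimum(
            np.minimum(r - self.r_in, self.r_out - r),
            self.half_length - np.abs(z - zc),
        )
        return np.where(outside > 0.0, outside, -np.maximum(depth, 0.0))

    def perturbed(self, pert: PerturbationSpec) -> "TumorShape":
        dzyx = xyz_to_zyx(pert.com_shift)
        zc, yc, xc = (c + d for c, d in zip(self.center_zyx, dzyx))
        r_out = self.r_out + pert.radius_delta
        half = self.half_length + pert.length_delta / 2.0
        if r_out <= self.r_in or half <= 0:
            raise PhantomSizingError(
                "perturbation collapses the tumour (non-positive wall or length)"
            )
        return TumorShape(
            (zc, yc, xc),
            self.r_in,
            r_out,
            half,
            bend_amplitude=self.bend_amplitude + pert.deformation_amplitude,
            bend_wavelength=pert.deformation_wavelength,
        )

    def bounds_zyx(self) -> tuple[np.ndarray, np.ndarray]:
        zc, yc, xc = self.center_zyx
        pad = self.r_out + abs(self.bend_amplitude)
        lo = np.array([zc - self.half_length, yc - pad, xc - pad])
        hi = np.array([zc + self.half_length, yc + pad, xc + pad])
        return lo, hi


@dataclass
class SyntheticPatient:
    """One simulated case: volumes, ground truth, and contour variants."""

    id: str
    group: str
    spec: PhantomSpec
    planning_ct: VoxelVolume
    pet_suv: VoxelVolume          # planning-frame, i.e. already registered
    truth_mask: BinaryMask
    truth_shape: TumorShape
    heart_mask: BinaryMask | None
    gtv_set: GtvSet
    applied_perturbations: dict[str, PerturbationSpec] = field(default_factory=dict)

    @property
    def esophagus_axis_mm(self) -> np.ndarray:
        """Tumour-axis polyline, (n, 3) in (LR, AP, CC) mm."""
        grid = self.truth_mask.grid
        z0, z1 = 0.0, grid.extent_mm[0]
        _, yc, xc = self.truth_shape.center_zyx
        return np.array([[xc, yc, z0], [xc, yc, z1]])


def _tumor_shape_for(spec: PhantomSpec) -> TumorShape:
    grid = spec.grid
    ext = grid.extent_mm
    zc = _LOCATION_CC_FRACTION[spec.tumor_location] * ext[0]
    # axis on a voxel centre so integer-mm shifts stay lattice-aligned
    yc = (grid.shape[1] // 2) * grid.spacing[1]
    xc = (grid.shape[2] // 2) * grid.spacing[2]
    return TumorShape(
        (zc, yc, xc),
        r_in=spec.tumor_radius - spec.wall_thickness,
        r_out=spec.tumor_radius,
        half_length=spec.tumor_length / 2.0,
    )


def _check_fits(shape: TumorShape, grid: Grid) -> None:
    lo, hi = shape.bounds_zyx()
    ext = np.asarray(grid.extent_mm)
    if np.any(lo < 0.0) or np.any(hi > ext):
        raise PhantomSizingError(
            f"tumour bounds {lo}..{hi} mm exceed grid extent {ext} mm"
        )


def voxelize(shape: TumorShape, grid: Grid) -> BinaryMask:
    """Centre-in-shape voxelisation of an analytic tumour shape."""
    z, y, x = grid.meshgrid_mm()
    return BinaryMask(shape.membership(z, y, x), grid)


def make_phantom(spec: PhantomSpec) -> SyntheticPatient:
    """Build one synthetic patient from a :class:`PhantomSpec`.

    The returned patient's ``gtv_set`` holds three identity copies of the
    truth mask; :func:`derive_contour_variants` replaces them with perturbed
    variants.  Deterministic given ``spec.seed``.
    """
    grid = spec.grid
    tumor = _tumor_shape_for(spec)
    _check_fits(tumor, grid)
    z, y, x = grid.meshgrid_mm()
    zc, yc, xc = tumor.center_zyx

    # ---- CT ------------------------------------------------------------
    ct = np.full(grid.shape, spec.background_hu)
    in_block = np.broadcast_to(
        (np.abs(y - yc) <= 30.0) & (np.abs(x - xc) <= 30.0), grid.shape
    )
    ct[in_block] = spec.mediastinum_hu

    heart_mask = None
    if spec.tumor_location in ("middle", "distal"):
        hz = 0.35 * grid.extent_mm[0]
        hy, hx, hr = yc - 38.0, xc, 20.0
        d_heart = np.sqrt((z - hz) ** 2 + (y - hy) ** 2 + (x - hx) ** 2)
        heart = d_heart <= hr
        ct[heart] = _HEART_HU
        heart_mask = BinaryMask(heart, grid)

    r_plane = np.hypot(y - yc, x - xc)
    in_tumor_cc = np.abs(z - zc) <= tumor.half_length
    normal_outer = spec.lumen_radius + spec.esophagus_wall
    wall = (r_plane >= spec.lumen_radius) & (r_plane <= normal_outer) & ~in_tumor_cc
    ct[wall] = spec.wall_hu

    truth = tumor.membership(z, y, x)
    ct[truth] = spec.tumor_hu

    lumen = ((r_plane < spec.lumen_radius) & ~in_tumor_cc) | (
        in_tumor_cc & (r_plane < tumor.r_in)
    )
    ct[lumen] = _AIR_HU

    # ---- PET -----------------------------------------------------------
    # cosine taper centred on the tumour boundary (edge at half-maximum),
    # emulating an even blur of a uniform-uptake lesion
    def _taper_weight(signed_d: np.ndarray) -> np.ndarray:
        half = spec.pet_taper / 2.0
        u = np.clip((signed_d + half) / spec.pet_taper, 0.0, 1.0)
        return 0.5 * (1.0 + np.cos(math.pi * u))

    pet = np.full(grid.shape, spec.background_suv)
    w = _taper_weight(tumor.signed_distance_mm(z, y, x))
    pet = np.maximum(pet, spec.background_suv + (spec.tumor_suvmax - spec.background_suv) * w)

    if heart_mask is not None and spec.heart_suv > spec.background_suv:
        wh = _taper_weight(d_heart - hr)
        pet = np.maximum(
            pet, spec.background_suv + (spec.heart_suv - spec.background_suv) * wh
        )

    # ---- noise ---------------------------------------------------------
    rng = np.random.default_rng(spec.seed)
    if spec.hu_noise_sd > 0:
        ct = ct + rng.normal(0.0, spec.hu_noise_sd, grid.shape)
    if spec.suv_noise_sd > 0:
        pet = pet + rng.normal(0.0, spec.suv_noise_sd, grid.shape)
    # float32 matches on-disk storage and halves the cohort footprint
    ct = np.clip(ct, -1024.0, 3071.0).astype(np.float32)
    pet = np.clip(pet, 0.0, None).astype(np.float32)

    truth_mask = BinaryMask(truth, grid)
    identity = PerturbationSpec()
    gtv_set = GtvSet(
        truth_mask.copy(), truth_mask.copy(), truth_mask.copy(), truth=truth_mask
    )
    return SyntheticPatient(
        id=f"{spec.group}000",
        group=spec.group,
        spec=spec,
        planning_ct=VoxelVolume(ct, grid),
        pet_suv=VoxelVolume(pet, grid),
        truth_mask=truth_mask,
        truth_shape=tumor,
        heart_mask=heart_mask,
        gtv_set=gtv_set,
        applied_perturbations={n: identity for n in ("GTV_3D", "GTV_PET-ref", "GTV_PET-reg")},
    )


def derive_contour_variants(
    patient: SyntheticPatient,
    perts: dict[str, PerturbationSpec],
) -> GtvSet:
    """Voxelise the three contour variants of a patient's truth shape.

    ``perts`` maps each variant name (``GTV_3D``, ``GTV_PET-ref``,
    ``GTV_PET-reg``) to its perturbation; missing names get the identity.
    The patient's ``gtv_set`` and ``applied_perturbations`` are updated in
    place and the new set returned.
    """
    if patient.truth_mask.is_empty:
        raise EmptyTruthError("patient has an empty truth mask")
    grid = patient.truth_mask.grid
    masks: dict[str, BinaryMask] = {}
    applied: dict[str, PerturbationSpec] = {}
    for name in ("GTV_3D", "GTV_PET-ref", "GTV_PET-reg"):
        pert = perts.get(name, PerturbationSpec())
        if pert.is_identity:
            masks[name] = patient.truth_mask.copy()
        else:
            shape = patient.truth_shape.perturbed(pert)
            _check_fits(shape, grid)
            masks[name] = voxelize(shape, grid)
        applied[name] = pert
    gtvs = GtvSet(
        masks["GTV_3D"], masks["GTV_PET-ref"], masks["GTV_PET-reg"],
        truth=patient.truth_mask,
    )
    patient.gtv_set = gtvs
    patient.applied_perturbations = applied
    return gtvs


class EmptyTruthError(ValueError):
    pass


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantPerturbationModel:
    """Gaussian draw model for one variant's perturbation (units mm)."""

    com_sd: tuple[float, float, float] = (0.0, 0.0, 0.0)   # (LR, AP, CC)
    com_bias: tuple[float, float, float] = (0.0, 0.0, 0.0)
    length_sd: float = 0.0
    length_bias: float = 0.0
    radius_sd: float = 0.0
    radius_bias: float = 0.0
    deformation_amplitude: float = 0.0

    def draw(self, rng: np.random.Generator) -> PerturbationSpec:
        shift = tuple(
            b + (rng.normal(0.0, s) if s > 0 else 0.0)
            for b, s in zip(self.com_bias, self.com_sd)
        )
        ld = self.length_bias + (rng.normal(0.0, self.length_sd) if self.length_sd > 0 else 0.0)
        rd = self.radius_bias + (rng.normal(0.0, self.radius_sd) if self.radius_sd > 0 else 0.0)
        return PerturbationSpec(
            com_shift=shift,
            length_delta=ld,
            radius_delta=rd,
            deformation_amplitude=self.deformation_amplitude,
        )


@dataclass(frozen=True)
class GroupPerturbationModel:
    """Per-variant perturbation distributions for one tumour-location group."""

    gtv_3d: VariantPerturbationModel = VariantPerturbationModel()
    gtv_pet_ref: VariantPerturbationModel = VariantPerturbationModel()
    gtv_pet_reg: VariantPerturbationModel = VariantPerturbationModel()

    def draw(self, rng: np.random.Generator) -> dict[str, PerturbationSpec]:
        return {
            "GTV_3D": self.gtv_3d.draw(rng),
            "GTV_PET-ref": self.gtv_pet_ref.draw(rng),
            "GTV_PET-reg": self.gtv_pet_reg.draw(rng),
        }


def default_group_perturbations(scale: float = 1.0) -> dict[str, GroupPerturbationModel]:
    """Default per-group perturbation distributions.

    Contour-variant differences are dominated by size disagreement (length
    and radius deltas) with mm-scale centroid scatter; the distal group (C)
    carries roughly three-fold larger centroid scatter, emulating the larger
    motion of distal tumours.  The PET-referenced variant is biased longer
    and narrower and the threshold-derived variant slightly shorter and
    narrower than the CT-only contour.  Magnitudes are calibrated so the
    cohort-median conformity index between variants is ~0.70; ``scale``
    multiplies every spread and bias for what-if studies.
    """
    def var(com_sd, com_bias=(0, 0, 0), lb=0.0, rb=0.0):
        return VariantPerturbationModel(
            com_sd=tuple(scale * s for s in com_sd),
            com_bias=tuple(scale * b for b in com_bias),
            length_sd=scale * 8.0,
            length_bias=scale * lb,
            radius_sd=scale * 1.05,
            radius_bias=scale * rb,
        )

    def group(s):
        return GroupPerturbationModel(
            gtv_3d=var(s),
            gtv_pet_ref=var(s, lb=6.0, rb=-0.9),
            gtv_pet_reg=var(s, lb=-1.6, rb=-0.7),
        )

    return {
        "A": group((0.35, 0.35, 0.5)),
        "B": group((0.7, 0.7, 1.0)),
        "C": group((1.5, 2.5, 2.5)),
    }


def _patient_seed(global_seed: int, patient_id: str) -> np.random.SeedSequence:
    # stable per-id substream: cohort-size changes never reshuffle patients
    return np.random.SeedSequence([int(global_seed), zlib.crc32(patient_id.encode())])


def _draw_patient_spec(
    base: PhantomSpec, location: str, rng: np.random.Generator, seed: int
) -> PhantomSpec:
    lo, hi = base.suvmax_range
    # right-skewed SUVmax, clipped to the enrolment range (mean ~13)
    suvmax = float(np.clip(rng.lognormal(math.log(10.3), 0.6), lo, hi))
    # per-patient size scatter around the base geometry, kept inside the
    # grid with margin for the perturbations applied downstream
    ext = np.asarray(base.grid.extent_mm)
    zc = _LOCATION_CC_FRACTION[location] * ext[0]
    yc = (base.grid_shape[1] // 2) * base.spacing[1]
    xc = (base.grid_shape[2] // 2) * base.spacing[2]
    max_len = 2.0 * (min(zc, ext[0] - zc) - 15.0)
    max_rad = min(yc, xc, ext[1] - yc, ext[2] - xc) - 8.0
    length = float(np.clip(
        rng.normal(base.tumor_length, 0.26 * base.tumor_length),
        0.4 * base.tumor_length, min(1.65 * base.tumor_length, max_len),
    ))
    radius = float(np.clip(
        rng.normal(base.tumor_radius, base.tumor_radius / 6.0),
        max(0.55 * base.tumor_radius, base.lumen_radius + 2.0),
        min(1.6 * base.tumor_radius, max_rad),
    ))
    return replace(
        base,
        tumor_location=location,
        tumor_suvmax=suvmax,
        tumor_length=length,
        tumor_radius=radius,
        wall_thickness=radius - base.lumen_radius,
        seed=seed,
    )


def make_cohort(
    n_a: int = 32,
    n_b: int = 24,
    n_c: int = 16,
    distributions: dict[str, GroupPerturbationModel] | None = None,
    seed: int = 0,
    base_spec: PhantomSpec | None = None,
) -> list[SyntheticPatient]:
    """Simulate a cohort with group sizes (upper/middle/distal) = (n_a, n_b, n_c).

    Defaults reproduce the study conditions: 72 patients split 32/24/16 with
    SUVmax drawn in [3.21, 49.50], so every patient passes the SUVmax >= 2
    enrolment filter.  ``distributions`` maps group label -> per-variant
    perturbation model (see :func:`default_group_perturbations`).
    """
    if min(n_a, n_b, n_c) < 0:
        raise ValueError("group counts must be >= 0")
    if distributions is None:
        distributions = default_group_perturbations()
    base = base_spec if base_spec is not None else PhantomSpec()
    patients: list[SyntheticPatient] = []
    for group, n in (("A", n_a), ("B", n_b), ("C", n_c)):
        location = GROUP_TO_LOCATION[group]
        model = distributions[group]
        for i in range(n):
            pid = f"{group}{i + 1:03d}"
            ss = _patient_seed(seed, pid)
            rng = np.random.default_rng(ss)
            noise_seed = int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
            spec = _draw_patient_spec(base, location, rng, noise_seed)
            patient = make_phantom(spec)
            patient.id = pid
            perts = {
                name: _clamp_perturbation(p, patient.truth_shape, spec.grid)
                for name, p in model.draw(rng).items()
            }
            derive_contour_variants(patient, perts)
            patients.append(patient)
    return patients


def _clamp_perturbation(
    pert: PerturbationSpec, shape: TumorShape, grid: Grid
) -> PerturbationSpec:
    """Truncate drawn deltas so the variant keeps >=1 mm wall and one slice."""
    rd_min = shape.r_in + 1.0 - shape.r_out
    ld_min = grid.spacing[0] - 2.0 * shape.half_length
    if pert.radius_delta >= rd_min and pert.length_delta >= ld_min:
        return pert
    return replace(
        pert,
        radius_delta=max(pert.radius_delta, rd_min),
        length_delta=max(pert.length_delta, ld_min),
    )
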