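"""Rule-based target-volume delineation on CT and PET volumes.

Two contouring routes are implemented:

* **SUV thresholding** inside a spherical region of interest: the effective
  threshold combines an absolute SUV floor of 2.5 with 20% of the SUVmax
  found inside the ROI; by default a single contour is produced at
  ``T = max(absolute, fraction × SUVmax)`` so that both published criteria
  act as floors.  Each criterion alone is also available as a mode, since
  clinical practice varies in how the two are combined.  Cases whose ROI
  SUVmax falls below 2 fail the enrolment criterion and raise.

* **CT wall rule**: on mediastinal window/level settings, an axial slice of
  the oesophagus is considered tumour-bearing when the soft-tissue wall
  around the lumen is thicker than 5 mm or the wall diameter (without gas)
  exceeds 10 mm.  The published rule is a manual-contouring instruction;
  the per-slice estimator here (maximal inscribed-disc wall thickness and
  in-plane Feret diameter of the component nearest the oesophageal axis) is
  an explicit machine surrogate of it for phantom work.

A heart-repair helper subtracts a CT-derived cardiac mask from a PET
contour, for cases whose myocardial uptake clears the threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import BinaryMask, Grid, VoxelVolume, require_same_grid, xyz_to_zyx

__all__ = [
    "ThresholdSpec",
    "CtRuleSpec",
    "DelineationResult",
    "EnrollmentError",
    "suv_threshold",
    "exclude_heart",
    "ct_wall_rule",
]

#: enrolment criterion: cases below this ROI SUVmax are not analysed
ENROLLMENT_SUVMAX = 2.0


class EnrollmentError(ValueError):
    """The ROI SUVmax is below the enrolment criterion (SUVmax >= 2)."""


@dataclass(frozen=True)
class ThresholdSpec:
    """PET auto-contour parameters.

    ``roi_center`` is (LR, AP, CC) mm; the sphere must be centred inside
    the grid.  ``mode`` selects how the two published criteria combine:
    ``"combined"`` (default, max of both), ``"absolute"`` or ``"fraction"``.
    """

    absolute_suv: float = 2.5
    fraction_of_max: float = 0.20
    roi_center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    roi_radius: float = 50.0
    mode: str = "combined"

    def __post_init__(self) -> None:
        if self.absolute_suv <= 0:
            raise ValueError("absolute_suv must be > 0")
        if not (0.0 < self.fraction_of_max < 1.0):
            raise ValueError("fraction_of_max must lie in (0, 1)")
        if self.roi_radius <= 0:
            raise ValueError("roi_radius must be > 0")
        if self.mode not in ("combined", "absolute", "fraction"):
            raise ValueError(f"unknown threshold mode {self.mode!r}")

    def effective_threshold(self, suvmax: float) -> float:
        if self.mode == "absolute":
            return self.absolute_suv
        if self.mode == "fraction":
            return self.fraction_of_max * suvmax
        return max(self.absolute_suv, self.fraction_of_max * suvmax)


@dataclass(frozen=True)
class CtRuleSpec:
    """Mediastinal window settings and wall-rule cut-offs."""

    window_width: float = 400.0     # HU
    window_level: float = 40.0      # HU
    wall_thickness_min: float = 5.0   # mm, keep slice if wall strictly thicker
    wall_diameter_min: float = 10.0   # mm, or wall diameter strictly larger
    soft_tissue_min_hu: float = 0.0   # windowed-HU floor for "soft tissue"
    axis_search_radius: float = 20.0  # mm, how far from the axis to look

    def __post_init__(self) -> None:
        for name in ("window_width", "window_level", "wall_thickness_min",
                     "wall_diameter_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class DelineationResult:
    """An auto-contour plus the quantities the operator logged."""

    mask: BinaryMask
    effective_threshold: float
    suvmax: float
    voxel_count: int


def _roi_sphere(grid: Grid, center_xyz, radius: float) -> np.ndarray:
    center = xyz_to_zyx(center_xyz)
    if not grid.contains_point_zyx(center):
        raise ValueError(f"ROI centre {tuple(center_xyz)} mm lies outside the grid")
    z, y, x = grid.meshgrid_mm()
    d2 = (z - center[0]) ** 2 + (y - center[1]) ** 2 + (x - center[2]) ** 2
    return d2 <= radius**2


def suv_threshold(pet: VoxelVolume, spec: ThresholdSpec) -> DelineationResult:
    """Threshold a PET volume inside a spherical ROI.

    The SUVmax is taken within the ROI sphere (mirroring the sphere-drag
    workflow of clinical auto-contouring), the effective threshold derived
    per ``spec.mode``, and all ROI voxels with SUV >= threshold kept.
    Raises :class:`EnrollmentError` when SUVmax < 2; warns on an empty
    result.
    """
    roi = _roi_sphere(pet.grid, spec.roi_center, spec.roi_radius)
    if not roi.any():
        raise ValueError("ROI sphere contains no voxels")
    suvmax = float(pet.data[roi].max())
    if suvmax < ENROLLMENT_SUVMAX:
        raise EnrollmentError(
            f"ROI SUVmax {suvmax:.2f} < {ENROLLMENT_SUVMAX}: case fails enrolment"
        )
    threshold = spec.effective_threshold(suvmax)
    mask = roi & (pet.data >= threshold)
    if not mask.any():
        warnings.warn(
            f"threshold {threshold:.2f} selected no voxels inside the ROI"
        )
    return DelineationResult(
        mask=BinaryMask(mask, pet.grid),
        effective_threshold=float(threshold),
        suvmax=suvmax,
        voxel_count=int(mask.sum()),
    )


def exclude_heart(
    gtv: BinaryMask, heart: BinaryMask, ct: VoxelVolume | None = None
) -> BinaryMask:
    """Repair a PET contour by removing the CT-determined heart.

    The heart boundary is taken from the supplied mask (delineated on CT);
    the optional ``ct`` argument only asserts shared geometry.  Disjoint
    masks return the contour unchanged; a fully covered contour returns an
    empty mask with a warning.
    """
    objs = [gtv, heart] + ([ct] if ct is not None else [])
    require_same_grid(*objs)
    out = gtv.data & ~heart.data
    if not out.any() and not gtv.is_empty:
        warnings.warn("heart exclusion removed the entire contour")
    return BinaryMask(out, gtv.grid)


def _axis_point_for_slice(axis_mm: np.ndarray, z_mm: float) -> tuple[float, float]:
    """Interpolate the oesophageal axis polyline at one slice; (AP, LR) mm."""
    pts = np.asarray(axis_mm, dtype=float)  # (n, 3) in (LR, AP, CC)
    order = np.argsort(pts[:, 2])
    pts = pts[order]
    x = np.interp(z_mm, pts[:, 2], pts[:, 0])
    y = np.interp(z_mm, pts[:, 2], pts[:, 1])
    return y, x


def _wall_component(
    soft: np.ndarray, ay: float, ax: float, sp_yx: tuple[float, float], max_r: float
):
    """Connected soft-tissue component nearest the axis point, or None."""
    labels, n = ndimage.label(soft)
    if n == 0:
        return None
    yy = np.arange(soft.shape[0])[:, None] * sp_yx[0]
    xx = np.arange(soft.shape[1])[None, :] * sp_yx[1]
    d = np.hypot(yy - ay, xx - ax)
    d_soft = np.where(soft, d, np.inf)
    best = np.unravel_index(np.argmin(d_soft), d_soft.shape)
    if d_soft[best] > max_r:
        return None
    return labels == labels[best]


def ct_wall_rule(
    ct: VoxelVolume, esophagus_axis, spec: CtRuleSpec | None = None
) -> BinaryMask:
    """Slice-wise oesophageal wall rule on a windowed CT volume.

    ``esophagus_axis`` is an (n, 3) polyline of (LR, AP, CC) mm points
    tracing the oesophageal lumen.  Per axial slice, HU are clamped to the
    mediastinal window, soft tissue is segmented, and the component nearest
    the axis point is kept iff its estimated wall thickness exceeds
    ``wall_thickness_min`` or its in-plane diameter exceeds
    ``wall_diameter_min``.  The union of kept components is the CT-based
    GTV surrogate.
    """
    if spec is None:
        spec = CtRuleSpec()
    axis_mm = np.asarray(esophagus_axis, dtype=float)
    if axis_mm.ndim != 2 or axis_mm.shape[1] != 3:
        raise ValueError("esophagus_axis must be an (n, 3) array of (LR, AP, CC) mm")
    for p in axis_mm:
        if not ct.grid.contains_point_zyx(xyz_to_zyx(p)):
            raise ValueError(f"axis point {tuple(p)} mm lies outside the grid")

    lo = spec.window_level - spec.window_width / 2.0
    hi = spec.window_level + spec.window_width / 2.0
    windowed = np.clip(ct.data, lo, hi)
    soft3d = windowed >= spec.soft_tissue_min_hu

    sp = ct.grid.spacing
    sp_yx = (sp[1], sp[2])
    inplane_voxel = 0.5 * (sp[1] + sp[2])
    out = np.zeros(ct.grid.shape, dtype=bool)
    for k in range(ct.grid.shape[0]):
        z_mm = k * sp[0]
        ay, ax = _axis_point_for_slice(axis_mm, z_mm)
        comp = _wall_component(soft3d[k], ay, ax, sp_yx, spec.axis_search_radius)
        if comp is None:
            continue
        # wall thickness: diameter of the largest inscribed disc
        thickness = 2.0 * float(
            ndimage.distance_transform_edt(comp, sampling=sp_yx).max()
        )
        pts = np.argwhere(comp).astype(float) * np.array(sp_yx)
        if len(pts) > 1:
            from .metrics import _max_pairwise_distance

            diameter = _max_pairwise_distance(pts) + inplane_voxel
        else:
            diameter = inplane_voxel
        if thickness > spec.wall_thickness_min or diameter > spec.wall_diameter_min:
            out[k] = comp
    return BinaryMask(out, ct.grid)


def tumor_roi(patient, margin: float = 10.0) -> ThresholdSpec:
    """ROI sphere covering a synthetic patient's tumour, for SUV contouring."""
    from .metrics import center_of_mass

    com = center_of_mass(patient.truth_mask)
    shape = patient.truth_shape
    radius = float(np.hypot(shape.half_length, shape.r_out) + margin)
    return ThresholdSpec(roi_center=tuple(com), roi_radius=radius)
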