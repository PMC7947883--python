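"""Pairwise geometric concordance metrics for binary target volumes.

Given two contours A and B on one voxel grid the module computes:

* the centre-of-mass (COM) displacement per anatomical axis (LR, AP, CC)
  and its 3D vector ``V = sqrt(dx^2 + dy^2 + dz^2)``;
* the conformity index ``CI = |A∩B| / |A∪B|`` (Jaccard coefficient;
  1 iff the volumes are identical);
* the degree of inclusion ``DI(A in B) = |A∩B| / |A|`` — if B is the
  reference volume, a plan drawn on A irradiates a fraction ``1 − DI(A in B)``
  of A unnecessarily;
* the Dice score ``2|A∩B| / (|A| + |B|)`` and the symmetric Hausdorff
  distance between member-voxel centres (registration-QA companions);
* per-contour shape measures: volume (cm^3), cranio-caudal length (cm) and
  maximum transverse diameter (cm).

COM is unweighted — contours, not intensity images, are compared.  All
internal computation is in mm; shape measures are reported in cm/cm^3 to
match clinical reporting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import cdist

from .core import (
    PAIR_NAMES,
    BinaryMask,
    EmptyMaskError,
    GtvSet,
    require_same_grid,
    zyx_to_xyz,
)

__all__ = [
    "DisplacementRecord",
    "OverlapRecord",
    "ShapeRecord",
    "MetricRecord",
    "center_of_mass",
    "displacement",
    "overlap",
    "shape_measures",
    "hausdorff",
    "compare_gtv_set",
]


@dataclass(frozen=True)
class DisplacementRecord:
    """Signed per-axis COM displacement (A minus B, mm) and its 3D vector."""

    dx_lr: float
    dy_ap: float
    dz_cc: float

    @property
    def vector_v(self) -> float:
        return float(np.sqrt(self.dx_lr**2 + self.dy_ap**2 + self.dz_cc**2))


@dataclass(frozen=True)
class OverlapRecord:
    """Volume-overlap measures of an ordered pair (A, B)."""

    ci: float
    di_a_in_b: float
    di_b_in_a: float
    dice: float
    hausdorff: float          # mm; NaN when a side is empty
    vol_a: float              # cm^3
    vol_b: float
    vol_intersection: float


@dataclass(frozen=True)
class ShapeRecord:
    """Size measures of one contour, in clinical units."""

    volume: float                    # cm^3
    length: float                    # cm, CC extent of occupied slices
    max_transverse_diameter: float   # cm


def center_of_mass(mask: BinaryMask) -> np.ndarray:
    """Unweighted COM of member-voxel centres, mm in (LR, AP, CC) order."""
    if mask.is_empty:
        raise EmptyMaskError("center of mass of an empty mask is undefined")
    idx_mean = np.array(
        [m.mean() for m in np.nonzero(mask.data)], dtype=float
    )
    com_zyx = idx_mean * np.asarray(mask.grid.spacing)
    return zyx_to_xyz(com_zyx)


def displacement(a: BinaryMask, b: BinaryMask) -> DisplacementRecord:
    """COM displacement of A relative to B with the 3D vector norm."""
    require_same_grid(a, b)
    da = center_of_mass(a) - center_of_mass(b)
    return DisplacementRecord(dx_lr=float(da[0]), dy_ap=float(da[1]), dz_cc=float(da[2]))


def _crop_pair(a: BinaryMask, b: BinaryMask):
    """Joint bounding-box views of two masks (speeds up distance transforms)."""
    union = a.data | b.data
    idx = np.argwhere(union)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    sl = tuple(slice(l, h) for l, h in zip(lo, hi))
    return a.data[sl], b.data[sl]


def hausdorff(a: BinaryMask, b: BinaryMask) -> float:
    """Symmetric Hausdorff distance (mm) between member-voxel centres.

    Computed with Euclidean distance transforms on the joint bounding box;
    exact for voxel-centre point sets because every member voxel (not just
    the surface) is a candidate.
    """
    require_same_grid(a, b)
    if a.is_empty or b.is_empty:
        raise EmptyMaskError("Hausdorff distance requires two nonempty masks")
    sp = a.grid.spacing
    da, db = _crop_pair(a, b)
    dist_to_b = ndimage.distance_transform_edt(~db, sampling=sp)
    dist_to_a = ndimage.distance_transform_edt(~da, sampling=sp)
    return float(max(dist_to_b[da].max(), dist_to_a[db].max()))


def overlap(a: BinaryMask, b: BinaryMask) -> OverlapRecord:
    """All pairwise overlap measures of the ordered pair (A, B).

    Both masks empty is an error.  One empty side yields CI = 0, DI of the
    empty side 0 (with a warning) and an undefined (NaN) Hausdorff.
    """
    require_same_grid(a, b)
    na, nb = a.count, b.count
    if na == 0 and nb == 0:
        raise EmptyMaskError("overlap of two empty masks is undefined")
    ni = int((a.data & b.data).sum())
    nu = na + nb - ni
    if na == 0 or nb == 0:
        warnings.warn("one mask is empty; its degree of inclusion is set to 0")
    ci = ni / nu
    di_ab = ni / na if na else 0.0
    di_ba = ni / nb if nb else 0.0
    dice = 2.0 * ni / (na + nb)
    hd = hausdorff(a, b) if (na and nb) else float("nan")
    cc = a.grid.voxel_volume_mm3 / 1000.0  # mm^3 -> cm^3
    return OverlapRecord(
        ci=ci,
        di_a_in_b=di_ab,
        di_b_in_a=di_ba,
        dice=dice,
        hausdorff=hd,
        vol_a=na * cc,
        vol_b=nb * cc,
        vol_intersection=ni * cc,
    )


def _max_pairwise_distance(points: np.ndarray) -> float:
    """Largest distance between 2D points; convex hull first when many."""
    if len(points) == 1:
        return 0.0
    if len(points) > 200:
        try:
            points = points[ConvexHull(points).vertices]
        except QhullError:
            pass  # collinear points; brute force below
    return float(cdist(points, points).max())


def shape_measures(mask: BinaryMask) -> ShapeRecord:
    """Volume, cranio-caudal length and maximum transverse diameter.

    Length is the occupied-slice extent ``(last − first + 1) × thickness``
    (internal empty slices do not subtract), matching the clinical reading
    of cranio-caudal tumour length.  The maximum transverse diameter is the
    largest in-plane distance between member-voxel centres on any axial
    slice plus one in-plane voxel (full-width convention).
    """
    if mask.is_empty:
        raise EmptyMaskError("shape measures of an empty mask are undefined")
    sp = mask.grid.spacing
    volume_cm3 = mask.count * mask.grid.voxel_volume_mm3 / 1000.0

    occupied = np.flatnonzero(mask.data.any(axis=(1, 2)))
    length_cm = (occupied[-1] - occupied[0] + 1) * sp[0] / 10.0

    inplane_voxel = 0.5 * (sp[1] + sp[2])
    best = 0.0
    for k in occupied:
        pts = np.argwhere(mask.data[k]).astype(float) * np.array([sp[1], sp[2]])
        best = max(best, _max_pairwise_distance(pts))
    diameter_cm = (best + inplane_voxel) / 10.0
    return ShapeRecord(
        volume=volume_cm3, length=length_cm, max_transverse_diameter=diameter_cm
    )


@dataclass
class MetricRecord:
    """All pairwise comparisons and per-variant shapes for one patient.

    ``displacements``/``overlaps`` are keyed ``"<A> and <B>"`` for the three
    pairs; ``inclusion`` expands the six ordered entries ``"<A> in <B>"``.
    Pairs that could not be computed (an empty contour) are listed in
    ``flagged`` and absent from the dictionaries.
    """

    patient_id: str = ""
    group: str = ""
    displacements: dict[str, DisplacementRecord] = field(default_factory=dict)
    overlaps: dict[str, OverlapRecord] = field(default_factory=dict)
    shapes: dict[str, ShapeRecord] = field(default_factory=dict)
    flagged: list[str] = field(default_factory=list)

    @property
    def inclusion(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for key, rec in self.overlaps.items():
            na, nb = key.split(" and ")
            out[f"{na} in {nb}"] = rec.di_a_in_b
            out[f"{nb} in {na}"] = rec.di_b_in_a
        return out

    def to_flat_dict(self) -> dict[str, float | str]:
        row: dict[str, float | str] = {"patient_id": self.patient_id, "group": self.group}
        for key, d in self.displacements.items():
            row[f"dx_lr [{key}]"] = d.dx_lr
            row[f"dy_ap [{key}]"] = d.dy_ap
            row[f"dz_cc [{key}]"] = d.dz_cc
            row[f"vector_v [{key}]"] = d.vector_v
        for key, o in self.overlaps.items():
            row[f"ci [{key}]"] = o.ci
            row[f"dice [{key}]"] = o.dice
            row[f"hausdorff_mm [{key}]"] = o.hausdorff
        for key, v in self.inclusion.items():
            row[f"di [{key}]"] = v
        for name, s in self.shapes.items():
            row[f"volume_cm3 [{name}]"] = s.volume
            row[f"length_cm [{name}]"] = s.length
            row[f"max_diameter_cm [{name}]"] = s.max_transverse_diameter
        return row


def compare_gtv_set(
    gtvs: GtvSet, patient_id: str = "", group: str = ""
) -> MetricRecord:
    """Run every pairwise and per-variant measure on one contour set.

    An empty variant flags the comparisons involving it; the remaining
    pairs and shapes are still computed.
    """
    require_same_grid(gtvs.gtv_3d, gtvs.gtv_pet_ref, gtvs.gtv_pet_reg)
    rec = MetricRecord(patient_id=patient_id, group=group)
    for name, mask in gtvs.items():
        if mask.is_empty:
            rec.flagged.append(name)
        else:
            rec.shapes[name] = shape_measures(mask)
    for na, nb in PAIR_NAMES:
        key = f"{na} and {nb}"
        if na in rec.flagged or nb in rec.flagged:
            rec.flagged.append(key)
            continue
        rec.displacements[key] = displacement(gtvs[na], gtvs[nb])
        rec.overlaps[key] = overlap(gtvs[na], gtvs[nb])
    return rec
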