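"""Core containers: voxel grids, scalar volumes, binary masks and GTV sets.

Arrays are ordered ``(CC, AP, LR)`` — axis 0 runs cranio-caudally (z), axis 1
antero-posteriorly (y), axis 2 left-right (x).  All physical quantities are in
millimetres.  User-facing coordinates (centre of mass, displacement, applied
shifts) are reported in the conventional ``(LR, AP, CC)`` = ``(x, y, z)``
order; :func:`zyx_to_xyz` / :func:`xyz_to_zyx` convert between the two.  The
centre of voxel ``(i, j, k)`` sits at ``(i*dz, j*dy, k*dx)`` mm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

#: array axis order (index 0, 1, 2)
ARRAY_AXES = ("CC", "AP", "LR")
#: reporting axis order for coordinates and displacements
REPORT_AXES = ("LR", "AP", "CC")

#: canonical variant names for the three contours of one patient
VARIANT_NAMES = ("GTV_3D", "GTV_PET-ref", "GTV_PET-reg")
#: the three pairwise comparisons, in conventional reporting order
PAIR_NAMES = (
    ("GTV_PET-reg", "GTV_PET-ref"),
    ("GTV_PET-reg", "GTV_3D"),
    ("GTV_PET-ref", "GTV_3D"),
)


class GridMismatchError(ValueError):
    """Two objects that must share a voxel geometry do not."""


class EmptyMaskError(ValueError):
    """An operation requiring a nonempty mask received an empty one."""


def zyx_to_xyz(v) -> np.ndarray:
    """Reverse an axis-ordered triple ``(CC, AP, LR) -> (LR, AP, CC)``."""
    return np.asarray(v, dtype=float)[::-1]


def xyz_to_zyx(v) -> np.ndarray:
    """Reverse a reporting-ordered triple ``(LR, AP, CC) -> (CC, AP, LR)``."""
    return np.asarray(v, dtype=float)[::-1]


@dataclass(frozen=True)
class Grid:
    """Voxel lattice geometry: shape and spacing in ``(CC, AP, LR)`` order."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]  # mm per axis

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or len(self.spacing) != 3:
            raise ValueError("grid shape and spacing must be 3-tuples")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        if any(n <= 0 for n in self.shape):
            raise ValueError(f"non-positive grid shape {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"non-positive voxel spacing {self.spacing}")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        """Physical span from first to last voxel centre, per axis."""
        return tuple((n - 1) * s for n, s in zip(self.shape, self.spacing))

    def axis_centers(self, axis: int) -> np.ndarray:
        """Voxel-centre coordinates (mm) along one array axis."""
        return np.arange(self.shape[axis]) * self.spacing[axis]

    def meshgrid_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable (z, y, x) voxel-centre coordinate arrays in mm."""
        z = self.axis_centers(0)[:, None, None]
        y = self.axis_centers(1)[None, :, None]
        x = self.axis_centers(2)[None, None, :]
        return z, y, x

    def contains_point_zyx(self, p_zyx) -> bool:
        p = np.asarray(p_zyx, dtype=float)
        hi = np.asarray(self.extent_mm)
        return bool(np.all(p >= 0.0) and np.all(p <= hi))


@dataclass
class VoxelVolume:
    """A 3D scalar image (HU or SUV) on a :class:`Grid`."""

    data: np.ndarray
    grid: Grid

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.dtype.kind != "f":
            self.data = self.data.astype(float)
        if self.data.shape != self.grid.shape:
            raise GridMismatchError(
                f"data shape {self.data.shape} != grid shape {self.grid.shape}"
            )

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.grid.spacing


@dataclass
class BinaryMask:
    """One binary structure (a GTV or an organ) on a :class:`Grid`."""

    data: np.ndarray
    grid: Grid

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.shape != self.grid.shape:
            raise GridMismatchError(
                f"mask shape {self.data.shape} != grid shape {self.grid.shape}"
            )

    @property
    def count(self) -> int:
        return int(self.data.sum())

    @property
    def is_empty(self) -> bool:
        return not self.data.any()

    def points_mm(self) -> np.ndarray:
        """(n, 3) physical voxel-centre coordinates of members, (CC, AP, LR) mm."""
        idx = np.argwhere(self.data)
        return idx * np.asarray(self.grid.spacing)

    def copy(self) -> "BinaryMask":
        return BinaryMask(self.data.copy(), self.grid)


def require_same_grid(*objs) -> Grid:
    """Assert all volumes/masks share one geometry; return it."""
    grids = {o.grid for o in objs}
    if len(grids) != 1:
        raise GridMismatchError(f"objects live on {len(grids)} different grids")
    return next(iter(grids))


def resample_mask(mask: BinaryMask, grid: Grid) -> BinaryMask:
    """Map a mask onto a reference geometry by nearest neighbour.

    Each reference voxel centre is looked up at the nearest source voxel
    centre; points outside the source lattice are background.  Nearest
    neighbour preserves binarity, which is why contours are resampled this
    way before comparison.  Identity when ``grid == mask.grid``.
    """
    if grid == mask.grid:
        return mask.copy()
    out = np.zeros(grid.shape, dtype=bool)
    src_sp = np.asarray(mask.grid.spacing)
    centers = [grid.axis_centers(a) for a in range(3)]
    idx = [np.rint(c / src_sp[a]).astype(int) for a, c in enumerate(centers)]
    ok = [(ix >= 0) & (ix < mask.grid.shape[a]) for a, ix in enumerate(idx)]
    iz, iy, ix = np.meshgrid(idx[0], idx[1], idx[2], indexing="ij")
    valid = ok[0][:, None, None] & ok[1][None, :, None] & ok[2][None, None, :]
    iz, iy, ix = (np.clip(a, 0, n - 1) for a, n in zip((iz, iy, ix), mask.grid.shape))
    out[valid] = mask.data[iz, iy, ix][valid]
    return BinaryMask(out, grid)


@dataclass
class GtvSet:
    """The three contour variants of one patient, plus truth when synthetic."""

    gtv_3d: BinaryMask
    gtv_pet_ref: BinaryMask
    gtv_pet_reg: BinaryMask
    truth: BinaryMask | None = None

    def __post_init__(self) -> None:
        masks = [self.gtv_3d, self.gtv_pet_ref, self.gtv_pet_reg]
        if self.truth is not None:
            masks.append(self.truth)
        require_same_grid(*masks)

    def __getitem__(self, name: str) -> BinaryMask:
        return {
            "GTV_3D": self.gtv_3d,
            "GTV_PET-ref": self.gtv_pet_ref,
            "GTV_PET-reg": self.gtv_pet_reg,
        }[name]

    def items(self) -> Iterator[tuple[str, BinaryMask]]:
        for name in VARIANT_NAMES:
            yield name, self[name]

    @property
    def grid(self) -> Grid:
        return self.gtv_3d.grid
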