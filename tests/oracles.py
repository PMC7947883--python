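"""Naive enumeration oracles, independent of the library's code paths.

Every oracle works from the explicit list of member-voxel centres (or a
brute-force sweep over voxel centres) and the textbook formula, so that a
fast implementation can be checked against an unoptimised one.
"""

from __future__ import annotations

import numpy as np


def member_points(mask) -> np.ndarray:
    """(n, 3) voxel-centre coordinates (CC, AP, LR) mm by index enumeration."""
    pts = []
    nz, ny, nx = mask.grid.shape
    dz, dy, dx = mask.grid.spacing
    for i in range(nz):
        for j in range(ny):
            for k in range(nx):
                if mask.data[i, j, k]:
                    pts.append((i * dz, j * dy, k * dx))
    return np.asarray(pts)


def com_oracle(mask) -> np.ndarray:
    """Mean voxel-centre coordinate, returned (LR, AP, CC) mm."""
    pts = member_points(mask)
    return pts.mean(axis=0)[::-1]


def count_cylinder_voxels(shape, grid) -> int:
    """Brute-force centre-in-shape count for an annular cylinder."""
    zc, yc, xc = shape.center_zyx
    n = 0
    for i in range(grid.shape[0]):
        z = i * grid.spacing[0]
        if abs(z - zc) > shape.half_length:
            continue
        for j in range(grid.shape[1]):
            y = j * grid.spacing[1]
            for k in range(grid.shape[2]):
                x = k * grid.spacing[2]
                r = np.hypot(y - yc, x - xc)
                if shape.r_in <= r <= shape.r_out:
                    n += 1
    return n


def overlap_oracle(a, b) -> dict:
    """Set-based intersection/union counts and the derived ratios."""
    sa = {tuple(ix) for ix in np.argwhere(a.data)}
    sb = {tuple(ix) for ix in np.argwhere(b.data)}
    ni = len(sa & sb)
    nu = len(sa | sb)
    return {
        "n_a": len(sa),
        "n_b": len(sb),
        "n_intersection": ni,
        "n_union": nu,
        "ci": ni / nu if nu else float("nan"),
        "di_a_in_b": ni / len(sa) if sa else 0.0,
        "di_b_in_a": ni / len(sb) if sb else 0.0,
        "dice": 2 * ni / (len(sa) + len(sb)) if (sa or sb) else float("nan"),
    }


def hausdorff_oracle(a, b) -> float:
    """O(n*m) max-min over all pairs of member-voxel centres."""
    pa = np.argwhere(a.data) * np.asarray(a.grid.spacing)
    pb = np.argwhere(b.data) * np.asarray(b.grid.spacing)
    d = np.sqrt(((pa[:, None, :] - pb[None, :, :]) ** 2).sum(axis=2))
    return float(max(d.min(axis=1).max(), d.min(axis=0).max()))


def length_oracle_cm(mask) -> float:
    occ = [i for i in range(mask.grid.shape[0]) if mask.data[i].any()]
    return (occ[-1] - occ[0] + 1) * mask.grid.spacing[0] / 10.0


def diameter_oracle_cm(mask) -> float:
    """Max in-plane pairwise distance over slices + one in-plane voxel, cm."""
    dz, dy, dx = mask.grid.spacing
    best = 0.0
    for i in range(mask.grid.shape[0]):
        pts = np.argwhere(mask.data[i]).astype(float) * np.array([dy, dx])
        if len(pts) == 0:
            continue
        diff = pts[:, None, :] - pts[None, :, :]
        best = max(best, float(np.sqrt((diff**2).sum(axis=2)).max()))
    return (best + 0.5 * (dy + dx)) / 10.0


def random_blob_mask(grid, rng, density=0.08):
    """Random nonempty mask: thresholded noise, one voxel guaranteed."""
    from gtvconcord import BinaryMask

    data = rng.random(grid.shape) < density
    if not data.any():
        data[tuple(rng.integers(0, n) for n in grid.shape)] = True
    return BinaryMask(data, grid)


def random_box_mask(grid, rng):
    """Random nonempty axis-aligned box mask."""
    from gtvconcord import BinaryMask

    data = np.zeros(grid.shape, dtype=bool)
    sl = []
    for n in grid.shape:
        a = int(rng.integers(0, n - 1))
        b = int(rng.integers(a + 1, n + 1))
        sl.append(slice(a, b))
    data[tuple(sl)] = True
    return BinaryMask(data, grid)
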