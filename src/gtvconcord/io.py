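"""Reading and writing volumes, masks and cohort manifests.

Volumes and masks travel as NIfTI (``.nii`` / ``.nii.gz``) via nibabel.  On
disk the data axes follow the NIfTI convention ``(LR, AP, CC)`` with voxel
spacing in the header; in memory arrays are ``(CC, AP, LR)`` (see
:mod:`gtvconcord.core`), so the adapters transpose on the way through.
Masks are stored as uint8 {0, 1} and validated strictly on read: any other
value is an error, reported with the offending-voxel count, because a
"binary" file with interpolated values is a sign of an upstream resampling
mistake, not something to silently threshold.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import BinaryMask, Grid, VoxelVolume

__all__ = [
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "write_manifest",
]


class NonBinaryMaskError(ValueError):
    """A file read as a mask contains values other than {0, 1}."""


def _grid_from_header(img) -> Grid:
    zooms = img.header.get_zooms()[:3]
    if any(not np.isfinite(s) or s <= 0 for s in zooms):
        raise ValueError(f"header carries no usable voxel spacing: {zooms}")
    # file axes (LR, AP, CC) -> array axes (CC, AP, LR)
    shape = img.shape[::-1]
    spacing = tuple(float(s) for s in zooms[::-1])
    return Grid(shape, spacing)


def _affine_for(grid: Grid) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = grid.spacing[::-1]
    return aff


def read_volume(path) -> VoxelVolume:
    """Read a scalar NIfTI volume; spacing comes from the header."""
    img = nib.load(str(path))
    grid = _grid_from_header(img)
    data = np.asarray(img.dataobj, dtype=float).transpose(2, 1, 0)
    return VoxelVolume(data, grid)


def write_volume(vol: VoxelVolume, path) -> None:
    img = nib.Nifti1Image(
        vol.data.transpose(2, 1, 0).astype(np.float32), _affine_for(vol.grid)
    )
    img.header.set_zooms(vol.grid.spacing[::-1])
    nib.save(img, str(path))


def read_mask(path) -> BinaryMask:
    """Read a strictly binary NIfTI mask; non-{0,1} values are rejected."""
    img = nib.load(str(path))
    grid = _grid_from_header(img)
    data = np.asarray(img.dataobj, dtype=float).transpose(2, 1, 0)
    offending = int(np.sum(~np.isin(data, (0.0, 1.0))))
    if offending:
        raise NonBinaryMaskError(
            f"{path}: {offending} voxel(s) are neither 0 nor 1"
        )
    return BinaryMask(data.astype(bool), grid)


def write_mask(mask: BinaryMask, path) -> None:
    img = nib.Nifti1Image(
        mask.data.transpose(2, 1, 0).astype(np.uint8), _affine_for(mask.grid)
    )
    img.header.set_zooms(mask.grid.spacing[::-1])
    nib.save(img, str(path))


def write_manifest(patients, path) -> pd.DataFrame:
    """Cohort manifest CSV: one row per patient with applied perturbations."""
    rows = []
    for p in patients:
        row = {
            "patient_id": p.id,
            "group": p.group,
            "tumor_location": p.spec.tumor_location,
            "tumor_suvmax": p.spec.tumor_suvmax,
            "tumor_length_mm": p.spec.tumor_length,
            "tumor_radius_mm": p.spec.tumor_radius,
        }
        for name, pert in p.applied_perturbations.items():
            tag = name.replace("GTV_", "").replace("-", "_").lower()
            row[f"{tag}_shift_lr_mm"] = pert.com_shift[0]
            row[f"{tag}_shift_ap_mm"] = pert.com_shift[1]
            row[f"{tag}_shift_cc_mm"] = pert.com_shift[2]
            row[f"{tag}_length_delta_mm"] = pert.length_delta
            row[f"{tag}_radius_delta_mm"] = pert.radius_delta
            row[f"{tag}_deformation_mm"] = pert.deformation_amplitude
        rows.append(row)
    df = pd.DataFrame(rows)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return df
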