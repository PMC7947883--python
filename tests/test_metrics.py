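"""Concordance metrics against enumeration oracles and exact identities."""

import numpy as np
import pytest

from gtvconcord import (
    BinaryMask,
    EmptyMaskError,
    Grid,
    GridMismatchError,
    GtvSet,
    center_of_mass,
    compare_gtv_set,
    displacement,
    hausdorff,
    overlap,
    resample_mask,
    shape_measures,
)
from oracles import (
    com_oracle,
    diameter_oracle_cm,
    hausdorff_oracle,
    length_oracle_cm,
    random_blob_mask,
)


def _cube(grid, lo, size):
    data = np.zeros(grid.shape, dtype=bool)
    data[lo[0]:lo[0] + size[0], lo[1]:lo[1] + size[1], lo[2]:lo[2] + size[2]] = True
    return BinaryMask(data, grid)


# ---------------------------------------------------------------- COM ----

def test_single_voxel_com_is_its_center():
    g = Grid((6, 6, 6), (3.0, 1.0, 1.5))
    m = BinaryMask(np.zeros(g.shape, dtype=bool), g)
    m.data[2, 3, 4] = True
    assert center_of_mass(m) == pytest.approx([4 * 1.5, 3 * 1.0, 2 * 3.0])


def test_symmetric_cube_com_is_geometric_center(tiny_grid):
    m = _cube(tiny_grid, (2, 3, 4), (4, 4, 4))
    dz, dy, dx = tiny_grid.spacing
    assert center_of_mass(m) == pytest.approx([5.5 * dx, 4.5 * dy, 3.5 * dz])


def test_random_mask_com_matches_enumeration(tiny_grid, rng):
    m = random_blob_mask(tiny_grid, rng, density=0.1)
    assert center_of_mass(m) == pytest.approx(com_oracle(m), abs=1e-12)


def test_com_of_empty_mask_raises(tiny_grid):
    with pytest.raises(EmptyMaskError):
        center_of_mass(BinaryMask(np.zeros(tiny_grid.shape, dtype=bool), tiny_grid))


# ------------------------------------------------------- displacement ----

def test_identical_masks_have_zero_vector(tiny_grid):
    m = _cube(tiny_grid, (1, 1, 1), (3, 3, 3))
    d = displacement(m, m)
    assert (d.dx_lr, d.dy_ap, d.dz_cc, d.vector_v) == (0, 0, 0, 0)


@pytest.mark.parametrize(
    "shift_vox,expected_v",
    [((0, 4, 3), 5.0), ((1, 2, 2), 3.0)],  # (CC, AP, LR) voxels on a 1 mm iso grid
)
def test_pythagorean_translations(shift_vox, expected_v):
    g = Grid((16, 16, 16), (1.0, 1.0, 1.0))
    a = _cube(g, (2, 2, 2), (5, 5, 5))
    b = _cube(g, tuple(2 + s for s in shift_vox), (5, 5, 5))
    assert displacement(b, a).vector_v == pytest.approx(expected_v, abs=1e-12)


def test_grid_mismatch_is_an_error():
    a = _cube(Grid((8, 8, 8), (1, 1, 1)), (1, 1, 1), (2, 2, 2))
    b = _cube(Grid((8, 8, 8), (2, 1, 1)), (1, 1, 1), (2, 2, 2))
    with pytest.raises(GridMismatchError):
        displacement(a, b)


# ------------------------------------------------------------ overlap ----

def test_identical_masks_give_perfect_overlap(tiny_grid):
    m = _cube(tiny_grid, (2, 2, 2), (4, 5, 6))
    rec = overlap(m, m)
    assert rec.ci == 1.0 and rec.di_a_in_b == 1.0 and rec.di_b_in_a == 1.0
    assert rec.dice == 1.0 and rec.hausdorff == 0.0


def test_disjoint_masks_give_zero_overlap(tiny_grid):
    a = _cube(tiny_grid, (0, 0, 0), (2, 2, 2))
    b = _cube(tiny_grid, (6, 6, 6), (2, 2, 2))
    rec = overlap(a, b)
    assert rec.ci == 0.0 and rec.di_a_in_b == 0.0 and rec.di_b_in_a == 0.0


def test_offset_cubes_give_known_fractions():
    g = Grid((20, 20, 20), (1.0, 1.0, 1.0))
    a = _cube(g, (0, 0, 0), (10, 10, 10))
    b = _cube(g, (0, 0, 5), (10, 10, 10))
    rec = overlap(a, b)
    assert rec.vol_intersection == pytest.approx(0.5)   # 500 voxels = 0.5 cm^3
    assert rec.ci == pytest.approx(1 / 3, abs=1e-15)
    assert rec.di_a_in_b == pytest.approx(0.5)
    assert rec.di_b_in_a == pytest.approx(0.5)
    assert rec.dice == pytest.approx(0.5)


def test_one_empty_side_warns_and_zeroes(tiny_grid):
    a = _cube(tiny_grid, (0, 0, 0), (2, 2, 2))
    empty = BinaryMask(np.zeros(tiny_grid.shape, dtype=bool), tiny_grid)
    with pytest.warns(UserWarning):
        rec = overlap(a, empty)
    assert rec.ci == 0.0 and rec.di_b_in_a == 0.0 and np.isnan(rec.hausdorff)
    with pytest.raises(EmptyMaskError):
        overlap(empty, empty)


def test_overlap_identities_on_random_pairs(tiny_grid, rng):
    """CI = Dice/(2-Dice) and CI = 1/(1/DI_ab + 1/DI_ba - 1); symmetry."""
    for _ in range(50):
        a = random_blob_mask(tiny_grid, rng, density=0.15)
        b = random_blob_mask(tiny_grid, rng, density=0.15)
        ab = overlap(a, b)
        ba = overlap(b, a)
        assert ab.ci == ba.ci
        assert ab.di_a_in_b == ba.di_b_in_a
        assert abs(ab.ci - ab.dice / (2 - ab.dice)) < 1e-12
        if ab.di_a_in_b > 0 and ab.di_b_in_a > 0:
            assert abs(ab.ci - 1 / (1 / ab.di_a_in_b + 1 / ab.di_b_in_a - 1)) < 1e-12
        assert ab.ci <= min(ab.di_a_in_b, ab.di_b_in_a) + 1e-15


def test_unnecessary_irradiation_identity(tiny_grid, rng):
    """1 - DI(A in B) equals the voxel fraction of A outside B."""
    a = random_blob_mask(tiny_grid, rng, density=0.2)
    b = random_blob_mask(tiny_grid, rng, density=0.2)
    rec = overlap(a, b)
    outside = int((a.data & ~b.data).sum())
    assert 1.0 - rec.di_a_in_b == pytest.approx(outside / a.count, abs=1e-15)


def test_joint_translation_leaves_overlap_invariant(rng):
    g = Grid((20, 18, 18), (2.0, 1.0, 1.0))
    a = random_blob_mask(Grid((10, 9, 9), g.spacing), rng, density=0.2)
    b = random_blob_mask(Grid((10, 9, 9), g.spacing), rng, density=0.2)
    def shifted(m, off):
        data = np.zeros(g.shape, dtype=bool)
        data[off[0]:off[0] + 10, off[1]:off[1] + 9, off[2]:off[2] + 9] = m.data
        return BinaryMask(data, g)
    r0 = overlap(shifted(a, (0, 0, 0)), shifted(b, (0, 0, 0)))
    r1 = overlap(shifted(a, (5, 4, 3)), shifted(b, (5, 4, 3)))
    assert (r0.ci, r0.di_a_in_b, r0.dice) == (r1.ci, r1.di_a_in_b, r1.dice)
    d0 = displacement(shifted(a, (0, 0, 0)), shifted(b, (0, 0, 0)))
    d1 = displacement(shifted(a, (5, 4, 3)), shifted(b, (5, 4, 3)))
    assert d0.vector_v == pytest.approx(d1.vector_v, abs=1e-9)


# ---------------------------------------------------------- hausdorff ----

def test_two_single_voxels_7mm_apart():
    g = Grid((10, 10, 10), (1.0, 1.0, 1.0))
    a = _cube(g, (1, 1, 1), (1, 1, 1))
    b = _cube(g, (1, 1, 8), (1, 1, 1))
    assert hausdorff(a, b) == pytest.approx(7.0)


def test_hausdorff_matches_pairwise_oracle(tiny_grid, rng):
    for _ in range(10):
        a = random_blob_mask(tiny_grid, rng, density=0.05)
        b = random_blob_mask(tiny_grid, rng, density=0.05)
        assert hausdorff(a, b) == pytest.approx(hausdorff_oracle(a, b), abs=1e-9)


def test_hausdorff_empty_input_raises(tiny_grid):
    a = _cube(tiny_grid, (0, 0, 0), (2, 2, 2))
    empty = BinaryMask(np.zeros(tiny_grid.shape, dtype=bool), tiny_grid)
    with pytest.raises(EmptyMaskError):
        hausdorff(a, empty)


# ------------------------------------------------------------- shapes ----

def test_cube_shape_measures_closed_form():
    g = Grid((20, 20, 20), (1.0, 1.0, 1.0))
    m = _cube(g, (3, 3, 3), (10, 10, 10))
    s = shape_measures(m)
    assert s.volume == pytest.approx(1.0)
    assert s.length == pytest.approx(1.0)
    assert s.max_transverse_diameter == pytest.approx((9 * np.sqrt(2) + 1) / 10)


def test_phantom_cylinder_diameter_near_analytic(small_patient, small_spec):
    s = shape_measures(small_patient.truth_mask)
    expected_cm = 2 * small_spec.tumor_radius / 10.0
    assert abs(s.max_transverse_diameter - expected_cm) <= 0.1 + 1e-9  # one voxel


def test_shape_measures_match_enumeration(tiny_grid, rng):
    m = random_blob_mask(tiny_grid, rng, density=0.1)
    s = shape_measures(m)
    assert s.length == pytest.approx(length_oracle_cm(m), abs=1e-12)
    assert s.max_transverse_diameter == pytest.approx(diameter_oracle_cm(m), abs=1e-9)
    assert s.volume == pytest.approx(m.count * tiny_grid.voxel_volume_mm3 / 1000.0)


# ---------------------------------------------------- compare_gtv_set ----

def test_identical_triplet_gives_unit_everything(tiny_grid):
    m = _cube(tiny_grid, (2, 2, 2), (5, 5, 5))
    rec = compare_gtv_set(GtvSet(m, m.copy(), m.copy()))
    for o in rec.overlaps.values():
        assert o.ci == 1.0 and o.di_a_in_b == 1.0 and o.di_b_in_a == 1.0
    for d in rec.displacements.values():
        assert d.vector_v == 0.0
    assert set(rec.inclusion) == {
        f"{a} in {b}"
        for a, b in [
            ("GTV_PET-reg", "GTV_PET-ref"), ("GTV_PET-ref", "GTV_PET-reg"),
            ("GTV_PET-reg", "GTV_3D"), ("GTV_3D", "GTV_PET-reg"),
            ("GTV_PET-ref", "GTV_3D"), ("GTV_3D", "GTV_PET-ref"),
        ]
    }


def test_compare_gtv_set_is_compositional(tiny_grid, rng):
    a = random_blob_mask(tiny_grid, rng, density=0.2)
    b = random_blob_mask(tiny_grid, rng, density=0.2)
    c = random_blob_mask(tiny_grid, rng, density=0.2)
    rec = compare_gtv_set(GtvSet(a, b, c))
    pair = overlap(c, b)  # GTV_PET-reg and GTV_PET-ref
    assert rec.overlaps["GTV_PET-reg and GTV_PET-ref"] == pair
    assert rec.displacements["GTV_PET-ref and GTV_3D"] == displacement(b, a)
    assert rec.shapes["GTV_3D"] == shape_measures(a)


def test_empty_variant_is_flagged_but_others_computed(tiny_grid):
    m = _cube(tiny_grid, (2, 2, 2), (5, 5, 5))
    empty = BinaryMask(np.zeros(tiny_grid.shape, dtype=bool), tiny_grid)
    rec = compare_gtv_set(GtvSet(m, empty, m.copy()))
    assert "GTV_PET-ref" in rec.flagged
    assert "GTV_PET-reg and GTV_3D" in rec.overlaps
    assert "GTV_PET-reg and GTV_PET-ref" not in rec.overlaps


# ----------------------------------------------------------- resample ----

def test_resample_identity_and_downsample(tiny_grid, rng):
    m = random_blob_mask(tiny_grid, rng, density=0.2)
    assert np.array_equal(resample_mask(m, tiny_grid).data, m.data)
    coarse = Grid((6, 7, 8), (4.0, 2.0, 3.0))
    r = resample_mask(m, coarse)
    assert r.grid == coarse
    # nearest-neighbour: every kept voxel maps back to a member source voxel
    for idx in np.argwhere(r.data):
        src = np.rint(idx * np.array(coarse.spacing) / np.array(tiny_grid.spacing))
        assert m.data[tuple(src.astype(int))]
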