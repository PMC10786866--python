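"""Unit cell, symmetry expansion, map interpolation, and model I/O."""

import gemmi
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from perturbxtal.structure_io import (
    Atom,
    CrystalStructure,
    DensityMap,
    UnitCell,
    cell_volume,
    map_value_at,
    map_values_at,
    read_map,
    read_structure,
    spacegroup_operators,
    symmetry_images,
    write_map,
    write_structure,
)


class TestUnitCell:
    def test_orthorhombic_volume_is_abc(self):
        assert cell_volume(UnitCell(1, 1, 1)) == pytest.approx(1.0)
        assert cell_volume(UnitCell(2, 3, 4)) == pytest.approx(24.0)

    def test_degenerate_angles_raise(self):
        with pytest.raises(ValueError):
            cell_volume(UnitCell(10, 10, 10, 10, 170, 90))

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            UnitCell(-1, 2, 3)
        with pytest.raises(ValueError):
            UnitCell(1, 2, 3, 0, 90, 90)

    def test_triclinic_volume_vs_monte_carlo(self, rng):
        """Rejection-sampling oracle: fraction of a bounding box falling inside
        the parallelepiped spanned by the cell vectors."""
        cell = UnitCell(8.0, 11.0, 9.0, 75.0, 98.0, 112.0)
        M = cell.orthogonalization_matrix
        corners = np.array([M @ np.array(c, dtype=float)
                            for c in np.ndindex(2, 2, 2)])
        lo, hi = corners.min(0), corners.max(0)
        n = 400_000
        pts = rng.uniform(lo, hi, size=(n, 3))
        frac = cell.fractionalize(pts)
        inside = np.all((frac >= 0) & (frac < 1), axis=1)
        box_volume = np.prod(hi - lo)
        mc = box_volume * inside.mean()
        assert cell_volume(cell) == pytest.approx(mc, rel=0.01)

    def test_fractionalization_matches_gemmi(self):
        cell = UnitCell(39.67, 63.51, 135.16, 82.0, 95.5, 101.0)
        g = gemmi.UnitCell(39.67, 63.51, 135.16, 82.0, 95.5, 101.0)
        p = np.array([5.3, -2.1, 40.7])
        f_g = g.fractionalize(gemmi.Position(*p))
        assert cell.fractionalize(p) == pytest.approx(
            [f_g.x, f_g.y, f_g.z], abs=1e-9)
        assert cell.orthogonalize(cell.fractionalize(p)) == pytest.approx(p)

    @given(st.floats(30, 80), st.floats(30, 80), st.floats(30, 160),
           st.floats(0.1, 5.0))
    def test_volume_monotone_in_each_edge(self, a, b, c, delta):
        base = cell_volume(UnitCell(a, b, c, 85, 92, 100))
        assert cell_volume(UnitCell(a + delta, b, c, 85, 92, 100)) > base
        assert cell_volume(UnitCell(a, b + delta, c, 85, 92, 100)) > base
        assert cell_volume(UnitCell(a, b, c + delta, 85, 92, 100)) > base


class TestSymmetryImages:
    def test_identity_shell_zero(self):
        ops = spacegroup_operators("P 1")
        imgs = symmetry_images(np.array([0.1, 0.2, 0.3]), ops, shell=0)
        assert imgs.shape == (1, 3)
        assert imgs[0] == pytest.approx([0.1, 0.2, 0.3])

    def test_p212121_has_four_images(self):
        ops = spacegroup_operators("P 21 21 21")
        assert len(ops) == 4
        imgs = symmetry_images(np.array([0.1, 0.2, 0.3]), ops, shell=0)
        assert imgs.shape == (4, 3)
        imgs1 = symmetry_images(np.array([0.1, 0.2, 0.3]), ops, shell=1)
        assert imgs1.shape == (4 * 27, 3)

    def test_image_set_closed_under_group(self):
        """Applying any operator to the wrapped image set permutes it."""
        ops = spacegroup_operators("P 21 21 21")
        p = np.array([0.137, 0.411, 0.689])
        wrapped = {tuple(np.round(x % 1.0, 9)) for x in symmetry_images(p, ops, 1)}
        for op in ops:
            mapped = {tuple(np.round((op.apply(np.array(x))) % 1.0, 9))
                      for x in wrapped}
            assert mapped == wrapped

    def test_images_preserve_distance_multiset(self, rng):
        """Symmetry operators are isometries of the crystal frame."""
        cell = UnitCell(31.0, 37.0, 43.0)
        ops = spacegroup_operators("P 21 21 21")
        pts = rng.uniform(0.2, 0.4, size=(6, 3))

        def dist_multiset(frac):
            orth = cell.orthogonalize(frac)
            d = np.linalg.norm(orth[:, None] - orth[None, :], axis=-1)
            return np.sort(d[np.triu_indices(len(frac), 1)])

        ref = dist_multiset(pts)
        for op in ops:
            assert dist_multiset(pts @ op.rot.T + op.tran) == pytest.approx(ref)


class TestMapInterpolation:
    def test_constant_map_raw_anywhere(self):
        m = DensityMap(np.full((4, 5, 6), 2.5), UnitCell(10, 10, 10))
        assert m.is_constant
        assert map_value_at(m, np.array([3.3, 7.7, 0.1]), scale="raw") == pytest.approx(2.5)
        with pytest.raises(ValueError):
            map_value_at(m, np.zeros(3), scale="sigma")

    def test_linear_ramp_reproduced_exactly(self):
        """Trilinear interpolation is exact for per-axis linear fields."""
        n = 10
        cell = UnitCell(n * 1.0, 10, 10)
        data = np.broadcast_to(np.arange(n, dtype=float)[:, None, None],
                               (n, 8, 8)).copy()
        m = DensityMap(data, cell)
        for x in [0.5, 1.25, 3.7, 8.999]:
            got = map_value_at(m, np.array([x, 2.0, 3.0]), scale="raw")
            assert got == pytest.approx(x, abs=1e-5)

    def test_matches_eight_corner_weighted_sum(self, rng):
        """Independent direct-formula oracle for trilinear interpolation."""
        shape = (7, 9, 11)
        cell = UnitCell(13.0, 17.0, 23.0)
        data = rng.normal(size=shape)
        m = DensityMap(data, cell)
        for _ in range(50):
            p = rng.uniform(-30, 30, size=3)
            f = cell.fractionalize(p) % 1.0
            g = f * shape
            i0 = np.floor(g).astype(int)
            w = g - i0
            expected = 0.0
            for dx in (0, 1):
                for dy in (0, 1):
                    for dz in (0, 1):
                        wt = ((w[0] if dx else 1 - w[0])
                              * (w[1] if dy else 1 - w[1])
                              * (w[2] if dz else 1 - w[2]))
                        idx = ((i0[0] + dx) % shape[0], (i0[1] + dy) % shape[1],
                               (i0[2] + dz) % shape[2])
                        expected += wt * data[idx]
            got = map_value_at(m, p, scale="raw")
            assert got == pytest.approx(expected, abs=1e-6)

    def test_periodicity_under_lattice_translation(self, rng):
        cell = UnitCell(13.0, 17.0, 23.0)
        m = DensityMap(rng.normal(size=(8, 8, 8)), cell)
        p = rng.uniform(0, 10, size=3)
        shift = cell.orthogonalize(np.array([2.0, -1.0, 3.0]))
        v0 = map_value_at(m, p, scale="sigma")
        v1 = map_value_at(m, p + shift, scale="sigma")
        assert abs(v0 - v1) < 1e-6

    def test_tricubic_mode_available(self, rng):
        cell = UnitCell(10, 10, 10)
        m = DensityMap(rng.normal(size=(12, 12, 12)), cell)
        v = map_value_at(m, np.array([1.0, 2.0, 3.0]), mode="tricubic", scale="raw")
        assert np.isfinite(v)
        with pytest.raises(ValueError):
            map_value_at(m, np.zeros(3), mode="nearest")


class TestModelIO:
    def test_round_trip_preserves_model(self, toy, tmp_path):
        path = tmp_path / "toy.pdb"
        write_structure(toy, path)
        back = read_structure(path, fmt="pdb")
        assert len(back.atoms) == len(toy.atoms)
        assert back.cell.a == pytest.approx(toy.cell.a, abs=1e-3)
        assert len(back.waters()) == len(toy.waters())
        assert back.spacegroup == "P 21 21 21"
        for a, b in zip(toy.atoms, back.atoms):
            assert np.linalg.norm(a.pos - b.pos) < 1e-3
            assert (a.name, a.resname, a.resseq) == (b.name, b.resname, b.resseq)

    def test_water_count_matches_independent_text_scan(self, toy, tmp_path):
        path = tmp_path / "toy.pdb"
        write_structure(toy, path)
        n_hoh = sum(1 for line in open(path)
                    if line.startswith(("ATOM", "HETATM")) and line[17:20] == "HOH")
        assert len(read_structure(path).waters()) == n_hoh

    def test_missing_cell_rejected(self, tmp_path):
        path = tmp_path / "nocell.pdb"
        path.write_text(
            "ATOM      1  CA  ALA A   1      11.000  12.000  13.000"
            "  1.00 20.00           C\nEND\n")
        with pytest.raises(ValueError, match="cell"):
            read_structure(path, fmt="pdb")

    def test_unparseable_file_raises(self, tmp_path):
        path = tmp_path / "junk.cif"
        path.write_text("this is not a structure\n")
        with pytest.raises(ValueError):
            read_structure(path, fmt="mmcif")

    def test_overfull_altloc_occupancy_warns_but_loads(self):
        atoms = [
            Atom("C", "CA", "A", 0.7, 10.0, np.zeros(3), "A", 1, "", "ALA", "polymer"),
            Atom("C", "CA", "B", 0.5, 10.0, np.ones(3), "A", 1, "", "ALA", "polymer"),
        ]
        st = CrystalStructure("over", atoms, UnitCell(20, 20, 20))
        st.validate_altloc_occupancy()
        assert any("occupancy sum" in w for w in st.warnings)

    def test_map_round_trip(self, toy_map, tmp_path):
        path = tmp_path / "toy.ccp4"
        write_map(toy_map, path)
        back = read_map(path)
        assert back.data.shape == toy_map.data.shape
        assert back.cell.a == pytest.approx(toy_map.cell.a, abs=1e-3)
        assert np.allclose(back.data, toy_map.data, atol=1e-5 * toy_map.rms)
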