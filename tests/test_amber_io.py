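"""AMBER-format reader/writer behaviour: prmtop, inpcrd, MOL2, frcmod."""

import math
import warnings

import numpy as np
import pytest

from topoconv import constants as C
from topoconv.amber_io import (
    parameter_source_from_text,
    read_frcmod,
    read_inpcrd,
    read_mol2,
    read_prmtop,
    write_frcmod,
    write_inpcrd,
    write_prmtop,
)
from topoconv.errors import ParseError, StructuralError
from topoconv.model import BoxSpec, ParameterSource


def _systems_equal(a, b, rel=1e-6):
    """Term-set equality: prmtop groups hydrogen-containing terms first, so
    ordering is canonicalised by atom tuple before comparing."""
    key = lambda t: t.atoms
    a = type(a)(**{**a.__dict__,
                   "bonds": sorted(a.bonds, key=key),
                   "angles": sorted(a.angles, key=key),
                   "torsions": sorted(a.torsions, key=lambda t: (t.kind, t.atoms, t.periodicity))})
    b = type(b)(**{**b.__dict__,
                   "bonds": sorted(b.bonds, key=key),
                   "angles": sorted(b.angles, key=key),
                   "torsions": sorted(b.torsions, key=lambda t: (t.kind, t.atoms, t.periodicity))})
    assert a.n_atoms == b.n_atoms
    for x, y in zip(a.atoms, b.atoms):
        assert (x.index, x.name, x.amber_type, x.element) == (
            y.index, y.name, y.amber_type, y.element)
        assert x.partial_charge == pytest.approx(y.partial_charge, rel=rel, abs=1e-9)
        assert x.mass == pytest.approx(y.mass, rel=rel)
    assert len(a.bonds) == len(b.bonds)
    for x, y in zip(a.bonds, b.bonds):
        assert x.atoms == y.atoms
        assert x.force_k == pytest.approx(y.force_k, rel=rel)
        assert x.r_eq == pytest.approx(y.r_eq, rel=rel)
    assert len(a.angles) == len(b.angles)
    for x, y in zip(a.angles, b.angles):
        assert x.atoms == y.atoms
        assert x.force_k == pytest.approx(y.force_k, rel=rel)
        assert x.theta_eq == pytest.approx(y.theta_eq, rel=rel)
    assert len(a.torsions) == len(b.torsions)
    for x, y in zip(a.torsions, b.torsions):
        assert (x.atoms, x.periodicity, x.kind, x.generates_14) == (
            y.atoms, y.periodicity, y.kind, y.generates_14)
        assert x.barrier_half == pytest.approx(y.barrier_half, rel=rel)
        assert x.phase == pytest.approx(y.phase, rel=rel, abs=1e-9)
    assert {t.type_name for t in a.lj_types} == {t.type_name for t in b.lj_types}
    for lt in a.lj_types:
        other = next(t for t in b.lj_types if t.type_name == lt.type_name)
        assert lt.A == pytest.approx(other.A, rel=rel)
        assert lt.B == pytest.approx(other.B, rel=rel)
    assert a.exclusions == b.exclusions


class TestPrmtop:
    def test_charge_unit_conversion(self):
        # the stored value is e * 18.2223; 18.2223^2 is the Coulomb constant
        assert -15.190727 / C.AMBER_ELECTROSTATIC == pytest.approx(-0.8336, abs=1e-4)
        assert C.AMBER_ELECTROSTATIC**2 == pytest.approx(C.COULOMB_KCAL, rel=1e-6)

    def test_water_fixture_read(self, tmp_path, toy_systems):
        _, texts = toy_systems["water_tip3p"]
        p = tmp_path / "w.prmtop"
        p.write_text(texts["prmtop"])
        system = read_prmtop(p)
        assert system.n_atoms == 3
        assert len(system.bonds) == 2
        assert system.net_charge == 0

    @pytest.mark.parametrize("name", ["water_tip3p", "methane", "chain4", "ring6"])
    def test_round_trip(self, tmp_path, toy_systems, name):
        """read -> write -> read is the identity within float tolerance."""
        system, texts = toy_systems[name]
        p1 = tmp_path / "a.prmtop"
        p1.write_text(texts["prmtop"])
        first = read_prmtop(p1)
        p2 = tmp_path / "b.prmtop"
        p2.write_text(write_prmtop(first))
        second = read_prmtop(p2)
        _systems_equal(first, second)
        _systems_equal(system, second, rel=1e-6)

    def test_missing_flag_is_named(self, tmp_path, toy_systems):
        _, texts = toy_systems["methane"]
        broken = texts["prmtop"].replace("%FLAG CHARGE", "%FLAG CHARGE_RENAMED")
        p = tmp_path / "x.prmtop"
        p.write_text(broken)
        with pytest.raises(ParseError, match="CHARGE"):
            read_prmtop(p)

    def test_pointer_array_mismatch(self, tmp_path, toy_systems):
        """NATOM inconsistent with the CHARGE block length is structural."""
        _, texts = toy_systems["methane"]
        lines = texts["prmtop"].splitlines()
        i = lines.index("%FLAG CHARGE") + 2
        lines[i] = "  " + "  ".join(lines[i].split()[:-1])  # drop one value
        p = tmp_path / "x.prmtop"
        p.write_text("\n".join(lines))
        with pytest.raises(StructuralError, match="CHARGE"):
            read_prmtop(p)

    def test_write_refuses_charge_sum_mismatch(self, methane):
        import copy

        bad = copy.deepcopy(methane)
        bad.atoms[0].partial_charge += 0.5
        with pytest.raises(StructuralError):
            write_prmtop(bad)

    def test_write_refuses_missing_lj(self, methane):
        import copy

        bad = copy.deepcopy(methane)
        bad.lj_types = []
        with pytest.raises(StructuralError, match="LJ"):
            write_prmtop(bad)

    def test_zero_torsion_system_valid(self, tmp_path, methane):
        text = write_prmtop(methane)
        p = tmp_path / "m.prmtop"
        p.write_text(text)
        assert read_prmtop(p).torsions == []


class TestInpcrd:
    def test_no_box(self, tmp_path, toy_systems):
        _, texts = toy_systems["water_tip3p"]
        p = tmp_path / "w.inpcrd"
        p.write_text(texts["inpcrd"])
        coords, box = read_inpcrd(p)
        assert coords.shape == (3, 3)
        assert box.kind == "none"

    def test_truncated_octahedron_classification(self, tmp_path):
        coords = np.zeros((1, 3))
        text = write_inpcrd(
            coords, BoxSpec("triclinic", (20.0, 20.0, 20.0),
                            (109.471219, 109.471219, 109.471219))
        )
        p = tmp_path / "b.inpcrd"
        p.write_text(text)
        _, box = read_inpcrd(p, has_box=True)
        assert box.kind == "truncated_octahedron"
        assert box.lengths == (20.0, 20.0, 20.0)

    def test_orthorhombic_classification(self, tmp_path):
        p = tmp_path / "b.inpcrd"
        p.write_text(write_inpcrd(np.zeros((1, 3)),
                                  BoxSpec("orthorhombic", (10.0, 12.0, 14.0),
                                          (90.0, 90.0, 90.0))))
        _, box = read_inpcrd(p, has_box=True)
        assert box.kind == "orthorhombic"

    def test_count_mismatch(self, tmp_path):
        p = tmp_path / "b.inpcrd"
        p.write_text("title\n    3\n  1.0 2.0 3.0 4.0\n")
        with pytest.raises(StructuralError):
            read_inpcrd(p)

    def test_non_numeric_field_names_line(self, tmp_path):
        p = tmp_path / "b.inpcrd"
        p.write_text("title\n    1\n  1.0 oops 3.0\n")
        with pytest.raises(ParseError, match="line 3"):
            read_inpcrd(p)


class TestMol2:
    def test_methane_fixture(self, tmp_path, toy_systems):
        _, texts = toy_systems["methane"]
        p = tmp_path / "m.mol2"
        p.write_text(texts["mol2"])
        system = read_mol2(p)
        assert system.n_atoms == 5
        assert len(system.bond_orders) == 4
        assert system.net_charge is None
        assert system.atoms[0].partial_charge == pytest.approx(-0.1048)

    def test_zero_charges_allowed(self, tmp_path):
        p = tmp_path / "z.mol2"
        p.write_text(
            "@<TRIPOS>MOLECULE\nzero\n 2 1 1 0 0\nSMALL\nNO_CHARGES\n"
            "@<TRIPOS>ATOM\n"
            " 1 H1 0.0 0.0 0.0 ho 1 MOL 0.0\n"
            " 2 H2 0.7 0.0 0.0 ho 1 MOL 0.0\n"
            "@<TRIPOS>BOND\n 1 1 2 1\n"
        )
        system = read_mol2(p)
        assert all(a.partial_charge == 0.0 for a in system.atoms)

    def test_bond_to_unknown_atom(self, tmp_path):
        p = tmp_path / "bad.mol2"
        p.write_text(
            "@<TRIPOS>MOLECULE\nbad\n 2 1 1 0 0\nSMALL\nNO_CHARGES\n"
            "@<TRIPOS>ATOM\n"
            " 1 H1 0.0 0.0 0.0 ho 1 MOL 0.0\n"
            " 2 H2 0.7 0.0 0.0 ho 1 MOL 0.0\n"
            "@<TRIPOS>BOND\n 1 1 99 1\n"
        )
        with pytest.raises(StructuralError, match="99"):
            read_mol2(p)

    def test_missing_block(self, tmp_path):
        p = tmp_path / "nob.mol2"
        p.write_text("@<TRIPOS>MOLECULE\nx\n 0 0\n")
        with pytest.raises(ParseError, match="ATOM"):
            read_mol2(p)

    def test_duplicate_atom_id(self, tmp_path):
        p = tmp_path / "dup.mol2"
        p.write_text(
            "@<TRIPOS>MOLECULE\nd\n 2 0 1 0 0\nSMALL\nNO_CHARGES\n"
            "@<TRIPOS>ATOM\n"
            " 1 H1 0.0 0.0 0.0 ho 1 MOL 0.0\n"
            " 1 H2 0.7 0.0 0.0 ho 1 MOL 0.0\n"
            "@<TRIPOS>BOND\n"
        )
        with pytest.raises(StructuralError, match="duplicate"):
            read_mol2(p)


class TestFrcmod:
    def test_continuation_folds_into_series(self):
        src = parameter_source_from_text(
            "title\n\nDIHE\n"
            "X -c3-c3-X    9     1.400      0.000   -2.0\n"
            "X -c3-c3-X    9     0.500    180.000    3.0\n"
        )
        key = ParameterSource.torsion_key("X", "c3", "c3", "X")
        series = src.torsion_table[key]
        assert len(series) == 2
        assert series[0][0] == pytest.approx(1.4 / 9)
        assert series[1][2] == 3

    def test_dangling_negative_periodicity(self):
        with pytest.raises(StructuralError, match="negative periodicity"):
            parameter_source_from_text(
                "title\n\nDIHE\nX -c3-c3-X   1   1.4   0.0   -2.0\n"
            )

    def test_empty_file_valid(self, tmp_path):
        p = tmp_path / "empty.frcmod"
        p.write_text("")
        src = read_frcmod(p)
        assert not src.bond_table and not src.torsion_table

    def test_duplicate_bond_last_wins_with_warning(self):
        with pytest.warns(UserWarning, match="last entry wins"):
            src = parameter_source_from_text(
                "title\n\nBOND\nc3-hc  300.0  1.10\nc3-hc  337.3  1.093\n"
            )
        assert src.bond_table[("c3", "hc")] == pytest.approx((337.3, 1.093))

    def test_round_trip_identity(self, tmp_path):
        text = (
            "toy\n\nMASS\nc3 12.01\nho 1.008\n\nBOND\nc3-c3  303.1  1.535\n\n"
            "ANGLE\nc3-c3-c3  63.21  110.63\n\nDIHE\n"
            "X -c3-c3-X   1   0.156    0.0   -3.0\n"
            "X -c3-c3-X   1   0.200  180.0    2.0\n\n"
            "IMPROPER\nX -X -c -o   1.1  180.0  2.0\n\n"
            "NONBON\n  c3  1.9080  0.1094\n  ho  0.0  0.0\n"
        )
        first = parameter_source_from_text(text)
        p = tmp_path / "rt.frcmod"
        p.write_text(write_frcmod(first))
        second = read_frcmod(p)
        assert set(first.bond_table) == set(second.bond_table)
        assert set(first.torsion_table) == set(second.torsion_table)
        for key in first.torsion_table:
            for (a, b) in zip(first.torsion_table[key], second.torsion_table[key]):
                assert a[0] == pytest.approx(b[0], rel=1e-6)
                assert a[1] == pytest.approx(b[1], abs=1e-9)
                assert a[2] == b[2]
        assert set(first.improper_table) == set(second.improper_table)
        for t in first.lj_table:
            assert second.lj_table[t] == pytest.approx(first.lj_table[t], abs=1e-9)

    def test_unknown_section(self):
        with pytest.raises(ParseError, match="section"):
            parameter_source_from_text("title\nGARBAGE LINE HERE 1.0 2.0\n")

    def test_parm_dat_dialect(self, tmp_path):
        text = (
            "toy parm set\n"
            "c3 12.01\nho 1.008\n"
            "\n"
            "C  H  HO\n"
            "\n"
            "c3-c3  303.1  1.535\n"
            "\n"
            "c3-c3-c3  63.21  110.63\n"
            "\n"
            "X -c3-c3-X   1   0.156    0.0   3.0\n"
            "\n"
            "X -X -c -o   1.1  180.0  2.0\n"
            "\n"
            "HW OW  0.0  0.0\n"
            "\n"
            "c3  c3\n"
            "\n"
            "MOD4  RE\n"
            "c3  1.9080  0.1094\n"
            "\n"
            "END\n"
        )
        p = tmp_path / "toy.dat"
        p.write_text(text)
        src = read_frcmod(p, dialect="parm_dat")
        assert ("c3", "c3") in src.bond_table
        assert ("c3", "c3", "c3") in src.angle_table
        assert ParameterSource.torsion_key("X", "c3", "c3", "X") in src.torsion_table
        assert src.lj_table["c3"] == pytest.approx((1.908, 0.1094))
        assert src.mass_table["c3"][0] == pytest.approx(12.01)
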