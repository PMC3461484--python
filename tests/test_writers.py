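"""Engine writers: GROMACS top/gro, CNS, CHARMM, and their validators."""

import copy
import math

import numpy as np
import pytest

from topoconv import constants as C
from topoconv.charmm import RMIN_HALF_PER_SIGMA_NM, validate_charmm, write_charmm
from topoconv.cns import validate_cns, write_cns
from topoconv.errors import StructuralError
from topoconv.gromacs import (
    GromacsSettings,
    read_gro,
    read_gromacs_top,
    write_gro,
    write_gromacs_top,
)
from topoconv.model import AtomRecord, BoxSpec, LJType, MolecularSystem, TorsionTerm
from topoconv.params import convert_box, sigma_eps_to_ab


def _dihedral_lines(top_text, funct):
    lines = []
    section = None
    for raw in top_text.splitlines():
        line = raw.split(";")[0].strip()
        if not line:
            continue
        if line.startswith("["):
            section = line.strip("[] ").lower()
            continue
        if section == "dihedrals" and int(line.split()[4]) == funct:
            lines.append(line.split())
    return lines


def _section_lines(top_text, name):
    lines, section = [], None
    for raw in top_text.splitlines():
        line = raw.split(";")[0].strip()
        if not line:
            continue
        if line.startswith("["):
            section = line.strip("[] ").lower()
            continue
        if section == name:
            lines.append(line)
    return lines


class TestGromacsTop:
    def test_defaults_directive(self, chain4):
        line = _section_lines(write_gromacs_top(chain4), "defaults")[0].split()
        assert line[0] == "1" and line[1] == "2" and line[2] == "yes"
        assert float(line[3]) == pytest.approx(0.5)
        assert float(line[4]) == pytest.approx(1.0 / 1.2, rel=1e-6)

    def test_chain4_single_pair_single_dihedral(self, chain4):
        top = write_gromacs_top(chain4)
        assert len(_section_lines(top, "pairs")) == 1
        assert len(_dihedral_lines(top, 9)) == 1

    def test_multi_component_quartet_never_combined(self, ring6):
        top = write_gromacs_top(ring6)
        f9 = _dihedral_lines(top, 9)
        assert len(f9) == 12  # 6 quartets x 2 Fourier components
        quartets = {tuple(l[:4]) for l in f9}
        assert len(quartets) == 6

    def test_impropers_emitted_as_function_4(self):
        from topoconv.fixtures import formaldehyde

        top = write_gromacs_top(formaldehyde())
        assert len(_dihedral_lines(top, 4)) == 1

    def test_type_prefix_and_collision(self, methane):
        top = write_gromacs_top(methane, GromacsSettings(type_prefix="q"))
        assert any(l.split()[0] == "qc3" for l in _section_lines(top, "atomtypes"))

    def test_writer_is_pure(self, ring6):
        assert write_gromacs_top(ring6) == write_gromacs_top(ring6)

    def test_round_trip_reader(self, chain4):
        gtop = read_gromacs_top(write_gromacs_top(chain4))
        assert gtop.n_atoms == 4
        assert gtop.pairs == [(1, 4)]
        assert gtop.fudge_lj == pytest.approx(0.5)
        # exclusions regenerated out to nrexcl=3 bonds
        assert gtop.exclusions[0] == [2, 3, 4]

    def test_unparameterised_system_refused(self, methane):
        bare = copy.deepcopy(methane)
        bare.lj_types = []
        with pytest.raises(StructuralError):
            write_gromacs_top(bare)


class TestGro:
    def test_atoms_at_origin(self, water):
        system = copy.deepcopy(water)
        system.coordinates = np.zeros((3, 3))
        text = write_gro(system)
        atom_lines = text.splitlines()[2:5]
        for line in atom_lines:
            assert [float(line[20:28]), float(line[28:36]), float(line[36:44])] == [
                0.0, 0.0, 0.0,
            ]

    def test_octahedron_box_line(self, water):
        box = BoxSpec.from_lengths_angles(
            (20.0, 20.0, 20.0), (109.471219, 109.471219, 109.471219)
        )
        vectors = convert_box(box)
        text = write_gro(water, box_vectors=vectors)
        fields = [float(x) for x in text.splitlines()[-1].split()]
        assert len(fields) == 9
        # v1y v1z and v2x order: gromacs puts diagonals first
        assert fields[0] == pytest.approx(2.0, abs=1e-5)
        assert fields[5] == pytest.approx(-2.0 / 3.0, abs=1e-5)  # v2x
        assert fields[7] == pytest.approx(-2.0 / 3.0, abs=1e-5)  # v3x
        assert fields[8] < 0  # v3y
        coords, box_read = read_gro(text)
        assert box_read == pytest.approx(np.array(vectors), abs=1e-5)
        assert coords == pytest.approx(water.coordinates, abs=1e-2)

    def test_large_atom_numbering_wraps(self):
        n = 100001
        atoms = [AtomRecord(i, "C", "c3", 0.0, 12.01, "C") for i in range(1, n + 1)]
        system = MolecularSystem(
            atoms=atoms,
            coordinates=np.zeros((n, 3)),
            lj_types=[LJType("c3", 1.0, 1.0)],
        )
        text = write_gro(system)
        last_atom_line = text.splitlines()[1 + n]
        assert int(last_atom_line[15:20]) == n % 100000


class TestCNS:
    def test_uppercase_atom_names(self, chain4):
        system = copy.deepcopy(chain4)
        system.atoms[0].name = "Br1"  # mixed case breaks CNS
        top, _par, _inp = write_cns(system)
        assert " BR1 " in top or "BR1" in top
        assert "Br1" not in top

    def test_chain4_bond_statements_and_dedup(self, chain4):
        top, par, _inp = write_cns(chain4)
        assert sum(1 for l in top.splitlines() if l.strip().startswith("BOND")) == 3
        # two distinct bond type keys: HO-OH and OH-OH
        assert sum(1 for l in par.splitlines() if l.startswith("BOND")) == 2

    def test_grammar_validator_accepts_emitted_text(self, toy_systems):
        for name in ("water_tip3p", "methane", "chain4", "ring6"):
            system, _ = toy_systems[name]
            top, par, _inp = write_cns(system)
            assert validate_cns(top, par) == []

    def test_grammar_validator_catches_garbage(self, chain4):
        top, par, _inp = write_cns(chain4)
        assert validate_cns(top + "\nthis is not CNS\n", par)

    def test_conflicting_duplicate_parameters_refused(self, chain4):
        system = copy.deepcopy(chain4)
        system.bonds[0].force_k *= 2.0  # same HO-OH type key, different value
        with pytest.raises(StructuralError, match="conflicting"):
            write_cns(system)


class TestCHARMM:
    def test_rmin_half_conversion(self):
        # sigma 0.1 nm -> Rmin/2 = 2^(1/6)/2 A x 10
        assert 0.1 * RMIN_HALF_PER_SIGMA_NM == pytest.approx(0.5612, abs=1e-4)

    def test_resi_charge_is_net_charge(self, chain4):
        rtf, _prm = write_charmm(chain4)
        resi = next(l for l in rtf.splitlines() if l.startswith("RESI"))
        assert float(resi.split()[2]) == float(chain4.net_charge)

    def test_mass_records_unique(self, ring6):
        rtf, _prm = write_charmm(ring6)
        masses = [l.split()[2] for l in rtf.splitlines() if l.startswith("MASS")]
        assert len(masses) == len(set(masses))

    def test_nonbonded_negative_epsilon(self, methane):
        _rtf, prm = write_charmm(methane)
        section = prm.splitlines()
        start = section.index("NONBONDED")
        for line in section[start + 1:]:
            if not line.strip() or line == "END":
                break
            assert float(line.split()[2]) <= 0.0

    def test_grammar_validator_accepts_emitted_text(self, toy_systems):
        for name in ("water_tip3p", "methane", "chain4", "ring6"):
            system, _ = toy_systems[name]
            rtf, prm = write_charmm(system)
            assert validate_charmm(rtf, prm) == []

    def test_writers_are_pure(self, chain4):
        assert write_charmm(chain4) == write_charmm(chain4)
        assert write_cns(chain4) == write_cns(chain4)
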