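"""GROMACS topology (.top) and coordinate (.gro) emission and re-parsing.

The writer emits AMBER-family defaults (nonbonded function 1, combination
rule 2 = sigma/epsilon Lorentz-Berthelot, pair generation on, LJ 1-4 scale
0.5, Coulomb 1-4 scale 1/1.2), proper dihedrals as function-9 lines (one
line per Fourier component, never combined) and impropers as function-4
periodic lines, preserving the AMBER analytic torsion form.

The reader parses exactly the dialect the writer emits (plus RB
function-3 dihedrals) back into a :class:`GromacsTopology` so the energy
oracle can certify the round trip without GROMACS installed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import networkx as nx
import numpy as np

from . import constants as C
from .errors import ParseError, StructuralError
from .model import MolecularSystem
from .params import (
    build_pairs_exclusions,
    convert_box,
    convert_harmonic,
    convert_torsion_f9,
    lj_ab_to_sigma_eps,
    recognize_water,
)

PathLike = Union[str, Path]

# 12 significant digits keep the re-parsed energies within 1e-6 relative
# of the source even through the r^-12 LJ amplification.
_F = "%.12g"


@dataclass
class GromacsSettings:
    """Knobs for topology emission.

    ``type_prefix`` is prepended to every molecule-local atom type to avoid
    clashes with force-field-wide GAFF/AMBER type names when the topology
    is included next to a standard force field.
    """

    type_prefix: str = "x"
    fudge_lj: float = C.LJ14_SCALE
    fudge_qq: float = C.COULOMB14_SCALE
    nrexcl: int = 3
    molecule_name: str = "MOL"


def write_gromacs_top(
    system: MolecularSystem,
    settings: Optional[GromacsSettings] = None,
    path: Optional[PathLike] = None,
) -> str:
    """Emit a self-contained GROMACS topology for a parameterised system."""
    s = settings or GromacsSettings()
    _check_ready(system)

    type_names = [lj.type_name for lj in system.lj_types]
    prefixed = {t: f"{s.type_prefix}{t}" for t in type_names}
    if len(set(prefixed.values())) != len(prefixed):
        raise StructuralError(
            f"atom-type name collision after applying prefix {s.type_prefix!r}"
        )

    water = recognize_water(system)
    pairs, _exclusions = build_pairs_exclusions(system)

    out: list[str] = ["; topology written by topoconv"]
    if water:
        out.append(f"; recognised water model: {water}")
    out += [
        "",
        "[ defaults ]",
        "; nbfunc  comb-rule  gen-pairs  fudgeLJ  fudgeQQ",
        f"  1  2  yes  {_F % s.fudge_lj}  {_F % s.fudge_qq}",
        "",
        "[ atomtypes ]",
        ";name  at.num  mass  charge  ptype  sigma  epsilon",
    ]
    from .amber_io import ATOMIC_NUMBERS

    for lj in system.lj_types:
        sigma, eps = lj_ab_to_sigma_eps(lj)
        mass = next(
            (a.mass for a in system.atoms if a.amber_type == lj.type_name), 0.0
        )
        element = next(
            (a.element for a in system.atoms if a.amber_type == lj.type_name), "X"
        )
        out.append(
            f"  {prefixed[lj.type_name]:<6s} {ATOMIC_NUMBERS.get(element, 0):3d} "
            f"{_F % mass}  0.0  A  {_F % sigma}  {_F % eps}"
        )

    out += [
        "",
        "[ moleculetype ]",
        ";name  nrexcl",
        f"  {s.molecule_name}  {s.nrexcl}",
        "",
        "[ atoms ]",
        ";nr  type  resnr  residue  atom  cgnr  charge  mass",
    ]
    for a in system.atoms:
        out.append(
            f"  {a.index:5d}  {prefixed[a.amber_type]:<6s} {a.residue_index:4d}  "
            f"{a.residue_name:<4s} {a.name:<5s} {a.index:5d}  "
            f"{a.partial_charge:.8f}  {_F % a.mass}"
        )

    if system.bonds:
        out += ["", "[ bonds ]", ";ai  aj  funct  b0_nm  kb"]
        for b in system.bonds:
            b0, kb = convert_harmonic(b.force_k, b.r_eq, "bond")
            out.append(
                f"  {b.atoms[0]:5d} {b.atoms[1]:5d}  1  {_F % b0}  {_F % kb}"
            )

    if pairs:
        out += ["", "[ pairs ]", ";ai  aj  funct"]
        for i, j in pairs:
            out.append(f"  {i:5d} {j:5d}  1")

    if system.angles:
        out += ["", "[ angles ]", ";ai  aj  ak  funct  theta0_deg  ktheta"]
        for a in system.angles:
            th0, ka = convert_harmonic(a.force_k, a.theta_eq, "angle")
            out.append(
                f"  {a.atoms[0]:5d} {a.atoms[1]:5d} {a.atoms[2]:5d}  1  "
                f"{_F % th0}  {_F % ka}"
            )

    propers = [t for t in system.torsions if t.kind == "proper"]
    impropers = [t for t in system.torsions if t.kind == "improper"]
    if propers:
        out += ["", "[ dihedrals ]", "; propers, function 9: one line per Fourier component"]
        for t in propers:
            phase_deg, k, n = convert_torsion_f9(t)
            out.append(
                f"  {t.atoms[0]:5d} {t.atoms[1]:5d} {t.atoms[2]:5d} {t.atoms[3]:5d}"
                f"  9  {_F % phase_deg}  {_F % k}  {n}"
            )
    if impropers:
        out += ["", "[ dihedrals ]", "; impropers, periodic function 4 (AMBER analytic form)"]
        for t in impropers:
            phase_deg = math.degrees(t.phase) % 360.0
            k = t.barrier_half * C.KCAL_TO_KJ
            out.append(
                f"  {t.atoms[0]:5d} {t.atoms[1]:5d} {t.atoms[2]:5d} {t.atoms[3]:5d}"
                f"  4  {_F % phase_deg}  {_F % k}  {t.periodicity}"
            )

    out += [
        "",
        "[ system ]",
        f"  {system.title or s.molecule_name}",
        "",
        "[ molecules ]",
        f"  {s.molecule_name}  1",
        "",
    ]
    text = "\n".join(out)
    if path is not None:
        Path(path).write_text(text)
    return text


def _check_ready(system: MolecularSystem) -> None:
    if not system.lj_types:
        raise StructuralError("system is not parameterised: no LJ tables")
    for a in system.atoms:
        system.lj_type_of(a.index)
    system.validate()


# ---------------------------------------------------------------------------
# reader (for the fidelity oracle)
# ---------------------------------------------------------------------------


@dataclass
class GromacsTopology:
    """Parsed GROMACS topology in engine units (nm, kJ/mol, degrees)."""

    atoms: list = field(default_factory=list)  # (name, type, charge, mass, resname, resnr)
    type_lj: dict = field(default_factory=dict)  # type -> (sigma_nm, eps_kJ)
    bonds: list = field(default_factory=list)  # (i, j, b0_nm, kb)
    angles: list = field(default_factory=list)  # (i, j, k, th0_deg, ka)
    dihedrals: list = field(default_factory=list)  # (i, j, k, l, funct, params)
    pairs: list = field(default_factory=list)  # (i, j)
    exclusions: list = field(default_factory=list)  # per-atom sorted lists (1-based)
    fudge_lj: float = C.LJ14_SCALE
    fudge_qq: float = C.COULOMB14_SCALE
    comb_rule: int = 2
    nrexcl: int = 3

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)


def read_gromacs_top(path_or_text: Union[PathLike, str]) -> GromacsTopology:
    """Parse the topology dialect this package writes.

    Supports [defaults], [atomtypes], a single [moleculetype] replicated by
    its [molecules] count, bonds/angles funct 1, dihedral functs 9/4/1/3
    and explicit [pairs]/[exclusions]; exclusions are completed from the
    bond graph out to nrexcl bonds, as GROMACS itself does.
    """
    text = str(path_or_text)
    if "\n" not in text and Path(text).exists():
        text = Path(text).read_text()

    gtop = GromacsTopology()
    section = None
    mol_atoms: list = []
    mol_bonds: list = []
    mol_angles: list = []
    mol_dihedrals: list = []
    mol_pairs: list = []
    mol_exclusions: dict[int, set[int]] = {}
    molecules: list[tuple[str, int]] = []
    mol_name = "MOL"
    n_moltypes = 0

    for raw in text.splitlines():
        line = raw.split(";")[0].strip()
        if not line:
            continue
        if line.startswith("["):
            section = line.strip("[] \t").lower()
            if section == "moleculetype":
                n_moltypes += 1
                if n_moltypes > 1:
                    raise ParseError(
                        "multiple [moleculetype] blocks are not supported by this reader"
                    )
            continue
        f = line.split()
        if section == "defaults":
            if int(f[0]) != 1:
                raise ParseError(f"unsupported nonbonded function {f[0]}")
            gtop.comb_rule = int(f[1])
            if gtop.comb_rule != 2:
                raise ParseError(f"unsupported combination rule {f[1]}")
            if len(f) >= 5:
                gtop.fudge_lj, gtop.fudge_qq = float(f[3]), float(f[4])
        elif section == "atomtypes":
            # name [at.num] mass charge ptype sigma epsilon
            name = f[0]
            try:
                sigma, eps = float(f[-2]), float(f[-1])
            except ValueError as exc:
                raise ParseError(f"bad atomtypes line: {line!r}") from exc
            gtop.type_lj[name] = (sigma, eps)
        elif section == "moleculetype":
            mol_name = f[0]
            gtop.nrexcl = int(f[1])
        elif section == "atoms":
            # nr type resnr residue atom cgnr charge [mass]
            nr = int(f[0])
            if nr != len(mol_atoms) + 1:
                raise StructuralError(f"non-contiguous atom numbering at {line!r}")
            charge = float(f[6]) if len(f) > 6 else 0.0
            mass = float(f[7]) if len(f) > 7 else 0.0
            mol_atoms.append((f[4], f[1], charge, mass, f[3], int(f[2])))
        elif section == "bonds":
            if int(f[2]) != 1:
                raise ParseError(f"unsupported bond funct in {line!r}")
            mol_bonds.append((int(f[0]), int(f[1]), float(f[3]), float(f[4])))
        elif section == "pairs":
            mol_pairs.append((int(f[0]), int(f[1])))
        elif section == "angles":
            if int(f[3]) != 1:
                raise ParseError(f"unsupported angle funct in {line!r}")
            mol_angles.append(
                (int(f[0]), int(f[1]), int(f[2]), float(f[4]), float(f[5]))
            )
        elif section == "dihedrals":
            funct = int(f[4])
            idx = tuple(int(x) for x in f[:4])
            if funct in (9, 4, 1):
                pars = (float(f[5]), float(f[6]), int(f[7]))
            elif funct == 3:
                pars = tuple(float(x) for x in f[5:11])
            else:
                raise ParseError(f"unsupported dihedral funct {funct}")
            mol_dihedrals.append((*idx, funct, pars))
        elif section == "exclusions":
            base = int(f[0])
            mol_exclusions.setdefault(base, set()).update(int(x) for x in f[1:])
        elif section == "molecules":
            molecules.append((f[0], int(f[1])))
        # [system], [settles] and unknown sections are tolerated

    if not mol_atoms:
        raise ParseError("topology has no [atoms] section")
    if not molecules:
        molecules = [(mol_name, 1)]
    total_copies = sum(count for name, count in molecules)
    for name, _count in molecules:
        if name != mol_name:
            raise ParseError(f"[molecules] references unknown moleculetype {name!r}")

    n_local = len(mol_atoms)
    for copy in range(total_copies):
        off = copy * n_local
        gtop.atoms.extend(mol_atoms)
        gtop.bonds.extend((i + off, j + off, b0, kb) for i, j, b0, kb in mol_bonds)
        gtop.angles.extend(
            (i + off, j + off, k + off, t0, ka) for i, j, k, t0, ka in mol_angles
        )
        gtop.dihedrals.extend(
            (i + off, j + off, k + off, l + off, fu, p)
            for i, j, k, l, fu, p in mol_dihedrals
        )
        gtop.pairs.extend((i + off, j + off) for i, j in mol_pairs)

    for name, _lj in ((a[1], None) for a in gtop.atoms):
        if name not in gtop.type_lj:
            raise StructuralError(f"atom type {name!r} missing from [atomtypes]")

    # exclusions: bond-graph distance <= nrexcl, plus explicit ones
    g = nx.Graph()
    g.add_nodes_from(range(1, gtop.n_atoms + 1))
    g.add_edges_from((i, j) for i, j, _b0, _kb in gtop.bonds)
    excl: list[set[int]] = [set() for _ in range(gtop.n_atoms)]
    for i in range(1, gtop.n_atoms + 1):
        for j, d in nx.single_source_shortest_path_length(g, i, cutoff=gtop.nrexcl).items():
            if j != i and d <= gtop.nrexcl:
                excl[i - 1].add(j)
                excl[j - 1].add(i)
    for copy in range(total_copies):
        off = copy * n_local
        for base, others in mol_exclusions.items():
            for j in others:
                excl[base + off - 1].add(j + off)
                excl[j + off - 1].add(base + off)
    gtop.exclusions = [sorted(s) for s in excl]
    return gtop


# ---------------------------------------------------------------------------
# coordinates (.gro)
# ---------------------------------------------------------------------------


def write_gro(
    system: MolecularSystem,
    box_vectors: Optional[np.ndarray] = None,
    clearance: float = C.DEFAULT_CLEARANCE_NM,
    path: Optional[PathLike] = None,
) -> str:
    """Write coordinates as .gro text (positions nm, 3 decimals).

    Atom and residue numbers wrap modulo the 5-character field width.  The
    box line carries the triclinic vector components in GROMACS order
    (v1x v2y v3z v1y v1z v2x v2z v3x v3y); a diagonal box emits 3 values.
    """
    if system.coordinates is None:
        raise StructuralError("cannot write .gro without coordinates")
    if box_vectors is None:
        box_vectors = convert_box(system.box, system.coordinates, clearance)
    out = [system.title or "MOL", "%5d" % system.n_atoms]
    for a, xyz in zip(system.atoms, system.coordinates):
        nm = xyz * C.ANGSTROM_TO_NM
        out.append(
            "%5d%-5s%5s%5d%8.3f%8.3f%8.3f"
            % (
                a.residue_index % 100000,
                a.residue_name[:5],
                a.name[:5],
                a.index % 100000,
                nm[0], nm[1], nm[2],
            )
        )
    v = np.asarray(box_vectors, dtype=float)
    off_diag = [v[0][1], v[0][2], v[1][0], v[1][2], v[2][0], v[2][1]]
    if any(abs(x) > 1e-12 for x in off_diag):
        fields = [v[0][0], v[1][1], v[2][2],
                  v[0][1], v[0][2], v[1][0], v[1][2], v[2][0], v[2][1]]
    else:
        fields = [v[0][0], v[1][1], v[2][2]]
    out.append(" ".join("%10.5f" % x for x in fields))
    text = "\n".join(out) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def read_gro(path_or_text: Union[PathLike, str]) -> tuple[np.ndarray, np.ndarray]:
    """Read a .gro file; returns (coordinates in Angstrom, box vectors in nm)."""
    text = str(path_or_text)
    if "\n" not in text and Path(text).exists():
        text = Path(text).read_text()
    lines = text.splitlines()
    if len(lines) < 3:
        raise ParseError(".gro too short")
    natoms = int(lines[1])
    if len(lines) < natoms + 3:
        raise StructuralError(f".gro declares {natoms} atoms but has too few lines")
    coords = np.zeros((natoms, 3))
    for n in range(natoms):
        line = lines[2 + n]
        try:
            coords[n] = [float(line[20:28]), float(line[28:36]), float(line[36:44])]
        except ValueError as exc:
            raise ParseError(f".gro line {3 + n}: bad coordinate field") from exc
    fields = [float(x) for x in lines[2 + natoms].split()]
    box = np.zeros((3, 3))
    if len(fields) >= 3:
        box[0][0], box[1][1], box[2][2] = fields[:3]
    if len(fields) == 9:
        box[0][1], box[0][2] = fields[3], fields[4]
        box[1][0], box[1][2] = fields[5], fields[6]
        box[2][0], box[2][1] = fields[7], fields[8]
    return coords / C.ANGSTROM_TO_NM, box
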