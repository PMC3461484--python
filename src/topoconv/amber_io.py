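"""Readers and writers for AMBER-side file formats.

Covers the %FLAG/%FORMAT-sectioned prmtop topology, the fixed-width
inpcrd/restart coordinate file, Tripos MOL2, and frcmod / parm-dat
parameter files.  The prmtop parser is native — no AmberTools binaries are
needed for the conversion path.

All parsers accept ASCII text, tolerate trailing whitespace and blank
lines, and raise :class:`~topoconv.errors.ParseError` (malformed text) or
:class:`~topoconv.errors.StructuralError` (inconsistent content).
"""

from __future__ import annotations

import math
import re
import warnings
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .constants import AMBER_ELECTROSTATIC
from .errors import ParseError, StructuralError
from .model import (
    AtomRecord,
    BondTerm,
    AngleTerm,
    BoxSpec,
    LJType,
    MolecularSystem,
    ParameterSource,
    TorsionTerm,
)

PathLike = Union[str, Path]

# Masses for the element range GAFF covers (plus a few common extras), amu.
ELEMENT_MASSES = {
    "H": 1.008, "C": 12.01, "N": 14.01, "O": 16.00, "F": 19.00,
    "P": 30.97, "S": 32.06, "Cl": 35.45, "Br": 79.90, "I": 126.90,
    "Na": 22.99, "K": 39.10, "Mg": 24.305, "Ca": 40.08, "Zn": 65.38,
}
ATOMIC_NUMBERS = {
    "H": 1, "C": 6, "N": 7, "O": 8, "F": 9, "P": 15, "S": 16,
    "Cl": 17, "Br": 35, "I": 53, "Na": 11, "K": 19, "Mg": 12,
    "Ca": 20, "Zn": 30,
}
_NUM_TO_ELEMENT = {v: k for k, v in ATOMIC_NUMBERS.items()}


def element_from_mass(mass: float) -> str:
    """Nearest standard element by mass (within 1 amu), else 'X'."""
    best, best_d = "X", 1.0 + 1e-9
    for el, m in ELEMENT_MASSES.items():
        d = abs(m - mass)
        if d < best_d:
            best, best_d = el, d
    return best


def guess_element(name: str) -> str:
    """Element from an atom name or type string ('Cl1' -> 'Cl', 'ho' -> 'H')."""
    letters = "".join(c for c in name if c.isalpha())
    if not letters:
        return "X"
    two = letters[:2].capitalize()
    if two in ELEMENT_MASSES:
        return two
    one = letters[0].upper()
    return one if one in ELEMENT_MASSES else "X"


def _read_text(path_or_text: PathLike) -> str:
    p = Path(path_or_text)
    return p.read_text()


# ---------------------------------------------------------------------------
# prmtop
# ---------------------------------------------------------------------------

_MANDATORY_FLAGS = [
    "POINTERS", "ATOM_NAME", "CHARGE", "MASS", "ATOM_TYPE_INDEX",
    "NUMBER_EXCLUDED_ATOMS", "NONBONDED_PARM_INDEX", "RESIDUE_LABEL",
    "RESIDUE_POINTER", "BOND_FORCE_CONSTANT", "BOND_EQUIL_VALUE",
    "ANGLE_FORCE_CONSTANT", "ANGLE_EQUIL_VALUE", "DIHEDRAL_FORCE_CONSTANT",
    "DIHEDRAL_PERIODICITY", "DIHEDRAL_PHASE", "LENNARD_JONES_ACOEF",
    "LENNARD_JONES_BCOEF", "BONDS_INC_HYDROGEN", "BONDS_WITHOUT_HYDROGEN",
    "ANGLES_INC_HYDROGEN", "ANGLES_WITHOUT_HYDROGEN",
    "DIHEDRALS_INC_HYDROGEN", "DIHEDRALS_WITHOUT_HYDROGEN",
    "EXCLUDED_ATOMS_LIST", "AMBER_ATOM_TYPE",
]

_FORMAT_RE = re.compile(r"(\d+)\s*([aAiIeEfFgG])\s*(\d+)")


def _parse_prmtop_sections(text: str) -> dict[str, tuple[str, list[str]]]:
    sections: dict[str, tuple[str, list[str]]] = {}
    current: Optional[str] = None
    for line in text.splitlines():
        if line.startswith("%VERSION") or line.startswith("%COMMENT"):
            continue
        if line.startswith("%FLAG"):
            parts = line.split()
            if len(parts) < 2:
                raise ParseError(f"malformed %FLAG line: {line!r}")
            current = parts[1]
            sections[current] = ("", [])
        elif line.startswith("%FORMAT"):
            if current is None:
                raise ParseError("%FORMAT before any %FLAG")
            try:
                fmt = line[line.index("(") + 1 : line.rindex(")")]
            except ValueError as exc:
                raise ParseError(f"malformed %FORMAT line: {line!r}") from exc
            sections[current] = (fmt, sections[current][1])
        elif current is not None:
            sections[current][1].append(line)
    return sections


def _decode_section(fmt: str, lines: list[str]) -> list:
    m = _FORMAT_RE.match(fmt.strip())
    if not m:
        raise ParseError(f"unsupported FORMAT spec {fmt!r}")
    _, kind, width = m.group(1), m.group(2).lower(), int(m.group(3))
    if kind == "a":
        out: list = []
        for line in lines:
            line = line.rstrip("\n")
            for start in range(0, len(line), width):
                chunk = line[start : start + width]
                if chunk.strip() or chunk:
                    out.append(chunk.strip())
        return [s for s in out if s != ""] if out else out
    tokens: list[str] = []
    for line in lines:
        tokens.extend(line.split())
    try:
        if kind == "i":
            return [int(t) for t in tokens]
        return [float(t) for t in tokens]
    except ValueError as exc:
        raise ParseError(f"non-numeric token in {fmt!r} section: {exc}") from exc


def read_prmtop(path: PathLike) -> MolecularSystem:
    """Parse an AMBER prmtop file into a :class:`MolecularSystem`.

    Charges are converted from the prmtop internal unit (e multiplied by
    18.2223, the square root of the Coulomb constant in kcal*A/mol/e^2)
    back to electron charges.  Dihedral index sign flags are decoded into
    proper/improper kinds and 1-4 generation flags; exclusion lists are
    symmetrised.  Coordinates are *not* read (see :func:`read_inpcrd`).
    """
    from .params import classify_torsions, guess_net_charge

    text = _read_text(path)
    sections = _parse_prmtop_sections(text)
    for flag in _MANDATORY_FLAGS:
        if flag not in sections:
            raise ParseError(f"prmtop is missing mandatory %FLAG {flag}")

    def sec(flag: str) -> list:
        fmt, lines = sections[flag]
        return _decode_section(fmt, lines)

    pointers = sec("POINTERS")
    if len(pointers) < 31:
        raise StructuralError(f"POINTERS has {len(pointers)} values, expected >= 31")
    (natom, ntypes, nbonh, _mbona, ntheth, _mtheta, nphih, _mphia, _nhparm,
     _nparm, nnb, nres, nbona, ntheta, nphia, numbnd, numang, nptra, _natyp,
     _nphb) = pointers[:20]
    ifbox = pointers[27]

    charges = sec("CHARGE")
    masses = sec("MASS")
    names = sec("ATOM_NAME")
    type_idx = sec("ATOM_TYPE_INDEX")
    amber_types = sec("AMBER_ATOM_TYPE")
    for label, arr, expect in (
        ("CHARGE", charges, natom), ("MASS", masses, natom),
        ("ATOM_NAME", names, natom), ("ATOM_TYPE_INDEX", type_idx, natom),
        ("AMBER_ATOM_TYPE", amber_types, natom),
    ):
        if len(arr) != expect:
            raise StructuralError(
                f"{label} has {len(arr)} entries but POINTERS declares NATOM={expect}"
            )

    if "ATOMIC_NUMBER" in sections:
        atnums = sec("ATOMIC_NUMBER")
        elements = [_NUM_TO_ELEMENT.get(z, "X") for z in atnums]
    else:
        elements = [element_from_mass(m) for m in masses]

    res_labels = sec("RESIDUE_LABEL")
    res_ptr = sec("RESIDUE_POINTER")
    if len(res_labels) != nres or len(res_ptr) != nres:
        raise StructuralError("residue block lengths inconsistent with NRES")

    res_of_atom = [0] * natom
    for ri in range(nres):
        start = res_ptr[ri] - 1
        end = res_ptr[ri + 1] - 1 if ri + 1 < nres else natom
        for ai in range(start, end):
            res_of_atom[ai] = ri

    atoms = [
        AtomRecord(
            index=i + 1,
            name=names[i],
            amber_type=amber_types[i],
            partial_charge=charges[i] / AMBER_ELECTROSTATIC,
            mass=masses[i],
            element=elements[i],
            residue_name=res_labels[res_of_atom[i]],
            residue_index=res_of_atom[i] + 1,
        )
        for i in range(natom)
    ]

    # bonded parameter type tables
    bond_k = sec("BOND_FORCE_CONSTANT")
    bond_r = sec("BOND_EQUIL_VALUE")
    angle_k = sec("ANGLE_FORCE_CONSTANT")
    angle_t = sec("ANGLE_EQUIL_VALUE")
    dihe_k = sec("DIHEDRAL_FORCE_CONSTANT")
    dihe_n = sec("DIHEDRAL_PERIODICITY")
    dihe_p = sec("DIHEDRAL_PHASE")
    if len(bond_k) != numbnd or len(bond_r) != numbnd:
        raise StructuralError("bond type tables inconsistent with NUMBND")
    if len(angle_k) != numang or len(angle_t) != numang:
        raise StructuralError("angle type tables inconsistent with NUMANG")
    if len(dihe_k) != nptra or len(dihe_n) != nptra or len(dihe_p) != nptra:
        raise StructuralError("dihedral type tables inconsistent with NPTRA")

    def decode_terms(flag: str, width: int, expected: int) -> list[list[int]]:
        arr = sec(flag)
        if len(arr) != width * expected:
            raise StructuralError(
                f"{flag} has {len(arr)} values, expected {width * expected}"
            )
        return [arr[i : i + width] for i in range(0, len(arr), width)]

    bonds: list[BondTerm] = []
    for entry in decode_terms("BONDS_INC_HYDROGEN", 3, nbonh) + decode_terms(
        "BONDS_WITHOUT_HYDROGEN", 3, nbona
    ):
        i, j, t = entry
        bonds.append(
            BondTerm(atoms=(i // 3 + 1, j // 3 + 1), force_k=bond_k[t - 1], r_eq=bond_r[t - 1])
        )

    angles: list[AngleTerm] = []
    for entry in decode_terms("ANGLES_INC_HYDROGEN", 4, ntheth) + decode_terms(
        "ANGLES_WITHOUT_HYDROGEN", 4, ntheta
    ):
        i, j, k, t = entry
        angles.append(
            AngleTerm(
                atoms=(i // 3 + 1, j // 3 + 1, k // 3 + 1),
                force_k=angle_k[t - 1],
                theta_eq=angle_t[t - 1],
            )
        )

    raw_dihedrals = decode_terms("DIHEDRALS_INC_HYDROGEN", 5, nphih) + decode_terms(
        "DIHEDRALS_WITHOUT_HYDROGEN", 5, nphia
    )
    torsions = classify_torsions(raw_dihedrals, dihe_k, dihe_n, dihe_p)

    # Lennard-Jones: keep the per-type diagonal; off-diagonals are
    # regenerated by Lorentz-Berthelot combining on write.
    acoef = sec("LENNARD_JONES_ACOEF")
    bcoef = sec("LENNARD_JONES_BCOEF")
    npairs = ntypes * (ntypes + 1) // 2
    if len(acoef) != npairs or len(bcoef) != npairs:
        raise StructuralError("LJ coefficient tables inconsistent with NTYPES")
    ico = sec("NONBONDED_PARM_INDEX")
    if len(ico) != ntypes * ntypes:
        raise StructuralError("NONBONDED_PARM_INDEX inconsistent with NTYPES")

    # map each distinct amber type to its LJ type index (first atom wins)
    type_name_of_index: dict[int, str] = {}
    for i in range(natom):
        type_name_of_index.setdefault(type_idx[i], amber_types[i])
    lj_types: list[LJType] = []
    seen_names: set[str] = set()
    for ti in sorted(type_name_of_index):
        name = type_name_of_index[ti]
        if name in seen_names:
            continue
        seen_names.add(name)
        diag = ico[ntypes * (ti - 1) + (ti - 1)]
        if diag <= 0:
            raise StructuralError("10-12 hydrogen-bond LJ entries are not supported")
        lj_types.append(LJType(type_name=name, A=acoef[diag - 1], B=bcoef[diag - 1]))

    # exclusions: prmtop lists j > i; zero is an empty-list placeholder
    n_excl = sec("NUMBER_EXCLUDED_ATOMS")
    excl_list = sec("EXCLUDED_ATOMS_LIST")
    if len(n_excl) != natom:
        raise StructuralError("NUMBER_EXCLUDED_ATOMS length != NATOM")
    if len(excl_list) != nnb:
        raise StructuralError("EXCLUDED_ATOMS_LIST length != NNB")
    exclusions: list[set[int]] = [set() for _ in range(natom)]
    pos = 0
    for i in range(natom):
        for j in excl_list[pos : pos + n_excl[i]]:
            if j > 0:
                exclusions[i].add(j)
                exclusions[j - 1].add(i + 1)
        pos += n_excl[i]

    box = BoxSpec()
    if ifbox > 0 and "BOX_DIMENSIONS" in sections:
        beta, bx, by, bz = sec("BOX_DIMENSIONS")[:4]
        box = BoxSpec.from_lengths_angles((bx, by, bz), (beta, beta, beta))

    title = " ".join(sec("TITLE")) if "TITLE" in sections else ""

    system = MolecularSystem(
        title=title,
        atoms=atoms,
        bonds=bonds,
        angles=angles,
        torsions=torsions,
        lj_types=lj_types,
        exclusions=[sorted(s) for s in exclusions],
        box=box,
    )
    system.net_charge = guess_net_charge([a.partial_charge for a in atoms])
    system.validate()
    return system


def _fmt_block(values, fmt: str, per_line: int) -> list[str]:
    if not values:
        return [""]
    lines = []
    for i in range(0, len(values), per_line):
        lines.append("".join(fmt % v for v in values[i : i + per_line]))
    return lines


def _is_h(atom: AtomRecord) -> bool:
    return atom.element == "H"


def write_prmtop(system: MolecularSystem, path: Optional[PathLike] = None) -> str:
    """Serialise a fully parameterised system as prmtop text.

    The emitted file re-reads via :func:`read_prmtop` into an equivalent
    system (floats within 1e-6 relative, integers exact).  Refuses systems
    without LJ tables or with charges inconsistent with the net charge.
    """
    from .params import sigma_eps_to_ab, lj_ab_to_sigma_eps

    if not system.lj_types:
        raise StructuralError("cannot write prmtop: system has no LJ tables")
    system.validate()
    for a in system.atoms:
        system.lj_type_of(a.index)  # raises if an atom type lacks LJ

    natom = system.n_atoms
    type_names = [lj.type_name for lj in system.lj_types]
    ntypes = len(type_names)
    type_index = {name: i + 1 for i, name in enumerate(type_names)}

    # unique bonded parameter tables, preserving first-appearance order
    def unique_table(items):
        table: dict[tuple, int] = {}
        idx = []
        for key in items:
            if key not in table:
                table[key] = len(table) + 1
            idx.append(table[key])
        return list(table), idx

    bond_types, bond_tidx = unique_table((b.force_k, b.r_eq) for b in system.bonds)
    angle_types, angle_tidx = unique_table((a.force_k, a.theta_eq) for a in system.angles)
    dihe_types, dihe_tidx = unique_table(
        (t.barrier_half, float(t.periodicity), t.phase) for t in system.torsions
    )

    atoms = system.atoms

    def encode_dihedral(t: TorsionTerm, tix: int) -> list[int]:
        i, j, k, l = t.atoms
        neg_k = t.kind == "improper" or not t.generates_14
        neg_l = t.kind == "improper"
        if (neg_k and k == 1) or (neg_l and l == 1):
            # atom 1 encodes as 0 and cannot carry a sign flag; the quartet
            # is reversed (energy-invariant for phases 0/pi)
            i, j, k, l = l, k, j, i
        if (neg_k and k == 1) or (neg_l and l == 1):
            raise StructuralError(
                f"cannot encode dihedral {t.atoms}: sign flag on atom 1 in both orders"
            )
        ek = -(3 * (k - 1)) if neg_k else 3 * (k - 1)
        el = -(3 * (l - 1)) if neg_l else 3 * (l - 1)
        return [3 * (i - 1), 3 * (j - 1), ek, el, tix]

    bonds_h, bonds_a = [], []
    for b, tix in zip(system.bonds, bond_tidx):
        i, j = b.atoms
        target = bonds_h if _is_h(atoms[i - 1]) or _is_h(atoms[j - 1]) else bonds_a
        target.append([3 * (i - 1), 3 * (j - 1), tix])
    angles_h, angles_a = [], []
    for a, tix in zip(system.angles, angle_tidx):
        i, j, k = a.atoms
        has_h = any(_is_h(atoms[x - 1]) for x in a.atoms)
        (angles_h if has_h else angles_a).append([3 * (i - 1), 3 * (j - 1), 3 * (k - 1), tix])
    dihe_h, dihe_a = [], []
    for t, tix in zip(system.torsions, dihe_tidx):
        has_h = any(_is_h(atoms[x - 1]) for x in t.atoms)
        (dihe_h if has_h else dihe_a).append(encode_dihedral(t, tix))

    # exclusion blocks (j > i only; 0 placeholder for empty)
    if system.exclusions:
        upper = [sorted(j for j in system.exclusions[i] if j > i + 1) for i in range(natom)]
    else:
        upper = [[] for _ in range(natom)]
    n_excl = [max(1, len(u)) for u in upper]
    excl_flat: list[int] = []
    for u in upper:
        excl_flat.extend(u if u else [0])

    # LJ pair tables via Lorentz-Berthelot combining of the diagonal
    sig_eps = {lj.type_name: lj_ab_to_sigma_eps(lj) for lj in system.lj_types}
    acoef, bcoef = [], []
    pair_index = {}
    count = 0
    for jt in range(1, ntypes + 1):
        for it in range(1, jt + 1):
            count += 1
            pair_index[(it, jt)] = count
            si, ei = sig_eps[type_names[it - 1]]
            sj, ej = sig_eps[type_names[jt - 1]]
            sij, eij = 0.5 * (si + sj), math.sqrt(ei * ej)
            a, b = sigma_eps_to_ab(sij, eij)
            acoef.append(a)
            bcoef.append(b)
    ico = []
    for it in range(1, ntypes + 1):
        for jt in range(1, ntypes + 1):
            lo, hi = min(it, jt), max(it, jt)
            ico.append(pair_index[(lo, hi)])

    nres = max(a.residue_index for a in atoms)
    res_labels, res_ptr = [], []
    for ri in range(1, nres + 1):
        members = [a for a in atoms if a.residue_index == ri]
        if not members:
            raise StructuralError(f"residue index {ri} has no atoms")
        res_labels.append(members[0].residue_name)
        res_ptr.append(min(a.index for a in members))
    nmxrs = max(
        sum(1 for a in atoms if a.residue_index == ri) for ri in range(1, nres + 1)
    )

    ifbox = 0
    if system.box.kind == "truncated_octahedron":
        ifbox = 2
    elif system.box.kind != "none":
        ifbox = 1

    pointers = [
        natom, ntypes, len(bonds_h), len(bonds_a), len(angles_h), len(angles_a),
        len(dihe_h), len(dihe_a), 0, 0, len(excl_flat), nres, len(bonds_a),
        len(angles_a), len(dihe_a), len(bond_types), len(angle_types),
        len(dihe_types), ntypes, 0, 0, 0, 0, 0, 0, 0, 0, ifbox, nmxrs, 0, 0,
    ]

    out: list[str] = ["%VERSION  VERSION_STAMP = V0001.000  DATE = 01/01/00  00:00:00"]

    def emit(flag: str, fmt_label: str, lines: list[str]) -> None:
        out.append(f"%FLAG {flag}")
        out.append(f"%FORMAT({fmt_label})")
        out.extend(lines)

    def emit_str(flag, values):
        emit(flag, "20a4", _fmt_block(values, "%-4s", 20))

    def emit_int(flag, values):
        emit(flag, "10I8", _fmt_block(values, "%8d", 10))

    def emit_flt(flag, values):
        emit(flag, "5E16.8", _fmt_block(values, "%16.8E", 5))

    emit_str("TITLE", [system.title[:76] or "MOL"])
    emit_int("POINTERS", pointers)
    emit_str("ATOM_NAME", [a.name for a in atoms])
    emit_flt("CHARGE", [a.partial_charge * AMBER_ELECTROSTATIC for a in atoms])
    emit_int("ATOMIC_NUMBER", [ATOMIC_NUMBERS.get(a.element, -1) for a in atoms])
    emit_flt("MASS", [a.mass for a in atoms])
    emit_int("ATOM_TYPE_INDEX", [type_index[a.amber_type] for a in atoms])
    emit_int("NUMBER_EXCLUDED_ATOMS", n_excl)
    emit_int("NONBONDED_PARM_INDEX", ico)
    emit_str("RESIDUE_LABEL", res_labels)
    emit_int("RESIDUE_POINTER", res_ptr)
    emit_flt("BOND_FORCE_CONSTANT", [k for k, _ in bond_types])
    emit_flt("BOND_EQUIL_VALUE", [r for _, r in bond_types])
    emit_flt("ANGLE_FORCE_CONSTANT", [k for k, _ in angle_types])
    emit_flt("ANGLE_EQUIL_VALUE", [t for _, t in angle_types])
    emit_flt("DIHEDRAL_FORCE_CONSTANT", [k for k, _, _ in dihe_types])
    emit_flt("DIHEDRAL_PERIODICITY", [n for _, n, _ in dihe_types])
    emit_flt("DIHEDRAL_PHASE", [p for _, _, p in dihe_types])
    emit_flt("SCEE_SCALE_FACTOR", [1.2] * len(dihe_types))
    emit_flt("SCNB_SCALE_FACTOR", [2.0] * len(dihe_types))
    emit_flt("LENNARD_JONES_ACOEF", acoef)
    emit_flt("LENNARD_JONES_BCOEF", bcoef)
    emit_int("BONDS_INC_HYDROGEN", [v for e in bonds_h for v in e])
    emit_int("BONDS_WITHOUT_HYDROGEN", [v for e in bonds_a for v in e])
    emit_int("ANGLES_INC_HYDROGEN", [v for e in angles_h for v in e])
    emit_int("ANGLES_WITHOUT_HYDROGEN", [v for e in angles_a for v in e])
    emit_int("DIHEDRALS_INC_HYDROGEN", [v for e in dihe_h for v in e])
    emit_int("DIHEDRALS_WITHOUT_HYDROGEN", [v for e in dihe_a for v in e])
    emit_int("EXCLUDED_ATOMS_LIST", excl_flat)
    emit_str("AMBER_ATOM_TYPE", [a.amber_type for a in atoms])
    if ifbox > 0 and system.box.lengths is not None:
        beta = system.box.angles[1] if system.box.angles else 90.0
        emit_flt("BOX_DIMENSIONS", [beta, *system.box.lengths])

    text = "\n".join(out) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# inpcrd
# ---------------------------------------------------------------------------


def read_inpcrd(
    path: PathLike, has_box: Optional[bool] = None
) -> tuple[np.ndarray, BoxSpec]:
    """Read a fixed-width AMBER restart/coordinate file.

    Returns coordinates in Angstrom and a classified :class:`BoxSpec`.
    ``has_box=None`` infers the box from the trailing float count; pass an
    explicit boolean to enforce the expectation.
    """
    lines = _read_text(path).splitlines()
    if len(lines) < 2:
        raise ParseError("inpcrd too short: need title and atom-count lines")
    try:
        natom = int(lines[1].split()[0])
    except (IndexError, ValueError) as exc:
        raise ParseError(f"inpcrd line 2: cannot read atom count: {lines[1]!r}") from exc

    values: list[float] = []
    for lineno, line in enumerate(lines[2:], start=3):
        for tok in line.split():
            try:
                values.append(float(tok))
            except ValueError as exc:
                raise ParseError(
                    f"inpcrd line {lineno}: non-numeric field {tok!r}"
                ) from exc

    n_coord = 3 * natom
    if has_box is None:
        has_box = len(values) == n_coord + 6
    expected = n_coord + (6 if has_box else 0)
    if len(values) != expected:
        # a lone velocity section would double the count; reject explicitly
        raise StructuralError(
            f"inpcrd holds {len(values)} floats but header declares {natom} atoms "
            f"({'with' if has_box else 'without'} box: expected {expected})"
        )
    coords = np.array(values[:n_coord], dtype=float).reshape(natom, 3)
    if has_box:
        box = BoxSpec.from_lengths_angles(values[n_coord : n_coord + 3], values[n_coord + 3 :])
    else:
        box = BoxSpec()
    return coords, box


def write_inpcrd(
    coordinates: np.ndarray, box: Optional[BoxSpec] = None,
    title: str = "generated", path: Optional[PathLike] = None,
) -> str:
    natom = len(coordinates)
    out = [title, "%5d" % natom]
    flat = [f for xyz in coordinates for f in xyz]
    if box is not None and box.kind != "none":
        flat.extend(box.lengths)
        flat.extend(box.angles)
    for i in range(0, len(flat), 6):
        out.append("".join("%12.7f" % v for v in flat[i : i + 6]))
    text = "\n".join(out) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# Tripos MOL2
# ---------------------------------------------------------------------------


def read_mol2(path: PathLike) -> MolecularSystem:
    """Read a Tripos MOL2 file: atoms, coordinates, types, charges, bonds.

    Bond connectivity is stored in ``bond_orders``; parameterised
    ``BondTerm`` objects are created later by the parameter engine.  The
    net charge is left unset — callers run
    :func:`topoconv.params.guess_net_charge`.
    """
    text = _read_text(path)
    blocks: dict[str, list[str]] = {}
    current = None
    for line in text.splitlines():
        s = line.strip()
        if s.startswith("@<TRIPOS>"):
            current = s[len("@<TRIPOS>") :].upper()
            blocks[current] = []
        elif current is not None and s and not s.startswith("#"):
            blocks[current].append(s)
    if "MOLECULE" not in blocks:
        raise ParseError("MOL2 is missing the @<TRIPOS>MOLECULE block")
    for required in ("ATOM", "BOND"):
        if required not in blocks:
            raise ParseError(f"MOL2 is missing the @<TRIPOS>{required} block")

    title = blocks["MOLECULE"][0] if blocks["MOLECULE"] else "MOL"

    atoms: list[AtomRecord] = []
    coords: list[list[float]] = []
    seen_ids: set[int] = set()
    for line in blocks["ATOM"]:
        f = line.split()
        if len(f) < 6:
            raise ParseError(f"MOL2 ATOM line too short: {line!r}")
        aid = int(f[0])
        if aid in seen_ids:
            raise StructuralError(f"duplicate MOL2 atom id {aid}")
        seen_ids.add(aid)
        x, y, z = float(f[2]), float(f[3]), float(f[4])
        atype = f[5]
        res_id = int(f[6]) if len(f) > 6 else 1
        res_name = f[7] if len(f) > 7 else "MOL"
        charge = float(f[8]) if len(f) > 8 else 0.0
        element = guess_element(atype.split(".")[0]) if "." in atype else guess_element(atype)
        if element == "X":
            element = guess_element(f[1])
        atoms.append(
            AtomRecord(
                index=aid, name=f[1], amber_type=atype,
                partial_charge=charge,
                mass=ELEMENT_MASSES.get(element, 0.0) or 1.0,
                element=element, residue_name=res_name[:3] or "MOL",
                residue_index=res_id,
            )
        )
        coords.append([x, y, z])

    atoms_sorted = sorted(atoms, key=lambda a: a.index)
    if [a.index for a in atoms_sorted] != list(range(1, len(atoms) + 1)):
        raise StructuralError("MOL2 atom ids are not a contiguous 1..N range")

    bond_orders: list[tuple[int, int, str]] = []
    for line in blocks["BOND"]:
        f = line.split()
        if len(f) < 4:
            raise ParseError(f"MOL2 BOND line too short: {line!r}")
        i, j, order = int(f[1]), int(f[2]), f[3]
        for a in (i, j):
            if not 1 <= a <= len(atoms):
                raise StructuralError(
                    f"MOL2 bond references atom id {a} outside 1..{len(atoms)}"
                )
        bond_orders.append((i, j, order))

    order = np.argsort([a.index for a in atoms])
    return MolecularSystem(
        title=title,
        atoms=atoms_sorted,
        coordinates=np.array(coords, dtype=float)[order],
        bond_orders=bond_orders,
    )


def write_mol2(system: MolecularSystem, path: Optional[PathLike] = None) -> str:
    if system.coordinates is None:
        raise StructuralError("cannot write MOL2 without coordinates")
    bonds = system.bond_orders or [(b.atoms[0], b.atoms[1], "1") for b in system.bonds]
    out = [
        "@<TRIPOS>MOLECULE",
        system.title or "MOL",
        "%5d %5d %5d %5d %5d" % (system.n_atoms, len(bonds), 1, 0, 0),
        "SMALL",
        "USER_CHARGES",
        "@<TRIPOS>ATOM",
    ]
    for a, xyz in zip(system.atoms, system.coordinates):
        out.append(
            "%7d %-8s %10.4f %10.4f %10.4f %-8s %3d %-8s %10.6f"
            % (a.index, a.name, xyz[0], xyz[1], xyz[2], a.amber_type,
               a.residue_index, a.residue_name, a.partial_charge)
        )
    out.append("@<TRIPOS>BOND")
    for n, (i, j, order) in enumerate(bonds, start=1):
        out.append("%6d %5d %5d %4s" % (n, i, j, order))
    text = "\n".join(out) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# frcmod / parm-dat parameter files
# ---------------------------------------------------------------------------

_TYPE_FIELD = r"([A-Za-z0-9\*\+]{1,2})"


def _match_types(line: str, count: int):
    """Split the leading hyphen-separated atom-type field off a parameter line."""
    pattern = r"^\s*" + r"\s*-\s*".join([_TYPE_FIELD] * count)
    m = re.match(pattern, line)
    if not m:
        raise ParseError(f"cannot read {count}-type field from line: {line!r}")
    return [t.upper() if t.upper() == "X" else t for t in m.groups()], line[m.end():]


_FRCMOD_SECTIONS = {
    "MASS": "mass", "BOND": "bond", "ANGL": "angle", "ANGLE": "angle",
    "DIHE": "dihedral", "DIHEDRAL": "dihedral", "IMPR": "improper",
    "IMPROPER": "improper", "NONB": "nonbond", "NONBON": "nonbond",
    "HBON": "hbond",
}


def _floats(text: str, n: int, context: str) -> list[float]:
    toks = text.split()
    if len(toks) < n:
        raise ParseError(f"{context}: expected {n} numeric fields in {text!r}")
    try:
        return [float(t) for t in toks[:n]]
    except ValueError as exc:
        raise ParseError(f"{context}: non-numeric field: {exc}") from exc


def read_frcmod(path: PathLike, dialect: str = "frcmod") -> ParameterSource:
    """Parse a frcmod or parm-dat parameter file into a ParameterSource.

    Torsion continuation lines (negative periodicity) are folded into
    multi-term Fourier series under a single canonical key.  Duplicate keys
    overwrite with a warning (last entry wins).
    """
    text = _read_text(path)
    label = f"frcmod:{Path(str(path)).stem}" if dialect == "frcmod" else f"parm:{Path(str(path)).stem}"
    source = ParameterSource(label=label)
    if dialect == "frcmod":
        _parse_frcmod_body(text, source)
    elif dialect == "parm_dat":
        _parse_parm_dat_body(text, source)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return source


def parameter_source_from_text(text: str, label: str = "frcmod:inline") -> ParameterSource:
    source = ParameterSource(label=label)
    _parse_frcmod_body(text, source)
    return source


class _TorsionAccumulator:
    """Folds negative-periodicity continuation lines into Fourier series."""

    def __init__(self, table: dict, what: str):
        self.table = table
        self.open_keys: set = set()
        self.what = what

    def add(self, key, pk, phase_rad, pn) -> None:
        if key in self.open_keys:
            self.table[key].append((pk, phase_rad, abs(pn)))
        else:
            if key in self.table:
                warnings.warn(f"duplicate {self.what} key {key}: last entry wins")
            self.table[key] = [(pk, phase_rad, abs(pn))]
        if pn < 0:
            self.open_keys.add(key)
        else:
            self.open_keys.discard(key)

    def finish(self) -> None:
        if self.open_keys:
            raise StructuralError(
                f"{self.what} series for {sorted(self.open_keys)} ends on a "
                "negative periodicity (dangling continuation)"
            )


def _add_mass(source, line):
    (t,), rest = _match_types(line, 1)
    mass = _floats(rest, 1, "MASS")[0]
    if t in source.mass_table:
        warnings.warn(f"duplicate MASS entry for {t}: last entry wins")
    source.mass_table[t] = (mass, element_from_mass(mass))


def _add_bond(source, line):
    types, rest = _match_types(line, 2)
    k, r = _floats(rest, 2, "BOND")
    key = ParameterSource.bond_key(*types)
    if key in source.bond_table:
        warnings.warn(f"duplicate BOND entry for {key}: last entry wins")
    source.bond_table[key] = (k, r)


def _add_angle(source, line):
    types, rest = _match_types(line, 3)
    k, theta_deg = _floats(rest, 2, "ANGLE")
    key = ParameterSource.angle_key(*types)
    if key in source.angle_table:
        warnings.warn(f"duplicate ANGLE entry for {key}: last entry wins")
    source.angle_table[key] = (k, math.radians(theta_deg))


def _add_nonbond(source, line):
    (t,), rest = _match_types(line, 1)
    rmin_half, eps = _floats(rest, 2, "NONBON")
    if t in source.lj_table:
        warnings.warn(f"duplicate NONBON entry for {t}: last entry wins")
    source.lj_table[t] = (rmin_half, eps)


def _parse_frcmod_body(text: str, source: ParameterSource) -> None:
    section = None
    dihe_acc = _TorsionAccumulator(source.torsion_table, "DIHE")
    impr_acc = _TorsionAccumulator(source.improper_table, "IMPROPER")
    lines = text.splitlines()
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip()
        if not line.strip():
            continue
        head = line.strip().split()[0].upper()
        if lineno == 1 and head not in _FRCMOD_SECTIONS:
            continue  # title line
        if head in _FRCMOD_SECTIONS and len(line.strip().split()) == 1:
            section = _FRCMOD_SECTIONS[head]
            continue
        if section is None:
            raise ParseError(f"frcmod line {lineno}: unknown section heading {head!r}")
        if section == "mass":
            _add_mass(source, line)
        elif section == "bond":
            _add_bond(source, line)
        elif section == "angle":
            _add_angle(source, line)
        elif section == "dihedral":
            types, rest = _match_types(line, 4)
            idivf, pk, phase_deg, pn = _floats(rest, 4, "DIHE")
            key = ParameterSource.torsion_key(*types)
            dihe_acc.add(key, pk / idivf, math.radians(phase_deg), int(round(pn)))
        elif section == "improper":
            types, rest = _match_types(line, 4)
            pk, phase_deg, pn = _floats(rest, 3, "IMPROPER")
            key = tuple(types)  # improper ordering is meaningful (central third)
            impr_acc.add(key, pk, math.radians(phase_deg), int(round(pn)))
        elif section == "nonbond":
            _add_nonbond(source, line)
        elif section == "hbond":
            continue
    dihe_acc.finish()
    impr_acc.finish()


def _parse_parm_dat_body(text: str, source: ParameterSource) -> None:
    """Positional parm-dat layout: title, MASS, hydrophilic line, BOND,
    ANGLE, DIHE, IMPROPER, 10-12 H-bond, equivalences, MOD4 NONBON."""
    dihe_acc = _TorsionAccumulator(source.torsion_table, "DIHE")
    impr_acc = _TorsionAccumulator(source.improper_table, "IMPROPER")
    # split into blank-line separated blocks; first line is the title
    lines = text.splitlines()[1:]
    blocks: list[list[str]] = [[]]
    for line in lines:
        if line.strip():
            blocks[-1].append(line)
        elif blocks[-1]:
            blocks.append([])
    blocks = [b for b in blocks if b]
    if not blocks:
        return
    stage = ["mass", "hydrophilic", "bond", "angle", "dihedral", "improper",
             "hbond", "equivalence", "nonbond"]
    for block, what in zip(blocks, stage):
        for line in block:
            if line.strip().upper() == "END":
                continue
            if what == "mass":
                _add_mass(source, line)
            elif what == "bond":
                _add_bond(source, line)
            elif what == "angle":
                _add_angle(source, line)
            elif what == "dihedral":
                types, rest = _match_types(line, 4)
                idivf, pk, phase_deg, pn = _floats(rest, 4, "DIHE")
                key = ParameterSource.torsion_key(*types)
                dihe_acc.add(key, pk / idivf, math.radians(phase_deg), int(round(pn)))
            elif what == "improper":
                types, rest = _match_types(line, 4)
                pk, phase_deg, pn = _floats(rest, 3, "IMPROPER")
                impr_acc.add(tuple(types), pk, math.radians(phase_deg), int(round(pn)))
            elif what == "nonbond":
                if line.strip().upper().startswith("MOD4"):
                    continue
                _add_nonbond(source, line)
            # hydrophilic / hbond / equivalence blocks are skipped
    dihe_acc.finish()
    impr_acc.finish()


def write_frcmod(source: ParameterSource, path: Optional[PathLike] = None) -> str:
    """Serialise a ParameterSource back to frcmod text (round-trip identity)."""
    out = [f"parameters written from {source.label}", "", "MASS"]
    for t, (mass, _el) in source.mass_table.items():
        out.append(f"{t:<2s}   {mass:10.4f}")
    out += ["", "BOND"]
    for (t1, t2), (k, r) in source.bond_table.items():
        out.append(f"{t1:<2s}-{t2:<2s}   {k:10.4f} {r:10.5f}")
    out += ["", "ANGLE"]
    for (t1, t2, t3), (k, theta) in source.angle_table.items():
        out.append(f"{t1:<2s}-{t2:<2s}-{t3:<2s}  {k:10.4f} {math.degrees(theta):10.4f}")
    out += ["", "DIHE"]
    for key, series in source.torsion_table.items():
        t1, t2, t3, t4 = key
        for n, (pk, phase, pn) in enumerate(series):
            last = n == len(series) - 1
            out.append(
                f"{t1:<2s}-{t2:<2s}-{t3:<2s}-{t4:<2s}   1 {pk:12.6f} "
                f"{math.degrees(phase):10.3f} {pn if last else -pn:6.1f}"
            )
    out += ["", "IMPROPER"]
    for key, series in source.improper_table.items():
        t1, t2, t3, t4 = key
        for n, (pk, phase, pn) in enumerate(series):
            last = n == len(series) - 1
            out.append(
                f"{t1:<2s}-{t2:<2s}-{t3:<2s}-{t4:<2s}  {pk:12.6f} "
                f"{math.degrees(phase):10.3f} {pn if last else -pn:6.1f}"
            )
    out += ["", "NONBON"]
    for t, (rmin_half, eps) in source.lj_table.items():
        out.append(f"  {t:<2s}  {rmin_half:10.5f} {eps:12.7f}")
    out.append("")
    text = "\n".join(out) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
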