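"""Functional-form, unit and convention transformations.

This is the conversion core: AMBER harmonic constants (k*(x-x0)^2, kcal,
Angstrom, radian) to GROMACS conventions (0.5*k*(x-x0)^2, kJ, nm, degree),
Fourier torsions to Ryckaert-Bellemans polynomials, LJ A/B coefficients to
sigma/epsilon, prmtop dihedral sign-flag decoding, 1-4 pair / exclusion
bookkeeping on the bond graph, box-shape conversion, water-model
recognition, net-charge rounding, the covalent-distance sanity filter and
the ordered parameter-source fallback (e.g. AMBER99SB falling back to
GAFF).
"""

from __future__ import annotations

import importlib.resources
import math
import warnings
from dataclasses import dataclass, field
from itertools import permutations
from typing import Iterable, Optional, Sequence, Union

import networkx as nx
import numpy as np

from . import constants as C
from .errors import (
    GeometryError,
    MissingParameterError,
    NetChargeError,
    StructuralError,
    TopoconvError,
)
from .model import (
    AngleTerm,
    BondTerm,
    BoxSpec,
    LJType,
    MolecularSystem,
    ParameterSource,
    TorsionTerm,
)

__all__ = [
    "RBCoefficients", "GeometryReport", "convert_harmonic",
    "convert_torsion_f9", "fourier_to_rb", "classify_torsions",
    "build_pairs_exclusions", "lj_ab_to_sigma_eps", "sigma_eps_to_ab",
    "convert_box", "recognize_water", "guess_net_charge",
    "validate_geometry", "resolve_parameters", "load_water_models",
]


# ---------------------------------------------------------------------------
# harmonic and torsion conversions
# ---------------------------------------------------------------------------


def convert_harmonic(
    force_k: float, equilibrium: float, term_kind: str
) -> tuple[float, float]:
    """Convert an AMBER harmonic term to GROMACS units and convention.

    AMBER writes k*(x-x0)^2, GROMACS 0.5*k*(x-x0)^2, hence the factor 2.

    bond:  (r_eq A, k kcal/mol/A^2)   -> (r_eq nm, k kJ/mol/nm^2)
    angle: (theta_eq rad, k kcal/mol/rad^2) -> (theta_eq deg, k kJ/mol/rad^2)
    """
    if force_k < 0:
        raise ValueError(f"negative force constant {force_k}")
    if term_kind == "bond":
        return (
            equilibrium * C.ANGSTROM_TO_NM,
            2.0 * C.KCAL_TO_KJ * force_k / C.ANGSTROM_TO_NM**2,
        )
    if term_kind == "angle":
        return (math.degrees(equilibrium), 2.0 * C.KCAL_TO_KJ * force_k)
    raise ValueError(f"unknown term_kind {term_kind!r}")


def convert_torsion_f9(term: TorsionTerm) -> tuple[float, float, int]:
    """Map one Fourier torsion component to a GROMACS function-9 line.

    Returns (phase degrees in [0, 360), k kJ/mol, periodicity).  Each
    component of a multi-term quartet maps to its own line; components are
    never combined.
    """
    if term.periodicity < 1:
        raise ValueError(f"periodicity {term.periodicity} < 1")
    phase_deg = math.degrees(term.phase) % 360.0
    return (phase_deg, term.barrier_half * C.KCAL_TO_KJ, term.periodicity)


@dataclass
class RBCoefficients:
    """Ryckaert-Bellemans coefficients C0..C5, kJ/mol, psi = phi - 180 deg."""

    C: tuple[float, float, float, float, float, float]

    def value(self, phi_rad: float | np.ndarray) -> np.ndarray:
        """Potential at dihedral angle phi (IUPAC convention), kJ/mol."""
        cos_psi = np.cos(np.asarray(phi_rad) - math.pi)
        acc = np.zeros_like(cos_psi, dtype=float)
        for coeff in reversed(self.C):  # Horner on C5..C0
            acc = acc * cos_psi + coeff
        return acc


def fourier_to_rb(series: Sequence[tuple[float, float, int]]) -> RBCoefficients:
    """Convert a Fourier torsion series to Ryckaert-Bellemans coefficients.

    ``series`` holds (Vn, phase_rad, n) with Vn the *full* barrier in
    kcal/mol, n in 1..4 and phase restricted to 0 or pi — the only phases
    for which the closed-form mapping exists.  Output is in kJ/mol under
    the psi = phi - 180 deg convention and equals the Fourier potential at
    every angle.
    """
    c = [0.0] * 6
    for vn, phase, n in series:
        cos_g = math.cos(phase)
        if abs(abs(cos_g) - 1.0) > 1e-9:
            raise ValueError(
                f"phase {phase} rad is neither 0 nor pi; this component must "
                "stay in function-9 Fourier form"
            )
        if not 1 <= n <= 4:
            raise ValueError(f"periodicity {n} outside 1..4 for RB conversion")
        g = vn * (1.0 if cos_g > 0 else -1.0)  # signed barrier
        c[0] += vn / 2.0
        if n == 1:
            c[0] += 0.0
            c[1] += -g / 2.0
        elif n == 2:
            c[0] += -g / 2.0
            c[2] += g
        elif n == 3:
            c[1] += 1.5 * g
            c[3] += -2.0 * g
        elif n == 4:
            c[0] += g / 2.0
            c[2] += -4.0 * g
            c[4] += 4.0 * g
    return RBCoefficients(C=tuple(ci * C.KCAL_TO_KJ for ci in c))


def fourier_value(
    series: Sequence[tuple[float, float, int]], phi_rad: float | np.ndarray
) -> np.ndarray:
    """Fourier torsion potential sum((Vn/2)(1+cos(n phi - gamma))), kJ/mol."""
    phi = np.asarray(phi_rad, dtype=float)
    acc = np.zeros_like(phi)
    for vn, phase, n in series:
        acc = acc + (vn / 2.0) * (1.0 + np.cos(n * phi - phase))
    return acc * C.KCAL_TO_KJ


def rb_from_torsions(terms: Sequence[TorsionTerm]) -> RBCoefficients:
    """RB coefficients for a quartet's TorsionTerm components (PK = Vn/2)."""
    return fourier_to_rb([(2.0 * t.barrier_half, t.phase, t.periodicity) for t in terms])


# ---------------------------------------------------------------------------
# prmtop dihedral sign decoding
# ---------------------------------------------------------------------------


def classify_torsions(
    raw: Sequence[Sequence[int]],
    k_table: Sequence[float],
    n_table: Sequence[float],
    phase_table: Sequence[float],
) -> list[TorsionTerm]:
    """Decode prmtop dihedral entries into TorsionTerm objects.

    prmtop encodes each dihedral as (3(i-1), 3(j-1), +-3(k-1), +-3(l-1),
    type): a negative fourth index marks an improper, a negative third
    index suppresses the 1-4 pair.  Output lists propers first, then
    impropers, each preserving input order, with unsigned indices.
    """
    propers: list[TorsionTerm] = []
    impropers: list[TorsionTerm] = []
    for entry in raw:
        i3, j3, k3, l3, tix = entry
        if i3 < 0 or j3 < 0:
            raise StructuralError(
                f"negative index in first/second dihedral position: {entry}"
            )
        if not 1 <= tix <= len(k_table):
            raise StructuralError(f"dihedral type index {tix} out of range")
        kind = "improper" if l3 < 0 else "proper"
        generates_14 = kind == "proper" and k3 >= 0
        atoms = (i3 // 3 + 1, j3 // 3 + 1, abs(k3) // 3 + 1, abs(l3) // 3 + 1)
        term = TorsionTerm(
            atoms=atoms,
            barrier_half=k_table[tix - 1],
            periodicity=int(round(n_table[tix - 1])),
            phase=phase_table[tix - 1] % (2.0 * math.pi),
            kind=kind,
            generates_14=generates_14,
        )
        (impropers if kind == "improper" else propers).append(term)
    return propers + impropers


# ---------------------------------------------------------------------------
# 1-4 pairs and exclusions
# ---------------------------------------------------------------------------


def bond_graph(system: MolecularSystem) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(1, system.n_atoms + 1))
    if system.bonds:
        g.add_edges_from(b.atoms for b in system.bonds)
    else:
        g.add_edges_from((i, j) for i, j, _ in system.bond_orders)
    return g


def build_pairs_exclusions(
    system: MolecularSystem,
) -> tuple[list[tuple[int, int]], list[list[int]]]:
    """Derive the scaled 1-4 pair list and full exclusion lists.

    Candidate pairs are the end atoms of proper torsions flagged
    ``generates_14``; a candidate survives only if its bond-graph distance
    is exactly 3 (pairs that are also 1-2 or 1-3 connected — e.g. in small
    rings — are dropped), and duplicates arising from multiple torsion
    paths (ring para pairs) are emitted once.  Exclusions are all 1-2, 1-3
    and 1-4 neighbours, symmetric.
    """
    n = system.n_atoms
    for t in system.torsions:
        for a in t.atoms:
            if not 1 <= a <= n:
                raise StructuralError(f"torsion {t.atoms} references unknown atom {a}")
    g = bond_graph(system)
    dist: list[dict[int, int]] = [
        nx.single_source_shortest_path_length(g, i, cutoff=3) for i in range(1, n + 1)
    ]

    pairs: set[tuple[int, int]] = set()
    for t in system.torsions:
        if t.kind != "proper" or not t.generates_14:
            continue
        i, l = t.atoms[0], t.atoms[3]
        if dist[i - 1].get(l, 99) == 3:
            pairs.add((min(i, l), max(i, l)))

    exclusions: list[set[int]] = [set() for _ in range(n)]
    for i in range(1, n + 1):
        for j, d in dist[i - 1].items():
            if j != i and 1 <= d <= 2:
                exclusions[i - 1].add(j)
                exclusions[j - 1].add(i)
    for i, j in pairs:
        exclusions[i - 1].add(j)
        exclusions[j - 1].add(i)

    return sorted(pairs), [sorted(s) for s in exclusions]


# ---------------------------------------------------------------------------
# Lennard-Jones dialects
# ---------------------------------------------------------------------------


def lj_ab_to_sigma_eps(
    lj: Union[LJType, tuple[float, float]], B: Optional[float] = None
) -> tuple[float, float]:
    """AMBER A (kcal A^12/mol), B (kcal A^6/mol) -> (sigma nm, epsilon kJ/mol).

    Zero-LJ atoms (A = B = 0, typical for polar hydrogens) map to (0, 0).
    """
    if isinstance(lj, LJType):
        a, b = lj.A, lj.B
    elif B is not None:
        a, b = float(lj), float(B)
    else:
        a, b = lj
    if a < 0 or b < 0:
        raise ValueError("LJ A and B must be non-negative")
    if a == 0.0 or b == 0.0:
        return (0.0, 0.0)
    sigma_ang = (a / b) ** (1.0 / 6.0)
    eps_kcal = b * b / (4.0 * a)
    return (sigma_ang * C.ANGSTROM_TO_NM, eps_kcal * C.KCAL_TO_KJ)


def sigma_eps_to_ab(sigma_nm: float, eps_kj: float) -> tuple[float, float]:
    """Inverse map: (sigma nm, epsilon kJ/mol) -> AMBER (A, B); round-trip identity."""
    if sigma_nm == 0.0 or eps_kj == 0.0:
        return (0.0, 0.0)
    sigma_ang = sigma_nm / C.ANGSTROM_TO_NM
    eps_kcal = eps_kj / C.KCAL_TO_KJ
    return (4.0 * eps_kcal * sigma_ang**12, 4.0 * eps_kcal * sigma_ang**6)


def rmin_half_eps_to_ab(rmin_half_ang: float, eps_kcal: float) -> tuple[float, float]:
    """AMBER NONBON convention (Rmin/2 A, eps kcal/mol) -> (A, B)."""
    if rmin_half_ang == 0.0 or eps_kcal == 0.0:
        return (0.0, 0.0)
    rmin = 2.0 * rmin_half_ang
    return (eps_kcal * rmin**12, 2.0 * eps_kcal * rmin**6)


# ---------------------------------------------------------------------------
# box conversion
# ---------------------------------------------------------------------------


def convert_box(
    box: BoxSpec,
    coordinates: Optional[np.ndarray] = None,
    clearance: float = C.DEFAULT_CLEARANCE_NM,
) -> np.ndarray:
    """Convert an inpcrd box description to triclinic row vectors in nm.

    A truncated octahedron with edge d yields a = (d, 0, 0),
    b = (-d/3, (2 sqrt2/3) d, 0), c = (-d/3, -(sqrt2/3) d, (sqrt6/3) d)
    (x 0.1 into nm); an orthorhombic box yields a diagonal matrix; with no
    box, a cubic cell is built from the coordinate bounding extent plus
    2 x ``clearance`` per axis.  General triclinic cells are supported via
    the standard crystallographic construction (the octahedron formula is
    its special case at all angles arccos(-1/3)).
    """
    if box.kind == "none":
        if coordinates is None:
            raise StructuralError("no box and no coordinates to derive one from")
        extent_nm = (coordinates.max(axis=0) - coordinates.min(axis=0)) * C.ANGSTROM_TO_NM
        edges = extent_nm + 2.0 * clearance
        return np.diag(edges)
    la, lb, lc = (x * C.ANGSTROM_TO_NM for x in box.lengths)
    if box.kind == "orthorhombic":
        return np.diag([la, lb, lc])
    if box.kind == "truncated_octahedron":
        # closed form: the inpcrd angle 109.471219 is a rounded print of
        # arccos(-1/3); use the exact cell
        s2, s6 = math.sqrt(2.0), math.sqrt(6.0)
        return np.array(
            [
                [la, 0.0, 0.0],
                [-lb / 3.0, 2.0 * s2 / 3.0 * lb, 0.0],
                [-lc / 3.0, -s2 / 3.0 * lc, s6 / 3.0 * lc],
            ]
        )
    alpha, beta, gamma = (math.radians(a) for a in box.angles)
    cos_a, cos_b, cos_g = math.cos(alpha), math.cos(beta), math.cos(gamma)
    sin_g = math.sin(gamma)
    if sin_g < 1e-12:
        raise StructuralError(f"degenerate cell: gamma = {box.angles[2]} deg")
    a_vec = np.array([la, 0.0, 0.0])
    b_vec = np.array([lb * cos_g, lb * sin_g, 0.0])
    cx = cos_b
    cy = (cos_a - cos_b * cos_g) / sin_g
    cz_sq = 1.0 - cx * cx - cy * cy
    if cz_sq <= 0:
        raise StructuralError(f"unsupported cell: angles {box.angles} are not realisable")
    c_vec = lc * np.array([cx, cy, math.sqrt(cz_sq)])
    return np.array([a_vec, b_vec, c_vec])


# ---------------------------------------------------------------------------
# water recognition
# ---------------------------------------------------------------------------


@dataclass
class WaterModel:
    name: str
    q_o: float
    q_h: float
    sigma_o: float  # nm
    eps_o: float  # kJ/mol


def load_water_models() -> list[WaterModel]:
    """Bundled reference table of recognisable 3-site water models."""
    text = (
        importlib.resources.files("topoconv") / "data" / "water_models.txt"
    ).read_text()
    models = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, qo, qh, sig, eps = line.split()
        models.append(WaterModel(name, float(qo), float(qh), float(sig), float(eps)))
    return models


def _rel_close(a: float, b: float, tol: float) -> bool:
    return abs(a - b) <= tol * max(abs(a), abs(b), 1e-30)


def recognize_water(system: MolecularSystem) -> Optional[str]:
    """Identify the water model of any 3-atom O/H/H residue, by parameters.

    Matching is on charges (within 1e-3 e) and on the oxygen LJ
    sigma/epsilon (within 1e-3 relative) against the bundled table —
    deliberately not on residue names, which renaming destroys.  Returns
    the first matching model name, or None.
    """
    by_res: dict[int, list] = {}
    for a in system.atoms:
        by_res.setdefault(a.residue_index, []).append(a)
    models = load_water_models()
    for res_atoms in by_res.values():
        if len(res_atoms) != 3:
            continue
        elements = sorted(a.element for a in res_atoms)
        if elements != ["H", "H", "O"]:
            continue
        o = next(a for a in res_atoms if a.element == "O")
        hs = [a for a in res_atoms if a.element == "H"]
        try:
            sigma, eps = lj_ab_to_sigma_eps(system.lj_type_of(o.index))
        except TopoconvError:
            continue
        for m in models:
            if (
                abs(o.partial_charge - m.q_o) <= C.WATER_MATCH_TOL
                and all(abs(h.partial_charge - m.q_h) <= C.WATER_MATCH_TOL for h in hs)
                and _rel_close(sigma, m.sigma_o, C.WATER_MATCH_TOL)
                and _rel_close(eps, m.eps_o, C.WATER_MATCH_TOL)
            ):
                return m.name
    return None


# ---------------------------------------------------------------------------
# net charge and geometry
# ---------------------------------------------------------------------------


def guess_net_charge(charges: Iterable[float]) -> int:
    """Round the charge sum to the nearest integer, with sanity thresholds.

    Deviation above 0.1 e raises (charge guessing would be unreliable);
    above 0.01 e a warning is attached, matching typical charge-derivation
    drift.
    """
    total = float(sum(charges))
    nearest = round(total)
    dev = abs(total - nearest)
    if dev > C.CHARGE_ERROR_TOL:
        raise NetChargeError(
            f"partial charges sum to {total:.4f}, {dev:.4f} e away from any "
            "integer; specify the net charge explicitly"
        )
    if dev > C.CHARGE_WARN_TOL:
        warnings.warn(
            f"partial charges sum to {total:.4f}; rounding to {nearest} "
            f"(deviation {dev:.4f} e)"
        )
    return int(nearest)


@dataclass
class GeometryReport:
    """Covalent-distance sanity filter result."""

    distances: list[tuple[tuple[int, int], float]] = field(default_factory=list)
    violations: list[tuple[tuple[int, int], float, str]] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.violations


def validate_geometry(system: MolecularSystem) -> GeometryReport:
    """Check every covalent bond length against the 0.5/3.0 A sanity window.

    Bonded atoms closer than 0.5 A or farther than 3.0 A indicate corrupt
    input coordinates; such systems are rejected before parameterisation.
    """
    if system.coordinates is None:
        raise StructuralError("geometry validation requires coordinates")
    report = GeometryReport()
    pairs = (
        [b.atoms for b in system.bonds]
        if system.bonds
        else [(i, j) for i, j, _ in system.bond_orders]
    )
    for i, j in pairs:
        d = float(np.linalg.norm(system.coordinates[i - 1] - system.coordinates[j - 1]))
        report.distances.append(((i, j), d))
        if d < C.BOND_MIN_ANGSTROM:
            report.violations.append(((i, j), d, "min_0.5"))
        elif d > C.BOND_MAX_ANGSTROM:
            report.violations.append(((i, j), d, "max_3.0"))
    return report


# ---------------------------------------------------------------------------
# parameter resolution with fallback
# ---------------------------------------------------------------------------


def _lookup_plain(tables: Sequence[tuple[str, dict]], key):
    for label, table in tables:
        if key in table:
            return table[key], label
    return None, None


def _lookup_torsion(sources: Sequence[ParameterSource], types: tuple[str, str, str, str]):
    """Exact key first, then single-wildcard, then double-wildcard, per source."""
    t1, t2, t3, t4 = types
    exact = ParameterSource.torsion_key(t1, t2, t3, t4)
    singles = [
        ParameterSource.torsion_key("X", t2, t3, t4),
        ParameterSource.torsion_key(t1, t2, t3, "X"),
    ]
    double = ParameterSource.torsion_key("X", t2, t3, "X")
    for src in sources:
        for key in [exact, *singles, double]:
            if key in src.torsion_table:
                return src.torsion_table[key], src.label
    return None, None


def _lookup_improper(sources: Sequence[ParameterSource], center_type: str, neigh_types):
    """Improper key order: (n1, n2, center, n3); wildcards fill from the left."""
    for src in sources:
        # exact neighbour permutations
        for perm in permutations(neigh_types):
            key = (perm[0], perm[1], center_type, perm[2])
            if key in src.improper_table:
                return src.improper_table[key], src.label, key
        for perm in permutations(neigh_types, 2):
            key = ("X", perm[0], center_type, perm[1])
            if key in src.improper_table:
                return src.improper_table[key], src.label, key
        for t in neigh_types:
            key = ("X", "X", center_type, t)
            if key in src.improper_table:
                return src.improper_table[key], src.label, key
    return None, None, None


def resolve_parameters(
    system: MolecularSystem, sources: Sequence[ParameterSource]
) -> dict[str, str]:
    """Parameterise a connectivity-only system from ordered sources.

    Each bond/angle/torsion/LJ parameter is taken from the FIRST source
    containing its key — the fallback chain (e.g. AMBER99SB tables first,
    GAFF second).  Angles and proper-torsion quartets are enumerated from
    the bond graph; impropers are added for every atom with exactly three
    neighbours for which some source defines a matching improper key.

    Returns a provenance map ``term-descriptor -> source label`` and fills
    the system in place.  A key absent from every source raises
    :class:`MissingParameterError` naming the type tuple.
    """
    if not sources:
        raise ValueError("at least one ParameterSource is required")
    for a in system.atoms:
        if not a.amber_type:
            raise StructuralError(f"atom {a.index} has no type assigned")

    provenance: dict[str, str] = {}
    atype = {a.index: a.amber_type for a in system.atoms}

    mass_tables = [(s.label, s.mass_table) for s in sources]
    for a in system.atoms:
        entry, label = _lookup_plain(mass_tables, a.amber_type)
        if entry is not None:
            a.mass, element = entry
            if element != "X":
                a.element = element
            provenance[f"mass:{a.amber_type}"] = label

    graph = bond_graph(system)
    if not system.bonds and not system.bond_orders:
        raise StructuralError("system has no connectivity to parameterise")

    bond_tables = [(s.label, s.bond_table) for s in sources]
    new_bonds: list[BondTerm] = []
    edge_list = (
        [b.atoms for b in system.bonds]
        if system.bonds
        else [(i, j) for i, j, _ in system.bond_orders]
    )
    for i, j in edge_list:
        key = ParameterSource.bond_key(atype[i], atype[j])
        entry, label = _lookup_plain(bond_tables, key)
        if entry is None:
            raise MissingParameterError(f"no bond parameters for type pair {key}")
        new_bonds.append(BondTerm(atoms=(i, j), force_k=entry[0], r_eq=entry[1]))
        provenance[f"bond:{'-'.join(key)}"] = label
    system.bonds = new_bonds

    angle_tables = [(s.label, s.angle_table) for s in sources]
    system.angles = []
    for j in sorted(graph.nodes):
        neigh = sorted(graph.neighbors(j))
        for a_i in range(len(neigh)):
            for b_i in range(a_i + 1, len(neigh)):
                i, k = neigh[a_i], neigh[b_i]
                key = ParameterSource.angle_key(atype[i], atype[j], atype[k])
                entry, label = _lookup_plain(angle_tables, key)
                if entry is None:
                    raise MissingParameterError(
                        f"no angle parameters for type triple {key}"
                    )
                system.angles.append(
                    AngleTerm(atoms=(i, j, k), force_k=entry[0], theta_eq=entry[1])
                )
                provenance[f"angle:{'-'.join(key)}"] = label

    system.torsions = []
    propers: list[TorsionTerm] = []
    for j, k in sorted(tuple(sorted(e)) for e in graph.edges):
        for i in sorted(graph.neighbors(j)):
            if i == k:
                continue
            for l in sorted(graph.neighbors(k)):
                if l == j or l == i:
                    continue
                types = (atype[i], atype[j], atype[k], atype[l])
                series, label = _lookup_torsion(sources, types)
                if series is None:
                    raise MissingParameterError(
                        f"no torsion parameters for type quadruple {types}"
                    )
                for n_comp, (pk, phase, per) in enumerate(series):
                    propers.append(
                        TorsionTerm(
                            atoms=(i, j, k, l),
                            barrier_half=pk,
                            periodicity=per,
                            phase=phase % (2 * math.pi),
                            kind="proper",
                            generates_14=(n_comp == 0),
                        )
                    )
                provenance[f"torsion:{'-'.join(types)}"] = label

    impropers: list[TorsionTerm] = []
    for center in sorted(graph.nodes):
        neigh = sorted(graph.neighbors(center))
        if len(neigh) != 3:
            continue
        neigh_types = tuple(atype[n] for n in neigh)
        series, label, key = _lookup_improper(sources, atype[center], neigh_types)
        if series is None:
            continue  # impropers are optional: only added where defined
        # canonical atom order: central atom third
        n_sorted = sorted(neigh, key=lambda n: (atype[n], n))
        quartet = (n_sorted[0], n_sorted[1], center, n_sorted[2])
        for pk, phase, per in series:
            impropers.append(
                TorsionTerm(
                    atoms=quartet,
                    barrier_half=pk,
                    periodicity=per,
                    phase=phase % (2 * math.pi),
                    kind="improper",
                )
            )
        provenance[f"improper:{'-'.join(key)}"] = label
    system.torsions = propers + impropers

    lj_tables = [(s.label, s.lj_table) for s in sources]
    system.lj_types = []
    for type_name in dict.fromkeys(a.amber_type for a in system.atoms):
        entry, label = _lookup_plain(lj_tables, type_name)
        if entry is None:
            raise MissingParameterError(f"no LJ parameters for type {type_name!r}")
        a_coef, b_coef = rmin_half_eps_to_ab(*entry)
        system.lj_types.append(LJType(type_name=type_name, A=a_coef, B=b_coef))
        provenance[f"lj:{type_name}"] = label

    _pairs, system.exclusions = build_pairs_exclusions(system)
    if system.net_charge is None:
        system.net_charge = guess_net_charge(a.partial_charge for a in system.atoms)
    system.validate()
    return provenance
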