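"""Vacuum single-point potential-energy evaluator.

This is the conversion-fidelity oracle: the same physical system is
evaluated in AMBER form (k(x-x0)^2 harmonics, Fourier torsions, kcal/A
units) and in GROMACS form (0.5 k harmonics, function-9 or
Ryckaert-Bellemans torsions, kJ/nm units) and the per-term energies must
agree.  Nonbonded interactions are summed over all non-excluded pairs
with no cutoff and no periodicity — the oracle certifies topology
conversion, not simulation realism, and on small vacuum systems the
full sum is exact and engine-independent.

Dihedral angles use the standard signed IUPAC convention (cis = 0).
Coordinates are always supplied in Angstrom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from . import constants as C
from .errors import MissingParameterError, StructuralError
from .model import MolecularSystem
from .params import (
    build_pairs_exclusions,
    convert_harmonic,
    convert_torsion_f9,
    lj_ab_to_sigma_eps,
    rb_from_torsions,
)

TERM_NAMES = (
    "bonds", "angles", "propers", "impropers",
    "lj_14", "coulomb_14", "lj_nb", "coulomb_nb",
)


@dataclass
class EnergyReport:
    """Per-term single-point energies, kJ/mol."""

    bonds: float = 0.0
    angles: float = 0.0
    propers: float = 0.0
    impropers: float = 0.0
    lj_14: float = 0.0
    coulomb_14: float = 0.0
    lj_nb: float = 0.0
    coulomb_nb: float = 0.0
    unit_system: str = "kJ/mol"

    @property
    def total(self) -> float:
        return sum(getattr(self, name) for name in TERM_NAMES)

    def as_dict(self) -> dict[str, float]:
        d = {name: getattr(self, name) for name in TERM_NAMES}
        d["total"] = self.total
        return d

    def to_tsv(self) -> str:
        lines = ["term\tenergy_kJ_mol"]
        for name, value in self.as_dict().items():
            lines.append(f"{name}\t{value:.10g}")
        return "\n".join(lines) + "\n"


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed dihedral in radians, IUPAC convention (cis = 0)."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return math.atan2(y, x)


def _distance(coords: np.ndarray, i: int, j: int, context: str) -> float:
    r = float(np.linalg.norm(coords[i - 1] - coords[j - 1]))
    if r < C.OVERLAP_MIN_ANGSTROM:
        raise StructuralError(
            f"atoms {i} and {j} overlap (r = {r:.2e} A) in {context} evaluation"
        )
    return r


def _lj_energy(sig_i, eps_i, sig_j, eps_j, r_nm: float) -> float:
    eps = math.sqrt(eps_i * eps_j)
    if eps == 0.0:
        return 0.0
    sig = 0.5 * (sig_i + sig_j)
    sr6 = (sig / r_nm) ** 6
    return 4.0 * eps * (sr6 * sr6 - sr6)


def _nonbonded(
    coords, charges, sigmas, epsilons, pairs_14, exclusions, fudge_lj, fudge_qq
):
    n = len(charges)
    lj14 = c14 = ljnb = cnb = 0.0
    pair_set = set(pairs_14)
    excl = [set(e) for e in exclusions] if exclusions else [set() for _ in range(n)]
    for i, j in pair_set:
        r = _distance(coords, i, j, "1-4") * C.ANGSTROM_TO_NM
        lj14 += fudge_lj * _lj_energy(
            sigmas[i - 1], epsilons[i - 1], sigmas[j - 1], epsilons[j - 1], r
        )
        c14 += fudge_qq * C.COULOMB_KJ_NM * charges[i - 1] * charges[j - 1] / r
    for i in range(1, n + 1):
        for j in range(i + 1, n + 1):
            if j in excl[i - 1] or (i, j) in pair_set:
                continue
            r = _distance(coords, i, j, "nonbonded") * C.ANGSTROM_TO_NM
            ljnb += _lj_energy(
                sigmas[i - 1], epsilons[i - 1], sigmas[j - 1], epsilons[j - 1], r
            )
            cnb += C.COULOMB_KJ_NM * charges[i - 1] * charges[j - 1] / r
    return lj14, c14, ljnb, cnb


def _system_nonbonded_arrays(system: MolecularSystem):
    sig, eps = [], []
    for a in system.atoms:
        s, e = lj_ab_to_sigma_eps(system.lj_type_of(a.index))
        sig.append(s)
        eps.append(e)
    charges = [a.partial_charge for a in system.atoms]
    return charges, sig, eps


def single_point_energy(
    system: Union[MolecularSystem, "object"],
    coordinates: Optional[np.ndarray] = None,
    form: str = "amber",
) -> EnergyReport:
    """Evaluate the potential energy of a system at fixed coordinates.

    ``form`` selects the analytic representation:

    * ``amber``       — k(x-x0)^2 harmonics, Fourier torsions
      PK(1+cos(n phi - gamma)), evaluated in kcal/A and reported in kJ
    * ``gromacs_f9``  — parameters converted to GROMACS units/conventions
      first (0.5 k harmonics, function-9 torsions), evaluated in kJ/nm
    * ``gromacs_rb``  — as f9 but proper torsion series collapsed to
      Ryckaert-Bellemans polynomials (phases must be 0 or pi)

    The three forms are algebraically identical; evaluating a system in
    two forms and comparing is the package's conversion-fidelity check.
    A re-parsed :class:`~topoconv.gromacs.GromacsTopology` may be passed
    instead of a MolecularSystem (its stored function types are used).
    """
    from .gromacs import GromacsTopology

    if isinstance(system, GromacsTopology):
        return _evaluate_gromacs_topology(system, coordinates)
    if coordinates is None:
        coordinates = system.coordinates
    if coordinates is None:
        raise StructuralError("no coordinates supplied for energy evaluation")
    coords = np.asarray(coordinates, dtype=float)
    if form == "amber":
        return _evaluate_amber(system, coords)
    if form in ("gromacs_f9", "gromacs_rb"):
        return _evaluate_gromacs_form(system, coords, rb=form == "gromacs_rb")
    raise ValueError(f"unknown energy form {form!r}")


def _bonded_geometry(system, coords):
    bond_r = [_distance(coords, *b.atoms, "bond") for b in system.bonds]
    angle_t = []
    for a in system.angles:
        i, j, k = a.atoms
        v1 = coords[i - 1] - coords[j - 1]
        v2 = coords[k - 1] - coords[j - 1]
        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        angle_t.append(math.acos(max(-1.0, min(1.0, cosang))))
    torsion_phi = [
        dihedral_angle(*(coords[x - 1] for x in t.atoms)) for t in system.torsions
    ]
    return bond_r, angle_t, torsion_phi


def _check_parameterised(system: MolecularSystem) -> None:
    if not system.lj_types:
        raise MissingParameterError("system has no LJ tables")
    for a in system.atoms:
        system.lj_type_of(a.index)


def _evaluate_amber(system: MolecularSystem, coords) -> EnergyReport:
    _check_parameterised(system)
    bond_r, angle_t, torsion_phi = _bonded_geometry(system, coords)
    rep = EnergyReport()
    for b, r in zip(system.bonds, bond_r):
        rep.bonds += b.force_k * (r - b.r_eq) ** 2
    for a, t in zip(system.angles, angle_t):
        rep.angles += a.force_k * (t - a.theta_eq) ** 2
    for term, phi in zip(system.torsions, torsion_phi):
        e = term.barrier_half * (1.0 + math.cos(term.periodicity * phi - term.phase))
        if term.kind == "improper":
            rep.impropers += e
        else:
            rep.propers += e
    rep.bonds *= C.KCAL_TO_KJ
    rep.angles *= C.KCAL_TO_KJ
    rep.propers *= C.KCAL_TO_KJ
    rep.impropers *= C.KCAL_TO_KJ

    pairs, derived_excl = build_pairs_exclusions(system)
    exclusions = system.exclusions if system.exclusions else derived_excl
    charges, sig, eps = _system_nonbonded_arrays(system)
    rep.lj_14, rep.coulomb_14, rep.lj_nb, rep.coulomb_nb = _nonbonded(
        coords, charges, sig, eps, pairs, exclusions, C.LJ14_SCALE, C.COULOMB14_SCALE
    )
    return rep


def _evaluate_gromacs_form(system: MolecularSystem, coords, rb: bool) -> EnergyReport:
    _check_parameterised(system)
    bond_r, angle_t, torsion_phi = _bonded_geometry(system, coords)
    rep = EnergyReport()
    for b, r in zip(system.bonds, bond_r):
        b0_nm, kb = convert_harmonic(b.force_k, b.r_eq, "bond")
        rep.bonds += 0.5 * kb * (r * C.ANGSTROM_TO_NM - b0_nm) ** 2
    for a, t in zip(system.angles, angle_t):
        th0_deg, ka = convert_harmonic(a.force_k, a.theta_eq, "angle")
        rep.angles += 0.5 * ka * (t - math.radians(th0_deg)) ** 2

    if rb:
        groups: dict[tuple, list] = {}
        for term, phi in zip(system.torsions, torsion_phi):
            if term.kind == "proper":
                groups.setdefault(term.atoms, ([], phi))[0].append(term)
        for atoms, (terms, phi) in groups.items():
            rep.propers += float(rb_from_torsions(terms).value(phi))
        for term, phi in zip(system.torsions, torsion_phi):
            if term.kind == "improper":
                phase_deg, k, n = convert_torsion_f9(
                    term if term.kind == "proper" else _as_proper(term)
                )
                rep.impropers += k * (1.0 + math.cos(n * phi - math.radians(phase_deg)))
    else:
        for term, phi in zip(system.torsions, torsion_phi):
            phase_deg, k, n = convert_torsion_f9(
                term if term.kind == "proper" else _as_proper(term)
            )
            e = k * (1.0 + math.cos(n * phi - math.radians(phase_deg)))
            if term.kind == "improper":
                rep.impropers += e
            else:
                rep.propers += e

    pairs, derived_excl = build_pairs_exclusions(system)
    exclusions = system.exclusions if system.exclusions else derived_excl
    charges, sig, eps = _system_nonbonded_arrays(system)
    rep.lj_14, rep.coulomb_14, rep.lj_nb, rep.coulomb_nb = _nonbonded(
        coords, charges, sig, eps, pairs, exclusions, C.LJ14_SCALE, C.COULOMB14_SCALE
    )
    return rep


def _as_proper(term):
    """Impropers share the periodic functional form; reuse the f9 mapping."""
    from dataclasses import replace

    return replace(term, kind="proper", generates_14=False)


def _evaluate_gromacs_topology(gtop, coordinates) -> EnergyReport:
    if coordinates is None:
        raise StructuralError("no coordinates supplied for energy evaluation")
    coords = np.asarray(coordinates, dtype=float)  # Angstrom
    rep = EnergyReport()
    for i, j, b0, kb in gtop.bonds:
        r = _distance(coords, i, j, "bond") * C.ANGSTROM_TO_NM
        rep.bonds += 0.5 * kb * (r - b0) ** 2
    for i, j, k, th0_deg, ka in gtop.angles:
        v1 = coords[i - 1] - coords[j - 1]
        v2 = coords[k - 1] - coords[j - 1]
        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        t = math.acos(max(-1.0, min(1.0, cosang)))
        rep.angles += 0.5 * ka * (t - math.radians(th0_deg)) ** 2
    for i, j, k, l, funct, pars in gtop.dihedrals:
        phi = dihedral_angle(coords[i - 1], coords[j - 1], coords[k - 1], coords[l - 1])
        if funct in (9, 4, 1):
            phase_deg, kd, mult = pars
            e = kd * (1.0 + math.cos(mult * phi - math.radians(phase_deg)))
        elif funct == 3:
            cos_psi = math.cos(phi - math.pi)
            e = 0.0
            for coeff in reversed(pars):
                e = e * cos_psi + coeff
        else:
            raise StructuralError(f"unsupported dihedral funct {funct}")
        if funct == 4:
            rep.impropers += e
        else:
            rep.propers += e

    charges = [a[2] for a in gtop.atoms]
    sig = [gtop.type_lj[a[1]][0] for a in gtop.atoms]
    eps = [gtop.type_lj[a[1]][1] for a in gtop.atoms]
    rep.lj_14, rep.coulomb_14, rep.lj_nb, rep.coulomb_nb = _nonbonded(
        coords, charges, sig, eps, gtop.pairs, gtop.exclusions,
        gtop.fudge_lj, gtop.fudge_qq,
    )
    return rep


# ---------------------------------------------------------------------------
# conversion fidelity
# ---------------------------------------------------------------------------


@dataclass
class ConversionReport:
    """Per-term relative difference between source and re-parsed energies."""

    source: EnergyReport = field(default_factory=EnergyReport)
    converted: EnergyReport = field(default_factory=EnergyReport)
    relative_differences: dict[str, float] = field(default_factory=dict)
    tolerance: float = 1e-6
    flagged: list[str] = field(default_factory=list)

    @property
    def max_relative_difference(self) -> float:
        return max(self.relative_differences.values(), default=0.0)

    @property
    def passed(self) -> bool:
        return not self.flagged

    def to_tsv(self) -> str:
        lines = ["term\tsource_kJ_mol\tconverted_kJ_mol\trel_diff\tflag"]
        src, conv = self.source.as_dict(), self.converted.as_dict()
        for name in (*TERM_NAMES, "total"):
            flag = "FAIL" if name in self.flagged else "ok"
            lines.append(
                f"{name}\t{src[name]:.10g}\t{conv[name]:.10g}\t"
                f"{self.relative_differences[name]:.3e}\t{flag}"
            )
        return "\n".join(lines) + "\n"


def _rel_diff(a: float, b: float) -> float:
    scale = max(abs(a), abs(b))
    if scale < 1e-10:  # both essentially zero, kJ/mol
        return 0.0
    return abs(a - b) / scale


def compare_conversion(
    system: MolecularSystem,
    coordinates: Optional[np.ndarray] = None,
    engine: str = "gromacs",
    tolerance: float = 1e-6,
) -> ConversionReport:
    """Write the system for ``engine``, re-parse the output, and compare
    single-point energies term by term.

    The source system is evaluated in AMBER form; the emitted topology is
    re-read by this package's own reader and evaluated in the engine's
    form.  Any per-term relative difference above ``tolerance`` is
    flagged.  Both evaluations use the same (source) coordinates: the
    check certifies the topology, not the coordinate file precision.
    """
    from .gromacs import read_gromacs_top, write_gromacs_top

    if engine != "gromacs":
        raise ValueError(f"energy comparison is implemented for gromacs, not {engine!r}")
    if coordinates is None:
        coordinates = system.coordinates
    source = single_point_energy(system, coordinates, form="amber")
    gtop = read_gromacs_top(write_gromacs_top(system))
    converted = single_point_energy(gtop, coordinates)

    report = ConversionReport(source=source, converted=converted, tolerance=tolerance)
    src, conv = source.as_dict(), converted.as_dict()
    for name in (*TERM_NAMES, "total"):
        d = _rel_diff(src[name], conv[name])
        report.relative_differences[name] = d
        if d > tolerance:
            report.flagged.append(name)
    return report
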