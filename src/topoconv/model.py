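"""Core domain types.

``MolecularSystem`` is the single in-memory container every reader
produces and every writer consumes: atoms, coordinates, bonded terms with
resolved parameters, per-type Lennard-Jones coefficients, exclusion lists
and the periodic box.  All quantities are stored in AMBER units
(kcal/mol, Angstrom, radian, electron charge); force constants follow the
AMBER convention k*(x - x0)**2 with no 1/2 factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .constants import CHARGE_WARN_TOL, TRUNC_OCT_ANGLE_DEG, TRUNC_OCT_ANGLE_TOL
from .errors import StructuralError


@dataclass
class AtomRecord:
    """One atom: identity, type, charge (e), mass (amu)."""

    index: int  # 1-based, unique
    name: str
    amber_type: str
    partial_charge: float
    mass: float
    element: str
    residue_name: str = "MOL"
    residue_index: int = 1


@dataclass
class BondTerm:
    """Harmonic bond k*(r-r_eq)^2; k in kcal/mol/A^2, r_eq in A."""

    atoms: tuple[int, int]
    force_k: float
    r_eq: float


@dataclass
class AngleTerm:
    """Harmonic angle k*(theta-theta_eq)^2; k in kcal/mol/rad^2, theta_eq in rad."""

    atoms: tuple[int, int, int]
    force_k: float
    theta_eq: float


@dataclass
class TorsionTerm:
    """One Fourier component PK*(1+cos(n*phi - gamma)) for an atom quartet.

    ``barrier_half`` is the prmtop PK = Vn/2 in kcal/mol.  A quartet with a
    multi-term Fourier series is represented by several TorsionTerm objects
    sharing the same ``atoms``.  ``generates_14`` marks the single component
    per proper quartet whose end atoms contribute a scaled 1-4 pair.
    """

    atoms: tuple[int, int, int, int]
    barrier_half: float
    periodicity: int
    phase: float  # radians
    kind: str = "proper"  # "proper" | "improper"
    generates_14: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("proper", "improper"):
            raise ValueError(f"unknown torsion kind {self.kind!r}")
        if not 1 <= self.periodicity <= 6:
            raise ValueError(f"periodicity {self.periodicity} outside 1..6")
        if self.kind == "improper":
            self.generates_14 = False


@dataclass
class LJType:
    """Per-type 12-6 coefficients A (kcal*A^12/mol) and B (kcal*A^6/mol)."""

    type_name: str
    A: float
    B: float

    def __post_init__(self) -> None:
        if self.A < 0 or self.B < 0:
            raise ValueError("LJ A and B must be non-negative")
        if (self.A == 0) != (self.B == 0):
            raise ValueError("LJ A and B must be zero together (zero-LJ hydrogens)")


@dataclass
class BoxSpec:
    """Periodic box as inpcrd stores it: lengths (A) + angles (deg)."""

    kind: str = "none"  # none | orthorhombic | truncated_octahedron | triclinic
    lengths: Optional[tuple[float, float, float]] = None
    angles: Optional[tuple[float, float, float]] = None

    @classmethod
    def from_lengths_angles(cls, lengths, angles) -> "BoxSpec":
        """Classify a lengths+angles box line into a box kind."""
        lengths = tuple(float(x) for x in lengths)
        angles = tuple(float(x) for x in angles)
        if all(abs(a - TRUNC_OCT_ANGLE_DEG) <= TRUNC_OCT_ANGLE_TOL for a in angles):
            kind = "truncated_octahedron"
        elif all(abs(a - 90.0) <= TRUNC_OCT_ANGLE_TOL for a in angles):
            kind = "orthorhombic"
        else:
            kind = "triclinic"
        return cls(kind=kind, lengths=lengths, angles=angles)


@dataclass
class MolecularSystem:
    title: str = ""
    atoms: list[AtomRecord] = field(default_factory=list)
    coordinates: Optional[np.ndarray] = None  # (n_atoms, 3) Angstrom
    bonds: list[BondTerm] = field(default_factory=list)
    angles: list[AngleTerm] = field(default_factory=list)
    torsions: list[TorsionTerm] = field(default_factory=list)
    lj_types: list[LJType] = field(default_factory=list)
    exclusions: list[list[int]] = field(default_factory=list)  # 1-based, per atom
    box: BoxSpec = field(default_factory=BoxSpec)
    net_charge: Optional[int] = None
    # mol2 route only: (i, j, order) connectivity before parameterisation
    bond_orders: list[tuple[int, int, str]] = field(default_factory=list)

    # -- convenience accessors -------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def lj_type_of(self, atom_index: int) -> LJType:
        """LJ type for a 1-based atom index."""
        type_name = self.atoms[atom_index - 1].amber_type
        for lj in self.lj_types:
            if lj.type_name == type_name:
                return lj
        raise StructuralError(f"no LJ type registered for atom type {type_name!r}")

    def total_charge(self) -> float:
        return float(sum(a.partial_charge for a in self.atoms))

    # -- invariants ------------------------------------------------------------

    def validate(self) -> None:
        """Check the container invariants; raise StructuralError on violation."""
        n = self.n_atoms
        seen = set()
        for a in self.atoms:
            if a.index < 1 or a.index in seen:
                raise StructuralError(f"atom index {a.index} invalid or duplicated")
            seen.add(a.index)
            if a.mass <= 0:
                raise StructuralError(f"atom {a.index} has non-positive mass")
        if self.coordinates is not None:
            if self.coordinates.shape != (n, 3):
                raise StructuralError(
                    f"coordinate shape {self.coordinates.shape} != ({n}, 3)"
                )
            if not np.all(np.isfinite(self.coordinates)):
                raise StructuralError("non-finite coordinates")
        for term in (*self.bonds, *self.angles, *self.torsions):
            for i in term.atoms:
                if not 1 <= i <= n:
                    raise StructuralError(f"term {term} references atom {i} outside 1..{n}")
        for b in self.bonds:
            if b.atoms[0] == b.atoms[1]:
                raise StructuralError(f"bond {b.atoms} joins an atom to itself")
            if b.r_eq <= 0 or b.force_k < 0:
                raise StructuralError(f"bond {b.atoms} has invalid parameters")
        for ang in self.angles:
            if len(set(ang.atoms)) != 3:
                raise StructuralError(f"angle {ang.atoms} atoms not pairwise distinct")
            if not 0 < ang.theta_eq <= math.pi + 1e-12:
                raise StructuralError(f"angle {ang.atoms} theta_eq outside (0, pi]")
        if self.net_charge is not None:
            if abs(self.total_charge() - self.net_charge) > CHARGE_WARN_TOL:
                raise StructuralError(
                    f"partial charges sum to {self.total_charge():.4f} but "
                    f"net_charge is {self.net_charge}"
                )
        if self.exclusions:
            if len(self.exclusions) != n:
                raise StructuralError("exclusion list count != atom count")
            for i, excl in enumerate(self.exclusions, start=1):
                for j in excl:
                    if i not in self.exclusions[j - 1]:
                        raise StructuralError(f"exclusion ({i},{j}) not symmetric")


@dataclass
class ParameterSource:
    """Ordered lookup tables for one force-field source (e.g. GAFF, a frcmod).

    Keys are canonicalised atom-type tuples: bonds and angles are
    order-independent (stored in canonical orientation), torsion keys match
    forward or reversed, and the wildcard type ``X`` is allowed in the outer
    torsion positions.  Torsion values are lists of
    (barrier_half, phase_rad, periodicity) tuples — a full Fourier series.
    """

    label: str
    mass_table: dict = field(default_factory=dict)  # type -> (mass, element)
    bond_table: dict = field(default_factory=dict)  # (t1,t2) -> (k, r_eq)
    angle_table: dict = field(default_factory=dict)  # (t1,t2,t3) -> (k, theta_eq_rad)
    torsion_table: dict = field(default_factory=dict)  # (t1..t4) -> [(pk, phase, n), ...]
    improper_table: dict = field(default_factory=dict)  # (t1..t4) -> [(pk, phase, n)]
    lj_table: dict = field(default_factory=dict)  # type -> (rmin_half_A, eps_kcal)

    @staticmethod
    def bond_key(t1: str, t2: str) -> tuple[str, str]:
        return (t1, t2) if t1 <= t2 else (t2, t1)

    @staticmethod
    def angle_key(t1: str, t2: str, t3: str) -> tuple[str, str, str]:
        return (t1, t2, t3) if t1 <= t3 else (t3, t2, t1)

    @staticmethod
    def torsion_key(t1: str, t2: str, t3: str, t4: str) -> tuple[str, str, str, str]:
        fwd = (t1, t2, t3, t4)
        rev = (t4, t3, t2, t1)
        return fwd if fwd <= rev else rev
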