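"""Deterministic toy molecular systems.

Each generator builds a chemically sane, fully parameterised
:class:`MolecularSystem` *through the same machinery real input takes*:
connectivity plus an frcmod-style parameter text resolved with
:func:`topoconv.params.resolve_parameters`.  The serialised prmtop /
inpcrd / mol2 / frcmod texts it returns are therefore mutually consistent,
so every conversion path can be tested without AmberTools.

The four standard systems:

* ``water_tip3p`` — one TIP3P water (recognition + zero-LJ hydrogens)
* ``methane``     — CH4 (angles, no torsions)
* ``chain4``      — hydrogen peroxide H-O-O-H (exactly one proper torsion,
  exactly one 1-4 pair)
* ``ring6``       — cyclohexane-like C6 ring (six torsion quartets whose
  1-4 pairs deduplicate to the three para pairs; two-component Fourier
  series per quartet)

Extra helpers beyond the standard names: :func:`formaldehyde` (one
improper) and :func:`water_dimer` (plain nonbonded interactions).
"""

from __future__ import annotations

import math

import numpy as np

from .amber_io import (
    parameter_source_from_text,
    write_frcmod,
    write_inpcrd,
    write_mol2,
    write_prmtop,
)
from .model import AtomRecord, MolecularSystem
from .params import resolve_parameters

TOY_SYSTEM_NAMES = ("water_tip3p", "methane", "chain4", "ring6")

_JITTER_ANGSTROM = 0.01  # deterministic per-seed coordinate noise


def _place_by_internal(a, b, c, r, theta_deg, phi_deg):
    """NeRF placement: new atom at distance r from a, angle theta (new-a-b),
    dihedral phi (new-a-b-c)."""
    theta = math.radians(theta_deg)
    phi = math.radians(phi_deg)
    ab = b - a
    bc = c - b
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    ab_u = ab / np.linalg.norm(ab)
    m = np.cross(n, ab_u)
    d = np.array(
        [
            -r * math.cos(theta),
            r * math.sin(theta) * math.cos(phi),
            r * math.sin(theta) * math.sin(phi),
        ]
    )
    frame = np.column_stack([ab_u, m, n])
    return a + frame @ d


# -- per-system definitions --------------------------------------------------

# TIP3P: sigma 3.15061 A -> Rmin/2 = sigma * 2^(1/6) / 2 = 1.76826 A
_WATER_FRCMOD = """toy TIP3P water parameters

MASS
OW  16.00
HW   1.008

BOND
OW-HW   553.0000    0.95720
HW-HW     0.0000    1.51390

ANGLE
HW-OW-HW   100.0000   104.5200

DIHE

IMPROPER

NONBON
  OW   1.768255   0.1521000
  HW   0.000000   0.0000000
"""

_METHANE_FRCMOD = """toy GAFF-like methane parameters

MASS
c3  12.01
hc   1.008

BOND
c3-hc   337.3000    1.09300

ANGLE
hc-c3-hc    39.4300   108.3500

DIHE

IMPROPER

NONBON
  c3   1.908000   0.1094000
  hc   1.487000   0.0157000
"""

_CHAIN4_FRCMOD = """toy hydrogen peroxide parameters

MASS
oh  16.00
ho   1.008

BOND
oh-ho   369.6000    0.97400
oh-oh   217.9000    1.46900

ANGLE
ho-oh-oh    47.5000    98.7000

DIHE
ho-oh-oh-ho   1     1.400000    180.000    2.0

IMPROPER

NONBON
  oh   1.721000   0.2104000
  ho   0.000000   0.0000000
"""

_RING6_FRCMOD = """toy six-ring parameters

MASS
c3  12.01

BOND
c3-c3   303.1000    1.53500

ANGLE
c3-c3-c3    63.2100   110.6300

DIHE
X -c3-c3-X    1     0.156000      0.000   -3.0
X -c3-c3-X    1     0.200000    180.000    2.0

IMPROPER

NONBON
  c3   1.908000   0.1094000
"""

_FORMALDEHYDE_FRCMOD = """toy formaldehyde parameters

MASS
c   12.01
o   16.00
ha   1.008

BOND
c -o    648.0000    1.21400
c -ha   340.0000    1.09000

ANGLE
ha-c -o     50.0000   122.0000
ha-c -ha    39.0000   116.0000

DIHE

IMPROPER
X -X -c -o    1.100000    180.000    2.0

NONBON
  c    1.908000   0.0860000
  o    1.661200   0.2100000
  ha   1.459000   0.0150000
"""


def _water_geometry():
    r, half = 0.9572, math.radians(104.52 / 2.0)
    return np.array(
        [
            [0.0, 0.0, 0.0],
            [r * math.sin(half), r * math.cos(half), 0.0],
            [-r * math.sin(half), r * math.cos(half), 0.0],
        ]
    )


def _build_water(residue_index: int = 1, offset=(0.0, 0.0, 0.0)):
    atoms = [
        AtomRecord(1, "O", "OW", -0.834, 16.00, "O", "WAT", residue_index),
        AtomRecord(2, "H1", "HW", 0.417, 1.008, "H", "WAT", residue_index),
        AtomRecord(3, "H2", "HW", 0.417, 1.008, "H", "WAT", residue_index),
    ]
    coords = _water_geometry() + np.asarray(offset)
    bond_orders = [(1, 2, "1"), (1, 3, "1")]
    return atoms, coords, bond_orders


def _methane_spec():
    atoms = [
        AtomRecord(1, "C1", "c3", -0.1048, 12.01, "C"),
        AtomRecord(2, "H1", "hc", 0.0262, 1.008, "H"),
        AtomRecord(3, "H2", "hc", 0.0262, 1.008, "H"),
        AtomRecord(4, "H3", "hc", 0.0262, 1.008, "H"),
        AtomRecord(5, "H4", "hc", 0.0262, 1.008, "H"),
    ]
    d = 1.093 / math.sqrt(3.0)
    coords = np.array(
        [
            [0.0, 0.0, 0.0],
            [d, d, d],
            [d, -d, -d],
            [-d, d, -d],
            [-d, -d, d],
        ]
    )
    bond_orders = [(1, 2, "1"), (1, 3, "1"), (1, 4, "1"), (1, 5, "1")]
    return atoms, coords, bond_orders, _METHANE_FRCMOD


def _chain4_spec():
    atoms = [
        AtomRecord(1, "H1", "ho", 0.400, 1.008, "H"),
        AtomRecord(2, "O1", "oh", -0.400, 16.00, "O"),
        AtomRecord(3, "O2", "oh", -0.400, 16.00, "O"),
        AtomRecord(4, "H2", "ho", 0.400, 1.008, "H"),
    ]
    o1 = np.array([0.0, 0.0, 0.0])
    o2 = np.array([1.469, 0.0, 0.0])
    # H1 in-plane at the equilibrium angle; H2 at a 111.8 deg skew dihedral
    h1 = _place_by_internal(o1, o2, o2 + np.array([0.0, 1.0, 0.0]), 0.974, 98.7, 0.0)
    h2 = _place_by_internal(o2, o1, h1, 0.974, 98.7, 111.8)
    coords = np.array([h1, o1, o2, h2])
    bond_orders = [(1, 2, "1"), (2, 3, "1"), (3, 4, "1")]
    return atoms, coords, bond_orders, _CHAIN4_FRCMOD


def _ring6_spec():
    atoms = [AtomRecord(i, f"C{i}", "c3", 0.0, 12.01, "C") for i in range(1, 7)]
    r_bond = 1.535
    radius = r_bond  # hexagon edge equals circumradius
    coords = np.array(
        [
            [radius * math.cos(k * math.pi / 3.0), radius * math.sin(k * math.pi / 3.0), 0.0]
            for k in range(6)
        ]
    )
    bond_orders = [(i, i % 6 + 1, "1") for i in range(1, 7)]
    return atoms, coords, bond_orders, _RING6_FRCMOD


def _formaldehyde_spec():
    atoms = [
        AtomRecord(1, "C1", "c", 0.4500, 12.01, "C"),
        AtomRecord(2, "O1", "o", -0.5730, 16.00, "O"),
        AtomRecord(3, "H1", "ha", 0.0615, 1.008, "H"),
        AtomRecord(4, "H2", "ha", 0.0615, 1.008, "H"),
    ]
    coords = np.array(
        [
            [0.0, 0.0, 0.0],
            [0.0, 1.214, 0.0],
            [0.944, -0.545, 0.0],
            [-0.944, -0.545, 0.0],
        ]
    )
    bond_orders = [(1, 2, "2"), (1, 3, "1"), (1, 4, "1")]
    return atoms, coords, bond_orders, _FORMALDEHYDE_FRCMOD


def _assemble(
    title: str,
    atoms,
    coords: np.ndarray,
    bond_orders,
    frcmod_text: str,
    seed: int,
) -> tuple[MolecularSystem, str]:
    rng = np.random.default_rng(seed)
    coords = np.asarray(coords, dtype=float) + rng.normal(
        0.0, _JITTER_ANGSTROM, size=(len(atoms), 3)
    )
    system = MolecularSystem(
        title=title,
        atoms=list(atoms),
        coordinates=coords,
        bond_orders=list(bond_orders),
    )
    source = parameter_source_from_text(frcmod_text, label=f"frcmod:{title}")
    resolve_parameters(system, [source])
    return system, write_frcmod(source)


def generate_toy_system(name: str, seed: int = 42):
    """Build a named toy system and its serialised file texts.

    Returns ``(system, texts)`` where ``texts`` maps ``prmtop``,
    ``inpcrd``, ``mol2`` and ``frcmod`` to deterministic file contents.
    Identical (name, seed) always yields identical bytes.
    """
    if name == "water_tip3p":
        atoms, coords, bond_orders = _build_water()
        spec = (atoms, coords, bond_orders, _WATER_FRCMOD)
    elif name == "methane":
        spec = _methane_spec()
    elif name == "chain4":
        spec = _chain4_spec()
    elif name == "ring6":
        spec = _ring6_spec()
    else:
        raise ValueError(
            f"unknown toy system {name!r}; valid names: {', '.join(TOY_SYSTEM_NAMES)}"
        )
    atoms, coords, bond_orders, frcmod_text = spec
    system, frcmod_out = _assemble(name, atoms, coords, bond_orders, frcmod_text, seed)
    texts = {
        "prmtop": write_prmtop(system),
        "inpcrd": write_inpcrd(system.coordinates, system.box, title=name),
        "mol2": write_mol2(system),
        "frcmod": frcmod_out,
    }
    return system, texts


def formaldehyde(seed: int = 42) -> MolecularSystem:
    """Extra fixture: planar H2C=O with one improper torsion."""
    atoms, coords, bond_orders, frcmod_text = _formaldehyde_spec()
    system, _ = _assemble("formaldehyde", atoms, coords, bond_orders, frcmod_text, seed)
    return system


def water_dimer(seed: int = 42, separation: float = 2.8) -> MolecularSystem:
    """Extra fixture: two TIP3P waters ``separation`` Angstrom apart (O-O).

    The two molecules are not bonded, so their cross interactions exercise
    the plain (unscaled) nonbonded energy path.
    """
    a1, c1, b1 = _build_water(residue_index=1)
    a2, c2, b2 = _build_water(residue_index=2, offset=(separation, 0.0, 0.0))
    for k, a in enumerate(a2):
        a.index = k + 4
    atoms = a1 + a2
    coords = np.vstack([c1, c2])
    bond_orders = b1 + [(i + 3, j + 3, o) for i, j, o in b2]
    system, _ = _assemble("water_dimer", atoms, coords, bond_orders, _WATER_FRCMOD, seed)
    return system
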