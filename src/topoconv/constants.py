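"""Physical constants and unit-conversion factors.

Every unit boundary in the package goes through this module so that the
writers and the energy oracle can never drift apart.  Internal storage is
always in AMBER units (kcal/mol, Angstrom, radian, electron charge);
conversion to engine units (kJ/mol, nm, degree) happens only in the
parameter engine and the writers.
"""

import math

# prmtop stores partial charges premultiplied by sqrt of the Coulomb
# constant in kcal*A/(mol*e^2); divide on read, multiply on write.
AMBER_ELECTROSTATIC = 18.2223

# Coulomb constant, kcal*A/(mol*e^2).  Consistency: AMBER_ELECTROSTATIC**2
# equals this value to ~1e-7 relative (asserted in the test suite).
COULOMB_KCAL = 332.0522173

KCAL_TO_KJ = 4.184
ANGSTROM_TO_NM = 0.1

# Coulomb constant in kJ*nm/(mol*e^2), derived so the two unit systems are
# numerically identical.
COULOMB_KJ_NM = COULOMB_KCAL * KCAL_TO_KJ * ANGSTROM_TO_NM

# AMBER-family 1-4 scaling: LJ divided by 2.0, Coulomb divided by 1.2.
LJ14_SCALE = 0.5
COULOMB14_SCALE = 1.0 / 1.2

# All box angles of a truncated octahedron, degrees: arccos(-1/3).
TRUNC_OCT_ANGLE_DEG = math.degrees(math.acos(-1.0 / 3.0))
TRUNC_OCT_ANGLE_TOL = 1e-4  # degrees, classification tolerance

# Net-charge sanity thresholds (electron charges).
CHARGE_WARN_TOL = 0.01
CHARGE_ERROR_TOL = 0.1

# Covalent-distance sanity filter bounds, Angstrom.
BOND_MIN_ANGSTROM = 0.5
BOND_MAX_ANGSTROM = 3.0

# Water-model recognition tolerance: absolute on charges (e),
# relative on LJ sigma/epsilon.
WATER_MATCH_TOL = 1e-3

# Nonbonded evaluation refuses overlapping atoms closer than this (Angstrom).
OVERLAP_MIN_ANGSTROM = 1e-6

# Minimum-image-free default clearance when building a box from a bare
# point cloud, nm per side.
DEFAULT_CLEARANCE_NM = 1.0
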