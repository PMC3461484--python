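# Methods

## The conversion model

`topoconv` treats a parameterised molecule as a single in-memory object
(`MolecularSystem`) holding atoms, coordinates, bonded terms with
resolved parameters, per-type Lennard-Jones coefficients, exclusion
lists and the periodic box.  All internal storage is in AMBER units —
kcal/mol, Ångström, radian, electron charge — with force constants in
the AMBER convention `k (x − x₀)²` (no ½).  Unit and convention changes
happen at exactly one boundary, the parameter engine (`params.py`), so
the writers and the energy oracle can never disagree about a factor of
4.184 or 2.  The pinned constants:

| constant | value | role |
|---|---|---|
| charge scale | 18.2223 | prmtop stores q·18.2223; its square is the Coulomb constant |
| Coulomb constant | 332.0522173 kcal·Å·mol⁻¹·e⁻² | nonbonded electrostatics |
| kcal→kJ | 4.184 | all energy output |
| LJ 1-4 scale | 0.5 | AMBER-family convention |
| Coulomb 1-4 scale | 1/1.2 | AMBER-family convention |
| box angle | arccos(−1/3) ≈ 109.471221° | truncated-octahedron recognition (±10⁻⁴ deg) |

## Functional-form mappings

**Harmonics.** bond: `(r₀ Å, k kcal/Å²) → (r₀·0.1 nm, 2·4.184·100·k
kJ/nm²)`; angle: `(θ₀ rad, k kcal/rad²) → (θ₀ deg, 2·4.184·k kJ/rad²)`.
The factor 2 bridges AMBER's `k(x−x₀)²` to the target `½k(x−x₀)²`.

**Torsions.** Each prmtop dihedral entry is one Fourier component
`PK(1+cos(nφ−γ))` with `PK = Vₙ/2`.  Emission is GROMACS function 9 —
one line per component, never combined, so multi-term quartets keep the
native AMBER analytic form; impropers go out as periodic function 4.
prmtop sign flags are decoded as: negative fourth index ⇒ improper,
negative third index ⇒ no 1-4 pair generated; output orders propers
before impropers, each preserving input order.  When a quartet's atoms
1 would need a sign flag (index 0 cannot carry one) the quartet is
reversed; this is energy-invariant for phases 0/π, the only phases AMBER
force fields use.

**Ryckaert–Bellemans.** The closed-form Fourier→RB map is implemented
for phases restricted to {0, π}, using the signed barrier `gₙ = Vₙ·cos γₙ`
under the ψ = φ − 180° convention:

```
C0 = Σ Vₙ/2 − g₂/2 + g₄/2      C1 = −g₁/2 + 3g₃/2
C2 = g₂ − 4g₄                  C3 = −2g₃
C4 = 4g₄                       C5 = 0
```

This generalisation reduces to the familiar conversion table under the
common AMBER phase pattern (γ=0 for n∈{1,3}, γ=π for n∈{2,4}) and is
verified against dense-grid evaluation (360 points, 100 random series,
agreement ≤ 10⁻⁹ kJ/mol).  Components with other phases must stay in
function-9 form; RB output is opt-in, function 9 is the default path.

**Lennard-Jones.** `σ = (A/B)^{1/6}·0.1 nm`, `ε = B²/(4A)·4.184 kJ/mol`;
the inverse `A = 4εσ¹²`, `B = 4εσ⁶` is a round-trip identity (≤10⁻¹⁰
relative over 1000 random inputs).  Atoms with A = B = 0 (polar
hydrogens) map to (0, 0) in both directions.  Pair coefficients use
Lorentz–Berthelot combining (arithmetic σ, geometric ε), equivalent to
AMBER's combining on Rmin.  CHARMM output converts
`Rmin/2 = σ·2^{1/6}/2` and writes −ε per its convention.

**1-4 pairs and exclusions.**  Candidate pairs are the end atoms of
proper torsions flagged as 1-4-generating; a candidate survives only if
its bond-graph distance is exactly 3.  This graph rule — rather than raw
torsion end-atom listing — makes ring deduplication principled: a
six-ring's six torsion paths yield exactly its three para pairs, and a
four-ring yields none (every candidate is also 1-2 or 1-3 connected).
Exclusions are all 1-2, 1-3 and 1-4 neighbours, kept symmetric.

**Boxes.**  inpcrd length+angle lines are classified by angle
(109.4712° → truncated octahedron, 90° → orthorhombic, else triclinic)
and converted to triclinic row vectors via the standard crystallographic
construction; the truncated-octahedron case uses the exact closed form
(the printed inpcrd angle is a rounded arccos(−1/3)).  With no box, a
diagonal cell is built from the coordinate bounding extent plus twice a
clearance (default 1.0 nm per side, configurable).

**Water.**  TIP3P and SPC/E are recognised by matching charges (±10⁻³ e)
and oxygen σ/ε (10⁻³ relative) against a bundled plain-text table
(`data/water_models.txt`, literature values cited inline) — deliberately
not by residue name, which renaming destroys.

**Net charge.**  The charge sum is rounded to the nearest integer;
deviation above 0.01 e warns, above 0.1 e is an error (automatic charge
guessing is unreliable at that point and the user must state the charge).

**Geometry filter.**  Before parameterisation every covalent bond length
is checked against a 0.5 Å minimum and 3.0 Å maximum; violations abort
the run, naming each offending bond and rule.  This mirrors the sanity
window used when screening large deposited-ligand sets, where corrupt
coordinates are common.

**Parameter fallback.**  Parameter sources (frcmod/parm-dat tables) form
an ordered chain; every key is taken from the first source holding it,
recording provenance per term — this implements the AMBER99SB-first,
GAFF-fallback behaviour.  Within a source, torsion lookup tries exact
keys, then single-wildcard (`X` in one outer position), then
double-wildcard.  Improper assignment adds a term only for atoms with
exactly three neighbours whose types match some source's improper key;
the canonical atom ordering places the central atom third.

## The energy oracle

`single_point_energy` evaluates bonds, angles, propers, impropers,
scaled 1-4 LJ/Coulomb and plain nonbonded terms at fixed coordinates,
with no cutoff and no periodicity: the oracle certifies topology
conversion, not simulation realism, and on small vacuum systems the full
pair sum is exact and engine-independent.  Three algebraically identical
forms are implemented (AMBER; GROMACS function-9; GROMACS RB), and
`compare_conversion` writes a system to GROMACS text, re-parses it with
the package's own reader, evaluates both representations *at the same
coordinates* and flags any per-term relative difference above 10⁻⁶.
Dihedral angles use the signed IUPAC convention (cis = 0).  Relative
differences use `|a−b|/max(|a|,|b|)`, with terms below 10⁻¹⁰ kJ/mol
treated as equal (both zero).  Overlapping nonbonded atoms (< 10⁻⁶ Å)
are an error naming the pair.

## Numerical and formatting choices

* Writers format parameters with 12 significant digits.  Six digits —
  a common choice — would be lossy here: a 10⁻⁶ relative error on σ is
  amplified ~12× through r⁻¹², violating the 10⁻⁶ energy-preservation
  bound the package promises.  Output remains deterministic (pure
  functions of system + settings; byte-identical on re-invocation).
* GROMACS atom types get a short configurable prefix (default `x`) so
  molecule-local GAFF/AMBER type names cannot collide with a force field
  the topology is included into; collisions after prefixing are an error.
* prmtop emission uses a fixed version stamp, so fixture bytes never
  depend on the wall clock.
* frcmod duplicate keys: last entry wins, with a warning.  Torsion
  continuation lines (negative periodicity) fold into one multi-term
  series; a series ending on a negative periodicity is a structural
  error.
* CNS output uppercases all atom and type names (mixed case breaks CNS);
  uppercase collisions between distinct types are an error, as are
  conflicting parameter values for one type key.  Because no CNS/CHARMM
  reader exists in-repo, those dialects are checked by a line-grammar
  validator, while the physics of the shared conversion path is
  certified through the GROMACS energy round trip.

## The toy-system generator

The fixture generator builds four small systems *through the same
machinery real input takes* — connectivity plus an frcmod text, resolved
with the fallback engine — so the serialised prmtop/inpcrd/mol2/frcmod
texts are mutually consistent and every route can be exercised without
AmberTools:

* `water_tip3p` — one TIP3P water: model recognition, zero-LJ hydrogens;
* `methane` — CH₄ with GAFF-like types: angles, no torsions;
* `chain4` — hydrogen peroxide H-O-O-H: exactly one single-component
  proper torsion and one 1-4 pair;
* `ring6` — a cyclohexane-like C₆ ring with two Fourier components per
  ring torsion: multi-term emission and para-pair deduplication.

Two extra builders cover what those four cannot: `formaldehyde` (an
improper on the sp² carbon) and `water_dimer` (plain nonbonded pairs
between unbonded molecules).  Coordinates are ideal geometries plus
deterministic per-seed Gaussian jitter (σ = 0.01 Å), keeping bond
lengths chemically sane (0.9–1.6 Å) while making every energy term
generically nonzero.  Parameter values are GAFF-like literature-scale
numbers chosen once for realism.

What the generator does *not* emulate: conformational diversity, charge
derivation (charges are fixed inputs), large molecules, elements outside
H/C/N/O/S/P/halogens, or solvated boxes at scale.  Passing tests
therefore certify the conversion machinery — parsing, unit algebra,
bookkeeping, emission — not the chemical quality of any force field.

## Known limitations

* NetCDF restarts, CHAMBER-style prmtop variants, polarisable blocks and
  residue-library (off/lib) files are out of scope.
* No Urey–Bradley terms, CMAP, virtual sites or per-system 1-4 scale
  factors (SCEE/SCNB are written as the AMBER constants, not read back).
* The GROMACS reader parses the dialect this package writes (plus RB
  dihedrals), not arbitrary hand-written topologies.
* Gasteiger/AM1-BCC charge derivation is delegated to external
  antechamber when present; without it the `user` charge route (MOL2
  column) is the self-contained path.
* Improper atom ordering follows this package's canonical rule (central
  atom third); other converters order improper quartets differently,
  which changes nothing for the 0/π phases in actual use.
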