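# topoconv

Convert AMBER-family small-molecule topologies and parameters into
correct all-atom inputs for **GROMACS**, **CNS/XPLOR** and **CHARMM** —
and prove, for every conversion, that the potential energy survived the
trip.

## The problem

Molecular-dynamics and NMR structure-calculation engines each speak their
own topology dialect.  The AMBER ecosystem (ANTECHAMBER, leap, GAFF)
produces excellent automatic parameterisations of arbitrary organic
molecules, but its output — the `prmtop`/`inpcrd` pair, frcmod parameter
files, MOL2 files with derived charges — must be re-expressed before
GROMACS, CNS or CHARMM can use it.  The translation is all conventions:

* AMBER harmonic terms are `k (x − x₀)²`; GROMACS wants `½ k (x − x₀)²`
  in kJ/mol and nm, so bond constants pick up a factor
  `2 × 4.184 × 100` and angle constants `2 × 4.184`.
* AMBER torsions are Fourier components `(Vₙ/2)(1 + cos(nφ − γ))`.
  Older converters collapsed each quartet into one Ryckaert–Bellemans
  polynomial `Σ Cₙ cosⁿψ`; `topoconv` keeps the native AMBER analytic
  form (GROMACS dihedral function 9, one line per component, impropers as
  periodic function 4) and offers the exact RB mapping where the phases
  permit it (γ ∈ {0, π}).
* Lennard-Jones tables switch between `A/r¹² − B/r⁶` coefficients and
  (σ, ε), with `σ = (A/B)^{1/6}`, `ε = B²/4A`.
* 1-4 interactions (atoms exactly three bonds apart) must be enumerated
  explicitly for GROMACS and scaled the AMBER way (LJ ÷ 2, Coulomb ÷ 1.2);
  rings make naive enumeration double-count.
* Truncated-octahedron boxes stored as lengths + 109.4712° angles become
  triclinic vectors `a=(d,0,0)`, `b=(−d/3, 2√2d/3, 0)`,
  `c=(−d/3, −√2d/3, √6d/3)`.
* CNS needs uppercase names and kcal/Å parameter statements; CHARMM wants
  rtf/prm files with `Rmin/2 = σ·2^{1/6}/2`.

Every one of these steps is a chance to silently corrupt a force field.
`topoconv`'s central design decision is that conversion is **certified**:
a built-in vacuum single-point energy evaluator computes
bond/angle/torsion/1-4/nonbonded energies of the source system (AMBER
form) and of the re-parsed emitted topology (GROMACS form) and demands
term-by-term agreement to 1 part in 10⁶.

## Worked example

Generate a deterministic toy system (hydrogen peroxide, H-O-O-H: 4 atoms,
3 bonds, 2 angles, one proper torsion, one 1-4 pair) and convert it:

```sh
topoconv fixture chain4 -o .
topoconv convert -i chain4.mol2 --frcmod chain4.frcmod --outputs gromacs,cns,charmm -o chain4_out
```

```
output folder: chain4_out
net charge: 0
fidelity: max per-term relative difference 3.999e-13 (ok)
```

The folder holds `chain4.top`/`chain4.gro` (GROMACS), CNS
topology/parameter/run-input files, CHARMM rtf/prm, a `manifest.json` and
the per-term fidelity report.  The single-point energy report for the
same system:

```sh
topoconv energy -p chain4.prmtop -x chain4.inpcrd
```

```
term        energy_kJ_mol
bonds       0.3218805484
angles      40.12013868
propers     10.01776973
impropers   0
lj_14       0
coulomb_14  94.48537387
lj_nb       0
coulomb_nb  0
total       144.9451628
```

Reading: bonds and angles sit near their equilibria (small strain from
the fixture's deterministic coordinate jitter), the single 2-fold torsion
contributes ~10 kJ/mol at the ~112° dihedral, and the dominant term is
the scaled 1-4 Coulomb repulsion between the two +0.4 e hydrogens.  The
hydrogens carry zero Lennard-Jones parameters (standard for
hydroxyl hydrogens), so `lj_14` is exactly zero.

The pure topology-converter route (no external tools at all):

```sh
topoconv amb2gmx -p system.prmtop -x system.inpcrd
```

recognises TIP3P/SPC-E water by charges and oxygen LJ parameters (not by
residue names), converts truncated-octahedron box lines to triclinic
vectors, builds a box from the coordinate extent plus a 1 nm clearance
when the inpcrd has none, and appends the same fidelity report.

## Layout

```
src/topoconv/
  model.py      core types (MolecularSystem, TorsionTerm, ParameterSource, ...)
  amber_io.py   prmtop / inpcrd / MOL2 / frcmod / parm-dat readers and writers
  params.py     unit, functional-form, box, water, 1-4 and fallback logic
  energy.py     single-point evaluator + conversion-fidelity comparison
  gromacs.py    .top/.gro writer and the re-parsing reader
  cns.py        CNS topology/parameter/run-input writer + grammar validator
  charmm.py     CHARMM rtf/prm writer + grammar validator
  fixtures.py   deterministic toy systems (water, methane, peroxide, 6-ring)
  pipeline.py   end-to-end conversion runs
  cli.py        `topoconv` command group
docs/methods.md  model, conventions, numerical choices, limitations
```
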