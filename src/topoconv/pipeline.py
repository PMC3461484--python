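"""End-to-end conversion pipelines behind the command-line interface.

Two routes exist:

* ``run_convert`` — small-molecule route: MOL2 (or PDB/MDL via OpenBabel
  when installed) plus frcmod/parm-dat parameter sources, resolved with
  the ordered fallback chain, then written for the requested engines.
* ``run_amb2gmx`` — topology-converter route: prmtop + inpcrd in,
  GROMACS .top/.gro out.  Needs nothing beyond the Python interpreter.

Every run ends with the conversion-fidelity check (source vs re-parsed
single-point energies) whenever GROMACS output was requested; the report
lands next to the emitted files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import constants as C
from .amber_io import read_frcmod, read_inpcrd, read_mol2, read_prmtop
from .charmm import validate_charmm, write_charmm
from .cns import validate_cns, write_cns
from .energy import ConversionReport, compare_conversion
from .errors import (
    GeometryError,
    NetChargeError,
    StructuralError,
    TopoconvError,
)
from .external import DEFAULT_TIMEOUT_S, invoke_external
from .gromacs import write_gro, write_gromacs_top
from .model import MolecularSystem, ParameterSource
from .params import (
    convert_box,
    guess_net_charge,
    recognize_water,
    resolve_parameters,
    validate_geometry,
)


@dataclass
class RunConfig:
    """Everything one conversion run needs."""

    input_path: Optional[Path] = None
    net_charge: Optional[int] = None
    forcefield_mode: str = "gaff"  # gaff | amber
    charge_mode: str = "user"  # bcc | gas | user
    outputs: tuple[str, ...] = ("gromacs",)
    parameter_files: tuple[Path, ...] = ()
    timeout: float = DEFAULT_TIMEOUT_S
    seed: int = 42
    clearance: float = C.DEFAULT_CLEARANCE_NM
    out_dir: Optional[Path] = None
    engine_binaries: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.timeout <= 0:
            raise ValueError("timeout must be positive")
        for engine in self.outputs:
            if engine not in ("gromacs", "cns", "charmm"):
                raise ValueError(f"unknown output engine {engine!r}")


@dataclass
class RunReport:
    out_dir: Path
    files: dict[str, Path] = field(default_factory=dict)
    water_model: Optional[str] = None
    net_charge: int = 0
    fidelity: Optional[ConversionReport] = None
    provenance: dict = field(default_factory=dict)
    messages: list[str] = field(default_factory=list)


def _output_folder(config: RunConfig, base: str) -> Path:
    if config.out_dir is not None:
        folder = Path(config.out_dir)
    else:
        folder = Path(f"{base}.ff{config.forcefield_mode}")
    folder.mkdir(parents=True, exist_ok=True)
    return folder


def _load_input(config: RunConfig) -> MolecularSystem:
    path = Path(config.input_path)
    if not path.exists():
        raise StructuralError(f"input file {path} does not exist")
    suffix = path.suffix.lower()
    if suffix == ".mol2":
        return read_mol2(path)
    if suffix in (".pdb", ".mdl", ".mol", ".sdf"):
        # PDB/MDL input needs an external conversion capability
        result = invoke_external(
            "obabel",
            [path.name, "-O", "input.mol2"],
            timeout=config.timeout,
            binary_path=config.engine_binaries.get("obabel"),
            input_files={path.name: path},
            output_roles={"mol2": "input.mol2"},
        )
        return read_mol2(result.files["mol2"])
    raise StructuralError(
        f"unsupported input format {suffix!r}: expected MOL2, PDB or MDL"
    )


def _obtain_charges(system: MolecularSystem, config: RunConfig) -> None:
    if config.charge_mode == "user":
        # charges come from the MOL2 charge column, already on the atoms
        return
    if config.charge_mode in ("bcc", "gas"):
        # both delegate to antechamber (sqm-based AM1-BCC or Gasteiger);
        # without the binary this is a capability error, not an approximation
        import tempfile

        from .amber_io import write_mol2

        scratch = Path(tempfile.mkdtemp(prefix="topoconv_charges_"))
        write_mol2(system, scratch / "input.mol2")
        result = invoke_external(
            "antechamber",
            ["-fi", "mol2", "-i", "input.mol2", "-fo", "mol2", "-o", "charged.mol2",
             "-c", config.charge_mode, "-nc", str(config.net_charge or 0), "-dr", "no"],
            timeout=config.timeout,
            binary_path=config.engine_binaries.get("antechamber"),
            workdir=scratch,
            output_roles={"mol2": "charged.mol2"},
        )
        charged = read_mol2(result.files["mol2"])
        if charged.n_atoms != system.n_atoms:
            raise StructuralError(
                "antechamber returned a different atom count than the input"
            )
        for atom, src in zip(system.atoms, charged.atoms):
            atom.partial_charge = src.partial_charge
        return
    raise ValueError(f"unknown charge mode {config.charge_mode!r}")


def _check_net_charge(system: MolecularSystem, config: RunConfig) -> int:
    guessed = guess_net_charge(a.partial_charge for a in system.atoms)
    if config.net_charge is not None and guessed != config.net_charge:
        raise NetChargeError(
            f"-n gave net charge {config.net_charge} but partial charges sum to "
            f"{system.total_charge():.4f} (nearest integer {guessed})"
        )
    system.net_charge = guessed
    return guessed


def _write_engines(
    system: MolecularSystem, config: RunConfig, folder: Path, base: str,
    report: RunReport,
) -> None:
    if "gromacs" in config.outputs:
        top = write_gromacs_top(system)
        gro = write_gro(system, clearance=config.clearance)
        (folder / f"{base}.top").write_text(top)
        (folder / f"{base}.gro").write_text(gro)
        report.files["gromacs_topology"] = folder / f"{base}.top"
        report.files["gromacs_coordinates"] = folder / f"{base}.gro"
        report.fidelity = compare_conversion(system)
        (folder / "fidelity_report.tsv").write_text(report.fidelity.to_tsv())
        report.files["fidelity_report"] = folder / "fidelity_report.tsv"
    if "cns" in config.outputs:
        top, par, inp = write_cns(system, base_name=base)
        violations = validate_cns(top, par)
        if violations:
            raise StructuralError(
                "emitted CNS text failed grammar validation: " + "; ".join(violations[:5])
            )
        (folder / f"{base}_cns.top").write_text(top)
        (folder / f"{base}_cns.param").write_text(par)
        (folder / f"{base}_cns.inp").write_text(inp)
        report.files["cns_topology"] = folder / f"{base}_cns.top"
        report.files["cns_parameters"] = folder / f"{base}_cns.param"
        report.files["cns_run_input"] = folder / f"{base}_cns.inp"
    if "charmm" in config.outputs:
        rtf, prm = write_charmm(system, base_name=base)
        violations = validate_charmm(rtf, prm)
        if violations:
            raise StructuralError(
                "emitted CHARMM text failed grammar validation: " + "; ".join(violations[:5])
            )
        (folder / f"{base}_charmm.rtf").write_text(rtf)
        (folder / f"{base}_charmm.prm").write_text(prm)
        report.files["charmm_rtf"] = folder / f"{base}_charmm.rtf"
        report.files["charmm_prm"] = folder / f"{base}_charmm.prm"


def _write_manifest(folder: Path, report: RunReport) -> None:
    manifest = {
        "files": {role: str(p.name) for role, p in report.files.items()},
        "net_charge": report.net_charge,
        "water_model": report.water_model,
        "fidelity_max_rel_diff": (
            report.fidelity.max_relative_difference if report.fidelity else None
        ),
        "messages": report.messages,
    }
    (folder / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def run_convert(config: RunConfig) -> RunReport:
    """Small-molecule conversion: input file -> per-engine output folder."""
    system = _load_input(config)
    base = Path(config.input_path).stem

    geometry = validate_geometry(system)
    if not geometry.passed:
        details = "; ".join(
            f"bond {i}-{j}: {d:.3f} A violates {rule}"
            for (i, j), d, rule in geometry.violations
        )
        raise GeometryError(f"covalent geometry check failed: {details}")

    _obtain_charges(system, config)
    report_net = _check_net_charge(system, config)

    if not config.parameter_files:
        raise StructuralError(
            "the self-contained route needs at least one frcmod/parm-dat "
            "parameter file (external leap is not required then)"
        )
    sources: list[ParameterSource] = []
    for p in config.parameter_files:
        dialect = "parm_dat" if Path(p).suffix.lower() == ".dat" else "frcmod"
        sources.append(read_frcmod(p, dialect=dialect))

    provenance = resolve_parameters(system, sources)

    folder = _output_folder(config, base)
    report = RunReport(out_dir=folder, net_charge=report_net, provenance=provenance)
    report.water_model = recognize_water(system)
    _write_engines(system, config, folder, base, report)
    _write_manifest(folder, report)
    return report


def run_amb2gmx(
    prmtop_path: Path,
    inpcrd_path: Path,
    clearance: float = C.DEFAULT_CLEARANCE_NM,
    out_dir: Optional[Path] = None,
) -> RunReport:
    """Self-contained prmtop + inpcrd -> GROMACS .top/.gro conversion."""
    system = read_prmtop(prmtop_path)
    coords, box = read_inpcrd(inpcrd_path)
    if len(coords) != system.n_atoms:
        raise StructuralError(
            f"prmtop declares {system.n_atoms} atoms but inpcrd holds {len(coords)}"
        )
    system.coordinates = np.asarray(coords)
    if box.kind != "none":
        system.box = box

    base = Path(prmtop_path).stem
    folder = Path(out_dir) if out_dir is not None else Path(f"{base}.amb2gmx")
    folder.mkdir(parents=True, exist_ok=True)

    report = RunReport(out_dir=folder, net_charge=system.net_charge or 0)
    report.water_model = recognize_water(system)
    if report.water_model:
        report.messages.append(f"recognised water model: {report.water_model}")
    if box.kind == "none":
        report.messages.append(
            f"no box in inpcrd; built one from coordinates + {clearance} nm clearance"
        )

    box_vectors = convert_box(system.box, system.coordinates, clearance)
    top = write_gromacs_top(system)
    gro = write_gro(system, box_vectors=box_vectors)
    (folder / f"{base}.top").write_text(top)
    (folder / f"{base}.gro").write_text(gro)
    report.files["gromacs_topology"] = folder / f"{base}.top"
    report.files["gromacs_coordinates"] = folder / f"{base}.gro"

    report.fidelity = compare_conversion(system)
    (folder / "fidelity_report.tsv").write_text(report.fidelity.to_tsv())
    report.files["fidelity_report"] = folder / "fidelity_report.tsv"
    _write_manifest(folder, report)
    return report
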