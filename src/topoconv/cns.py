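"""CNS/XPLOR topology, parameter and run-input emission.

CNS requires uppercase atom and type names (mixed-case names make its
parser fail), parameters in kcal/Angstrom units, and unique-by-type
parameter statements.  Since no CNS reader exists in this package, a
line-grammar validator checks the emitted dialect instead; the physics is
certified through the GROMACS energy round trip, which shares every
converted number via the common parameter engine.
"""

from __future__ import annotations

import math
import re
from pathlib import Path
from typing import Optional, Union

from .errors import StructuralError
from .model import MolecularSystem
from .params import lj_ab_to_sigma_eps
from . import constants as C

PathLike = Union[str, Path]


def _upper_types(system: MolecularSystem) -> dict[str, str]:
    """Map atom types to their uppercase CNS names, refusing collisions."""
    mapping: dict[str, str] = {}
    seen: dict[str, str] = {}
    for lj in system.lj_types:
        up = lj.type_name.upper()
        if up in seen and seen[up] != lj.type_name:
            raise StructuralError(
                f"atom types {seen[up]!r} and {lj.type_name!r} collide as "
                f"uppercase CNS type {up!r}"
            )
        seen[up] = lj.type_name
        mapping[lj.type_name] = up
    return mapping


def _dedup(table: dict, key, value, what: str, tol: float = 1e-8):
    if key in table:
        old = table[key]
        same = all(abs(a - b) <= tol * max(1.0, abs(a), abs(b)) for a, b in zip(old, value))
        if not same:
            raise StructuralError(
                f"conflicting {what} parameters for type key {key}: {old} vs {value}"
            )
    else:
        table[key] = value


def write_cns(
    system: MolecularSystem, base_name: str = "MOL", out_dir: Optional[PathLike] = None
) -> tuple[str, str, str]:
    """Emit (topology text, parameter text, run-input template text)."""
    if not system.lj_types:
        raise StructuralError("system is not parameterised")
    system.validate()
    types = _upper_types(system)
    aname = {a.index: a.name.upper() for a in system.atoms}
    atype = {a.index: types[a.amber_type] for a in system.atoms}
    resname = (system.atoms[0].residue_name or "MOL").upper()

    top: list[str] = [
        f"remarks topology for {base_name}",
        "set echo=false end",
        "autogenerate angles=True dihedrals=True end",
        "",
    ]
    for lj in system.lj_types:
        mass = next(a.mass for a in system.atoms if a.amber_type == lj.type_name)
        top.append(f"MASS {types[lj.type_name]:<4s} {mass:9.5f}")
    top += ["", f"RESIdue {resname}", "GROUP"]
    for a in system.atoms:
        top.append(
            f"  ATOM {aname[a.index]:<4s} TYPE={atype[a.index]:<4s} "
            f"CHARGE={a.partial_charge:9.6f} END"
        )
    top.append("")
    for b in system.bonds:
        top.append(f"  BOND {aname[b.atoms[0]]:<4s} {aname[b.atoms[1]]:<4s}")
    for ang in system.angles:
        i, j, k = ang.atoms
        top.append(f"  ANGLe {aname[i]:<4s} {aname[j]:<4s} {aname[k]:<4s}")
    seen_quartets = set()
    for t in system.torsions:
        if t.kind != "proper" or t.atoms in seen_quartets:
            continue
        seen_quartets.add(t.atoms)
        i, j, k, l = t.atoms
        top.append(
            f"  DIHEdral {aname[i]:<4s} {aname[j]:<4s} {aname[k]:<4s} {aname[l]:<4s}"
        )
    seen_quartets.clear()
    for t in system.torsions:
        if t.kind != "improper" or t.atoms in seen_quartets:
            continue
        seen_quartets.add(t.atoms)
        i, j, k, l = t.atoms
        top.append(
            f"  IMPRoper {aname[i]:<4s} {aname[j]:<4s} {aname[k]:<4s} {aname[l]:<4s}"
        )
    top += ["END", "", "set echo=true end", ""]

    # parameter file: unique-by-type statements in kcal / Angstrom
    bond_table: dict = {}
    for b in system.bonds:
        key = tuple(sorted((atype[b.atoms[0]], atype[b.atoms[1]])))
        _dedup(bond_table, key, (b.force_k, b.r_eq), "BOND")
    angle_table: dict = {}
    for ang in system.angles:
        i, j, k = ang.atoms
        key = (min(atype[i], atype[k]), atype[j], max(atype[i], atype[k]))
        _dedup(angle_table, key, (ang.force_k, math.degrees(ang.theta_eq)), "ANGLe")
    dihe_table: dict[tuple, list] = {}
    impr_table: dict[tuple, list] = {}
    for t in system.torsions:
        i, j, k, l = t.atoms
        fwd = (atype[i], atype[j], atype[k], atype[l])
        rev = fwd[::-1]
        key = fwd if fwd <= rev else rev
        table = dihe_table if t.kind == "proper" else impr_table
        entry = (t.barrier_half, t.periodicity, math.degrees(t.phase) % 360.0)
        series = table.setdefault(key, [])
        if entry not in series:
            if any(e[1] == entry[1] and e != entry for e in series):
                raise StructuralError(
                    f"conflicting torsion parameters for {key} periodicity {entry[1]}"
                )
            series.append(entry)

    par: list[str] = [f"remarks parameters for {base_name}", "set echo=false end", ""]
    for (t1, t2), (k, r) in sorted(bond_table.items()):
        par.append(f"BOND {t1:<4s} {t2:<4s} {k:10.4f} {r:10.5f}")
    for (t1, t2, t3), (k, th) in sorted(angle_table.items()):
        par.append(f"ANGLe {t1:<4s} {t2:<4s} {t3:<4s} {k:10.4f} {th:10.4f}")
    for key, series in sorted(dihe_table.items()):
        t1, t2, t3, t4 = key
        parts = " ".join(
            f"{pk:10.4f} {per:2d} {ph:8.2f}" for pk, per, ph in series
        )
        par.append(
            f"DIHEdral {t1:<4s} {t2:<4s} {t3:<4s} {t4:<4s} MULT {len(series)} {parts}"
        )
    for key, series in sorted(impr_table.items()):
        t1, t2, t3, t4 = key
        for pk, per, ph in series:
            par.append(
                f"IMPRoper {t1:<4s} {t2:<4s} {t3:<4s} {t4:<4s} {pk:10.4f} {per:2d} {ph:8.2f}"
            )
    for lj in system.lj_types:
        sigma_nm, eps_kj = lj_ab_to_sigma_eps(lj)
        sigma = sigma_nm / C.ANGSTROM_TO_NM
        eps = eps_kj / C.KCAL_TO_KJ
        par.append(
            f"NONBonded {types[lj.type_name]:<4s} {eps:10.6f} {sigma:10.6f} "
            f"{eps * C.LJ14_SCALE:10.6f} {sigma:10.6f}"
        )
    par += ["", "set echo=true end", ""]

    inp = "\n".join(
        [
            f"remarks minimal single-point energy input for {base_name}",
            f"topology @{base_name}.top end",
            f"parameter @{base_name}.param end",
            "segment",
            f"  name={resname[:4]}",
            f"  molecule number=1 name={resname} end",
            "end",
            f"coordinates @{base_name}.pdb",
            "energy end",
            "stop",
            "",
        ]
    )

    top_text, par_text = "\n".join(top), "\n".join(par)
    if out_dir is not None:
        d = Path(out_dir)
        (d / f"{base_name}_cns.top").write_text(top_text)
        (d / f"{base_name}_cns.param").write_text(par_text)
        (d / f"{base_name}_cns.inp").write_text(inp)
    return top_text, par_text, inp


# ---------------------------------------------------------------------------
# line-grammar validation
# ---------------------------------------------------------------------------

_NAME = r"[A-Z0-9\*\+']{1,4}"
_NUM = r"[-+]?\d+(?:\.\d+)?(?:[eE][-+]?\d+)?"

_TOP_PATTERNS = [
    re.compile(p)
    for p in (
        rf"^remarks\b.*$",
        r"^set echo=(false|true) end$",
        r"^autogenerate .*end$",
        rf"^MASS {_NAME}\s+{_NUM}\s*$",
        rf"^RESIdue {_NAME}\s*$",
        r"^GROUP$",
        rf"^\s*ATOM {_NAME}\s+TYPE={_NAME}\s+CHARGE=\s*{_NUM} END$",
        rf"^\s*BOND {_NAME}\s+{_NAME}\s*$",
        rf"^\s*ANGLe {_NAME}\s+{_NAME}\s+{_NAME}\s*$",
        rf"^\s*DIHEdral {_NAME}\s+{_NAME}\s+{_NAME}\s+{_NAME}\s*$",
        rf"^\s*IMPRoper {_NAME}\s+{_NAME}\s+{_NAME}\s+{_NAME}\s*$",
        r"^END$",
    )
]

_PAR_PATTERNS = [
    re.compile(p)
    for p in (
        r"^remarks\b.*$",
        r"^set echo=(false|true) end$",
        rf"^BOND {_NAME}\s+{_NAME}\s+{_NUM}\s+{_NUM}\s*$",
        rf"^ANGLe {_NAME}\s+{_NAME}\s+{_NAME}\s+{_NUM}\s+{_NUM}\s*$",
        rf"^DIHEdral {_NAME}\s+{_NAME}\s+{_NAME}\s+{_NAME}\s+MULT \d+(\s+{_NUM}\s+\d+\s+{_NUM})+\s*$",
        rf"^IMPRoper {_NAME}\s+{_NAME}\s+{_NAME}\s+{_NAME}\s+{_NUM}\s+\d+\s+{_NUM}\s*$",
        rf"^NONBonded {_NAME}(\s+{_NUM}){{4}}\s*$",
    )
]


def validate_cns(topology_text: str, parameter_text: str) -> list[str]:
    """Validate emitted CNS texts line by line; returns grammar violations."""
    violations: list[str] = []
    for label, text, patterns in (
        ("topology", topology_text, _TOP_PATTERNS),
        ("parameters", parameter_text, _PAR_PATTERNS),
    ):
        for lineno, line in enumerate(text.splitlines(), start=1):
            if not line.strip():
                continue
            if not any(p.match(line) for p in patterns):
                violations.append(f"{label} line {lineno}: {line!r}")
            if line != line.upper() and not line.startswith("remarks") \
                    and not line.startswith("set") and not line.startswith("autogenerate"):
                # atom/type fields must be uppercase; keyword mixed case is CNS style
                tokens = line.split()
                for tok in tokens[1:]:
                    if "=" in tok:
                        tok = tok.split("=", 1)[1]
                    if tok.isalpha() and tok != tok.upper():
                        violations.append(
                            f"{label} line {lineno}: lowercase name {tok!r}"
                        )
    return violations
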