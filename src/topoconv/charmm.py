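"""CHARMM residue topology (rtf) and parameter (prm) emission.

CHARMM shares AMBER's bonded conventions for bonds (Kb(b-b0)^2) and
torsions (Kchi(1+cos(n chi - delta))), so force constants transfer
unchanged in kcal/Angstrom units; Lennard-Jones entries are rewritten in
the NONBONDED convention (ignored column, -epsilon, Rmin/2 with
Rmin/2 = sigma * 2^(1/6) / 2).  Only the rtf/prm pair is produced — psf
generation belongs to CHARMM itself.
"""

from __future__ import annotations

import math
import re
from pathlib import Path
from typing import Optional, Union

from . import constants as C
from .errors import StructuralError
from .model import MolecularSystem
from .params import lj_ab_to_sigma_eps

PathLike = Union[str, Path]

RMIN_HALF_PER_SIGMA_NM = 2.0 ** (1.0 / 6.0) / 2.0 / C.ANGSTROM_TO_NM  # nm -> A


def write_charmm(
    system: MolecularSystem, base_name: str = "MOL", out_dir: Optional[PathLike] = None
) -> tuple[str, str]:
    """Emit (rtf text, prm text) for a parameterised system."""
    if not system.lj_types:
        raise StructuralError("system is not parameterised")
    system.validate()
    atype = {a.index: a.amber_type for a in system.atoms}
    aname = {a.index: a.name for a in system.atoms}
    resname = system.atoms[0].residue_name or "MOL"
    net = system.net_charge if system.net_charge is not None else 0

    type_names = [lj.type_name for lj in system.lj_types]
    if len(set(type_names)) != len(type_names):
        raise StructuralError("duplicate MASS record type names")

    rtf: list[str] = [f"* residue topology for {base_name}", "*", "36  1", ""]
    for n, lj in enumerate(system.lj_types, start=1):
        mass = next(a.mass for a in system.atoms if a.amber_type == lj.type_name)
        element = next(a.element for a in system.atoms if a.amber_type == lj.type_name)
        rtf.append(f"MASS {n:5d} {lj.type_name:<6s} {mass:10.5f} {element}")
    rtf += ["", f"RESI {resname:<4s} {float(net):8.3f}", "GROUP"]
    for a in system.atoms:
        rtf.append(f"ATOM {aname[a.index]:<6s} {atype[a.index]:<6s} {a.partial_charge:10.6f}")
    for b in system.bonds:
        rtf.append(f"BOND {aname[b.atoms[0]]:<6s} {aname[b.atoms[1]]:<6s}")
    for t in system.torsions:
        if t.kind == "improper":
            i, j, k, l = t.atoms
            rtf.append(
                f"IMPR {aname[i]:<6s} {aname[j]:<6s} {aname[k]:<6s} {aname[l]:<6s}"
            )
    rtf += ["PATC FIRS NONE LAST NONE", "", "END", ""]

    def dedup(table, key, value, what, tol=1e-8):
        if key in table:
            old = table[key]
            if not all(
                abs(a - b) <= tol * max(1.0, abs(a), abs(b)) for a, b in zip(old, value)
            ):
                raise StructuralError(
                    f"conflicting {what} parameters for {key}: {old} vs {value}"
                )
        else:
            table[key] = value

    bonds: dict = {}
    for b in system.bonds:
        key = tuple(sorted((atype[b.atoms[0]], atype[b.atoms[1]])))
        dedup(bonds, key, (b.force_k, b.r_eq), "BONDS")
    angles: dict = {}
    for ang in system.angles:
        i, j, k = ang.atoms
        key = (min(atype[i], atype[k]), atype[j], max(atype[i], atype[k]))
        dedup(angles, key, (ang.force_k, math.degrees(ang.theta_eq)), "ANGLES")
    dihedrals: dict = {}
    impropers: dict = {}
    for t in system.torsions:
        i, j, k, l = t.atoms
        fwd = (atype[i], atype[j], atype[k], atype[l])
        rev = fwd[::-1]
        key = (fwd if fwd <= rev else rev, t.periodicity)
        table = dihedrals if t.kind == "proper" else impropers
        dedup(
            table, key,
            (t.barrier_half, math.degrees(t.phase) % 360.0),
            "DIHEDRALS" if t.kind == "proper" else "IMPROPER",
        )

    prm: list[str] = [f"* parameters for {base_name}", "*", "", "BONDS"]
    for (t1, t2), (k, r) in sorted(bonds.items()):
        prm.append(f"{t1:<6s} {t2:<6s} {k:10.4f} {r:10.5f}")
    prm += ["", "ANGLES"]
    for (t1, t2, t3), (k, th) in sorted(angles.items()):
        prm.append(f"{t1:<6s} {t2:<6s} {t3:<6s} {k:10.4f} {th:10.4f}")
    prm += ["", "DIHEDRALS"]
    for ((t1, t2, t3, t4), per), (k, ph) in sorted(dihedrals.items()):
        prm.append(
            f"{t1:<6s} {t2:<6s} {t3:<6s} {t4:<6s} {k:10.4f} {per:2d} {ph:8.2f}"
        )
    prm += ["", "IMPROPER"]
    for ((t1, t2, t3, t4), per), (k, ph) in sorted(impropers.items()):
        prm.append(
            f"{t1:<6s} {t2:<6s} {t3:<6s} {t4:<6s} {k:10.4f} {per:2d} {ph:8.2f}"
        )
    prm += ["", "NONBONDED"]
    for lj in system.lj_types:
        sigma_nm, eps_kj = lj_ab_to_sigma_eps(lj)
        rmin_half = sigma_nm * RMIN_HALF_PER_SIGMA_NM
        eps_kcal = eps_kj / C.KCAL_TO_KJ
        prm.append(
            f"{lj.type_name:<6s} {0.0:6.2f} {-eps_kcal:10.6f} {rmin_half:10.6f}"
        )
    prm += ["", "END", ""]

    rtf_text, prm_text = "\n".join(rtf), "\n".join(prm)
    if out_dir is not None:
        d = Path(out_dir)
        (d / f"{base_name}_charmm.rtf").write_text(rtf_text)
        (d / f"{base_name}_charmm.prm").write_text(prm_text)
    return rtf_text, prm_text


# ---------------------------------------------------------------------------
# line-grammar validation
# ---------------------------------------------------------------------------

_NAME = r"[A-Za-z0-9\*\+']{1,6}"
_NUM = r"[-+]?\d+(?:\.\d+)?(?:[eE][-+]?\d+)?"

_RTF_PATTERNS = [
    re.compile(p)
    for p in (
        r"^\*.*$",
        r"^\d+\s+\d+$",
        rf"^MASS\s+\d+\s+{_NAME}\s+{_NUM}\s+[A-Za-z]{{1,2}}$",
        rf"^RESI\s+{_NAME}\s+{_NUM}$",
        r"^GROUP$",
        rf"^ATOM\s+{_NAME}\s+{_NAME}\s+{_NUM}$",
        rf"^BOND(\s+{_NAME}){{2}}$",
        rf"^IMPR(\s+{_NAME}){{4}}$",
        r"^PATC FIRS NONE LAST NONE$",
        r"^END$",
    )
]

_PRM_PATTERNS = [
    re.compile(p)
    for p in (
        r"^\*.*$",
        r"^(BONDS|ANGLES|DIHEDRALS|IMPROPER|NONBONDED)$",
        rf"^{_NAME}\s+{_NAME}\s+{_NUM}\s+{_NUM}$",  # bond
        rf"^{_NAME}\s+{_NAME}\s+{_NAME}\s+{_NUM}\s+{_NUM}$",  # angle
        rf"^{_NAME}\s+{_NAME}\s+{_NAME}\s+{_NAME}\s+{_NUM}\s+\d+\s+{_NUM}$",  # dihedral
        rf"^{_NAME}\s+{_NUM}\s+{_NUM}\s+{_NUM}$",  # nonbonded
        r"^END$",
    )
]


def _validate(text: str, patterns, label: str) -> list[str]:
    violations = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if not any(p.match(stripped) for p in patterns):
            violations.append(f"{label} line {lineno}: {line!r}")
    return violations


def validate_charmm(rtf_text: str, prm_text: str) -> list[str]:
    """Validate emitted rtf/prm texts line by line; returns grammar violations."""
    return _validate(rtf_text, _RTF_PATTERNS, "rtf") + _validate(
        prm_text, _PRM_PATTERNS, "prm"
    )
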