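"""Optional invocation of external AmberTools/OpenBabel binaries.

Every conversion path in this package works without external tools; these
helpers only exist for the charge-derivation and PDB/MDL input routes
that genuinely need antechamber/leap/sqm or obabel.  Invocations run in
an isolated scratch directory with a wall-clock limit, and a missing
binary is reported as a capability error distinct from a tool failure.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .errors import (
    ExternalToolError,
    ExternalToolMissingError,
    ExternalToolTimeoutError,
)

KNOWN_TOOLS = ("antechamber", "tleap", "sleap", "xleap", "sqm", "obabel")

DEFAULT_TIMEOUT_S = 3600.0  # interactive default; batch work may raise it


@dataclass
class ExternalResult:
    tool: str
    returncode: int
    stdout: str
    stderr: str
    files: dict[str, Path] = field(default_factory=dict)  # role -> produced file


def find_tool(tool: str, binary_path: Optional[str] = None) -> str:
    """Resolve a tool to an executable path or raise a capability error."""
    candidate = binary_path or tool
    resolved = shutil.which(candidate)
    if resolved is None:
        raise ExternalToolMissingError(
            f"external tool {tool!r} is not installed or not on PATH; "
            "this step needs it (the prmtop and MOL2+frcmod routes do not)"
        )
    return resolved


def invoke_external(
    tool: str,
    args: Sequence[str],
    timeout: float = DEFAULT_TIMEOUT_S,
    binary_path: Optional[str] = None,
    input_files: Optional[dict[str, Path]] = None,
    output_roles: Optional[dict[str, str]] = None,
    workdir: Optional[Path] = None,
) -> ExternalResult:
    """Run an external binary in a scratch directory with a time limit.

    ``input_files`` maps scratch-relative names to files copied in before
    the run; ``output_roles`` maps roles to scratch-relative names
    collected after it.  Raises :class:`ExternalToolMissingError` if the
    binary is absent, :class:`ExternalToolTimeoutError` on timeout (with
    partial logs attached) and :class:`ExternalToolError` on nonzero exit.
    """
    if timeout <= 0:
        raise ValueError("timeout must be positive")
    exe = find_tool(tool, binary_path)
    scratch = Path(workdir) if workdir is not None else Path(tempfile.mkdtemp(prefix=f"topoconv_{tool}_"))
    scratch.mkdir(parents=True, exist_ok=True)
    for name, src in (input_files or {}).items():
        shutil.copy(src, scratch / name)
    try:
        proc = subprocess.run(
            [exe, *args],
            cwd=scratch,
            stdin=subprocess.DEVNULL,
            capture_output=True,
            text=True,
            timeout=timeout,
        )
    except subprocess.TimeoutExpired as exc:
        raise ExternalToolTimeoutError(
            f"{tool} exceeded the {timeout:.0f} s wall-clock limit; partial "
            f"stdout:\n{(exc.stdout or b'')[:2000]!r}"
        ) from exc
    result = ExternalResult(
        tool=tool, returncode=proc.returncode, stdout=proc.stdout, stderr=proc.stderr
    )
    if proc.returncode != 0:
        raise ExternalToolError(
            f"{tool} failed with exit code {proc.returncode}; stderr:\n"
            f"{proc.stderr[:2000]}"
        )
    for role, name in (output_roles or {}).items():
        produced = scratch / name
        if not produced.exists():
            raise ExternalToolError(f"{tool} did not produce expected file {name!r}")
        result.files[role] = produced
    return result
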