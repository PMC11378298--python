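"""File-exchange adapter for an external semiempirical energy engine.

The adapter writes the fragment as an XYZ file annotated with its total
charge, runs a user-configured command template, and extracts the total
energy (hartree) from the engine's standard output with a configured
regular expression.  Energies convert to kcal/mol by 627.5095.

Only the total energy is available from this backend; component fields
stay unset, so EDDA component maps require the classical backend.
"""

from __future__ import annotations

import re
import subprocess
import tempfile
from pathlib import Path

from .energy import BackendConfig, HARTREE_TO_KCAL
from .errors import ArgumentError, EngineError
from .records import Fragment


def write_xyz(fragment: Fragment, path) -> None:
    """Write a fragment as XYZ; the comment line carries 'charge=<q>'."""
    lines = [str(len(fragment.atoms)),
             f"charge={fragment.formal_charge}"]
    for a in fragment.atoms:
        x, y, z = a.coords
        lines.append(f"{a.element:<2s} {x:18.10f} {y:18.10f} {z:18.10f}")
    Path(path).write_text("\n".join(lines) + "\n")


def parse_engine_output(text: str, pattern: str) -> float:
    """Extract the total energy (hartree) from engine output."""
    m = re.search(pattern, text)
    if m is None:
        raise EngineError(
            f"engine output did not match pattern {pattern!r}",
            captured_output=text)
    try:
        return float(m.group(1))
    except (IndexError, ValueError) as exc:
        raise EngineError(
            f"pattern {pattern!r} did not capture a numeric group: {exc}",
            captured_output=text)


def external_engine_energy(fragment: Fragment, config: BackendConfig) -> float:
    """Run the configured engine on a fragment; total energy in kcal/mol."""
    if not config.external_command or not config.external_pattern:
        raise ArgumentError(
            "external engine requires external_command and external_pattern")
    with tempfile.TemporaryDirectory(prefix="pocketedda_") as tmp:
        xyz = Path(tmp) / "fragment.xyz"
        write_xyz(fragment, xyz)
        cmd = config.external_command.format(xyz=str(xyz),
                                             charge=fragment.formal_charge)
        proc = subprocess.run(cmd, shell=True, capture_output=True,
                              text=True, cwd=tmp)
        if proc.returncode != 0:
            raise EngineError(
                f"engine exited with status {proc.returncode}",
                captured_output=proc.stdout + proc.stderr)
        hartree = parse_engine_output(proc.stdout, config.external_pattern)
    return hartree * HARTREE_TO_KCAL


def supermolecule_interaction(e_union: float, e_a: float, e_b: float) -> float:
    """E(A∪B) − E(A) − E(B) for three engine totals (any consistent unit)."""
    return e_union - e_a - e_b
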