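"""Hook up an external quantum-chemistry engine via file exchange.

The adapter writes a fragment as XYZ, runs a configured shell command,
and parses the total energy (hartree) from its output with a regular
expression.  Here a tiny stand-in script plays the engine so the
example runs anywhere; point ``external_command`` at a real
semiempirical binary (e.g. an xtb-style ``{xyz}`` invocation) for
production use.
"""

import sys
import tempfile
from pathlib import Path

from pocketedda import (AtomRecord, BackendConfig, Fragment,
                        external_engine_energy)
from pocketedda.external import supermolecule_interaction

STUB = """\
print("fake engine v0")
print("TOTAL ENERGY -0.500000 Eh")
"""

with tempfile.TemporaryDirectory() as tmp:
    stub = Path(tmp) / "engine.py"
    stub.write_text(STUB)
    config = BackendConfig(
        engine="external",
        external_command=f"{sys.executable} {stub} {{xyz}}",
        external_pattern=r"TOTAL ENERGY\s+(-?\d+\.\d+)\s+Eh")
    frag = Fragment("HE", [AtomRecord("He", "HE", (0, 0, 0))])
    e = external_engine_energy(frag, config)
    print(f"engine total energy: {e:.5f} kcal/mol "
          f"(−0.5 Eh × 627.5095)")

# supermolecule interaction from three engine totals (hartree):
e_int = supermolecule_interaction(-1.0, -0.4, -0.5)
print(f"interaction energy: {e_int:.1f} Eh = {e_int * 627.5095:.5f} "
      f"kcal/mol")
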