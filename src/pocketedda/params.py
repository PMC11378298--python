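"""Per-element backend parameters and plain-text parameter tables.

The classical backend needs a Lennard-Jones well depth and radius and a
Born radius for every atom.  Defaults below are generic all-atom values;
an explicit table (key-value text, one element per line) overrides them.

Table format::

    # element  epsilon(kcal/mol)  sigma(A)  born_radius(A)
    C  0.086  3.40  1.70
    O  0.210  2.96  1.52
"""

from __future__ import annotations

from typing import Dict, Optional

from .errors import FormatError, ParameterError
from .records import Fragment

# epsilon kcal/mol, sigma Å (generic AMBER-like values), Born radius Å.
DEFAULT_ELEMENT_PARAMS: Dict[str, tuple] = {
    "H":  (0.0157, 2.65, 1.20),
    "C":  (0.0860, 3.40, 1.70),
    "N":  (0.1700, 3.25, 1.55),
    "O":  (0.2100, 2.96, 1.52),
    "S":  (0.2500, 3.56, 1.80),
    "P":  (0.2000, 3.74, 1.85),
    "F":  (0.0610, 3.12, 1.47),
    "Cl": (0.2650, 3.47, 1.75),
    "Br": (0.3200, 3.66, 1.85),
    "I":  (0.4000, 3.83, 1.98),
    "Na": (0.0028, 3.33, 1.55),
    "K":  (0.0003, 4.74, 2.02),
    "Mg": (0.8950, 1.41, 1.18),
    "Ca": (0.4600, 2.41, 1.37),
    "Zn": (0.0125, 1.96, 1.09),
    "Fe": (0.0130, 2.59, 1.30),
    "Se": (0.2900, 3.62, 1.90),
}


def read_parameter_table(path) -> Dict[str, tuple]:
    """Parse a key-value parameter table: element -> (eps, sigma, born)."""
    table: Dict[str, tuple] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 4:
                raise FormatError(
                    f"{path}: line {lineno}: expected 'element eps sigma born', "
                    f"got {len(parts)} fields"
                )
            try:
                eps, sigma, born = (float(x) for x in parts[1:])
            except ValueError:
                raise FormatError(f"{path}: line {lineno}: non-numeric parameter")
            table[parts[0].capitalize()] = (eps, sigma, born)
    return table


def resolve_parameters(fragment: Fragment,
                       table: Optional[Dict[str, tuple]] = None) -> None:
    """Fill missing LJ/Born parameters from the table, then the defaults.

    Explicit per-atom values already on the record are kept.  Raises
    :class:`ParameterError` naming the atom if no source has the element.
    """
    for idx, atom in enumerate(fragment.atoms):
        src = None
        if table and atom.element in table:
            src = table[atom.element]
        elif atom.element in DEFAULT_ELEMENT_PARAMS:
            src = DEFAULT_ELEMENT_PARAMS[atom.element]
        if atom.lj_epsilon is None:
            if src is None:
                raise ParameterError(
                    f"no LJ parameters for atom {idx} ({atom.name}, element "
                    f"{atom.element}) in fragment {fragment.label!r}"
                )
            atom.lj_epsilon = src[0]
        if atom.lj_sigma is None:
            if src is None:
                raise ParameterError(
                    f"no LJ parameters for atom {idx} ({atom.name}) "
                    f"in fragment {fragment.label!r}"
                )
            atom.lj_sigma = src[1]
        if atom.born_radius is None:
            if src is None:
                raise ParameterError(
                    f"no Born radius for atom {idx} ({atom.name}) "
                    f"in fragment {fragment.label!r}"
                )
            atom.born_radius = src[2]
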