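"""Shared fixtures: programmatic PDB text, toy fragments, configs."""

from __future__ import annotations

import numpy as np
import pytest

from pocketedda.energy import BackendConfig
from pocketedda.records import AtomRecord, Fragment


def pdb_line(record: str, serial: int, name: str, resname: str, chain: str,
             resnum: int, x: float, y: float, z: float, occ: float = 1.0,
             element: str = "", altloc: str = " ") -> str:
    """One fixed-column ATOM/HETATM record."""
    elem = element or name[0]
    return (f"{record:<6s}{serial:>5d} {name:<4s}{altloc:1s}{resname:>3s} "
            f"{chain:1s}{resnum:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
            f"{occ:6.2f}{0.0:6.2f}          {elem:>2s}")


# rough but chemically consistent backbone of a Gly-Ala-Gly tripeptide:
# peptide C(i)–N(i+1) distances ~1.33 Å
TRIPEPTIDE_ATOMS = [
    # (resname, resnum, name, x, y, z, element)
    ("GLY", 1, "N", 0.000, 0.000, 0.000, "N"),
    ("GLY", 1, "CA", 1.450, 0.000, 0.000, "C"),
    ("GLY", 1, "C", 2.000, 1.300, 0.000, "C"),
    ("GLY", 1, "O", 1.400, 2.350, 0.000, "O"),
    ("ALA", 2, "N", 3.330, 1.300, 0.000, "N"),
    ("ALA", 2, "CA", 4.200, 2.400, 0.000, "C"),
    ("ALA", 2, "CB", 4.100, 3.300, 1.200, "C"),
    ("ALA", 2, "C", 5.650, 2.000, 0.000, "C"),
    ("ALA", 2, "O", 6.000, 0.850, 0.000, "O"),
    ("GLY", 3, "N", 6.550, 3.000, 0.000, "N"),
    ("GLY", 3, "CA", 7.980, 2.900, 0.000, "C"),
    ("GLY", 3, "C", 8.600, 4.280, 0.000, "C"),
    ("GLY", 3, "O", 7.950, 5.300, 0.000, "O"),
]


@pytest.fixture
def tripeptide_pdb(tmp_path):
    lines = [
        pdb_line("ATOM", i + 1, nm, rn, "A", num, x, y, z, element=el)
        for i, (rn, num, nm, x, y, z, el) in enumerate(TRIPEPTIDE_ATOMS)
    ]
    # a HETATM ligand near the middle residue
    lines.append(pdb_line("HETATM", 99, "C1", "LIG", "A", 90,
                          4.2, 4.5, 2.5, element="C"))
    lines.append("END")
    path = tmp_path / "tripeptide.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def config():
    return BackendConfig()


@pytest.fixture
def gas_config():
    """Classical backend without solvation (pure closed-form regime)."""
    return BackendConfig(solvation=False)


def point_ion(label: str, coords, charge: float,
              lj: tuple = (0.0, 3.3), born: float = 2.0) -> Fragment:
    elem = "Na" if charge >= 0 else "Cl"
    atom = AtomRecord(element=elem, name=elem.upper(), coords=coords,
                      charge=charge, lj_epsilon=lj[0], lj_sigma=lj[1],
                      born_radius=born)
    return Fragment(label=label, atoms=[atom], formal_charge=int(charge))


def random_fragment(rng: np.random.Generator, label: str, n_atoms: int,
                    center, spread: float = 1.0) -> Fragment:
    """Random small fragment with full parameters, charges summing ~0."""
    elems = ["C", "N", "O", "H"]
    atoms = []
    charges = rng.uniform(-0.5, 0.5, size=n_atoms)
    charges -= charges.mean()
    for i in range(n_atoms):
        el = elems[int(rng.integers(0, len(elems)))] if n_atoms > 1 else "C"
        atoms.append(AtomRecord(
            element=el, name=f"{el}{i}",
            coords=np.asarray(center) + rng.uniform(-spread, spread, 3),
            charge=float(charges[i]),
            lj_epsilon=float(rng.uniform(0.01, 0.3)),
            lj_sigma=float(rng.uniform(2.5, 3.8)),
            born_radius=float(rng.uniform(1.1, 2.0)),
            mobile=(el == "H")))
    return Fragment(label=label, atoms=atoms, formal_charge=0)
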