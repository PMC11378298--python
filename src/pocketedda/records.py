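"""Core molecular containers: atoms, fragments, structures, topologies.

Units are Å for coordinates and distances, elementary charge (e) for
charges, and kcal/mol for energies, throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import ArgumentError

# Elements the energy backends know about.  Anything else still parses,
# but parameter resolution will fail loudly unless the user supplies a
# table entry.
KNOWN_ELEMENTS = {
    "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne",
    "Na", "Mg", "Al", "Si", "P", "S", "Cl", "Ar", "K", "Ca",
    "Fe", "Zn", "Se", "Br", "I",
}


@dataclass
class AtomRecord:
    """One atom with coordinates, charge and backend parameters.

    ``mobile`` is True only for hydrogens eligible for in-pocket
    refinement; heavy atoms are always immobile.
    """

    element: str
    name: str
    coords: np.ndarray
    charge: float = 0.0
    lj_epsilon: Optional[float] = None   # kcal/mol
    lj_sigma: Optional[float] = None     # Å
    born_radius: Optional[float] = None  # Å
    is_cap: bool = False
    mobile: bool = False

    def __post_init__(self):
        self.element = self.element.strip().capitalize()
        if self.element not in KNOWN_ELEMENTS:
            raise ArgumentError(f"unrecognized element symbol {self.element!r}")
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,):
            raise ArgumentError("coords must be a 3-vector")
        if self.lj_epsilon is not None and self.lj_epsilon < 0:
            raise ArgumentError("lj_epsilon must be >= 0")
        if self.lj_sigma is not None and self.lj_sigma <= 0:
            raise ArgumentError("lj_sigma must be > 0")
        if self.born_radius is not None and self.born_radius <= 0:
            raise ArgumentError("born_radius must be > 0")
        if self.mobile and not self.is_hydrogen:
            raise ArgumentError("only hydrogens may be mobile")

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"

    def copy(self) -> "AtomRecord":
        return replace(self, coords=self.coords.copy())


@dataclass
class Topology:
    """Toy bonded topology: harmonic bonds (i, j, k, r0).

    k in kcal/mol/Å², r0 in Å.  Used for bonded energy terms, for
    nonbonded exclusions (pairs closer than 3 bonds) and for donor
    lookup in hydrogen-bond gating.
    """

    bonds: list = field(default_factory=list)  # (i, j, k, r0)

    def bond_graph(self, n_atoms: int) -> list:
        adj = [[] for _ in range(n_atoms)]
        for i, j, _, _ in self.bonds:
            adj[i].append(j)
            adj[j].append(i)
        return adj

    def excluded_pairs(self, n_atoms: int) -> set:
        """Atom pairs separated by fewer than 3 bonds (1-2 and 1-3)."""
        adj = self.bond_graph(n_atoms)
        excl = set()
        for i in range(n_atoms):
            for j in adj[i]:
                excl.add((min(i, j), max(i, j)))
                for k in adj[j]:
                    if k != i:
                        excl.add((min(i, k), max(i, k)))
        return excl


@dataclass
class Fragment:
    """A capped molecular unit: the ligand or one pocket residue."""

    label: str
    atoms: list
    formal_charge: int = 0
    source_residue_ids: list = field(default_factory=list)  # [(chain, resnum)]
    topology: Optional[Topology] = None

    def __post_init__(self):
        if not self.atoms:
            raise ArgumentError(f"fragment {self.label!r} has no atoms")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms])

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms])

    def copy(self) -> "Fragment":
        return Fragment(
            label=self.label,
            atoms=[a.copy() for a in self.atoms],
            formal_charge=self.formal_charge,
            source_residue_ids=list(self.source_residue_ids),
            topology=self.topology,
        )

    def normalize_charges(self) -> None:
        """Shift partial charges uniformly so they sum to the formal charge."""
        delta = (self.formal_charge - float(np.sum(self.charges))) / len(self.atoms)
        for a in self.atoms:
            a.charge += delta


def merge_fragments(a: Fragment, b: Fragment, label: Optional[str] = None) -> Fragment:
    """Union of two fragments (supermolecule), topologies concatenated."""
    atoms = [x.copy() for x in a.atoms] + [x.copy() for x in b.atoms]
    topo = None
    if a.topology is not None or b.topology is not None:
        off = len(a.atoms)
        bonds = list(a.topology.bonds) if a.topology else []
        if b.topology:
            bonds += [(i + off, j + off, k, r0) for i, j, k, r0 in b.topology.bonds]
        topo = Topology(bonds=bonds)
    return Fragment(
        label=label or f"{a.label}+{b.label}",
        atoms=atoms,
        formal_charge=a.formal_charge + b.formal_charge,
        topology=topo,
    )


ResidueKey = tuple  # (chain, resnum, resname)


@dataclass
class MolecularStructure:
    """Atoms grouped by (chain, residue number, residue name)."""

    residues: dict          # ResidueKey -> list[AtomRecord]
    hetero: dict            # ResidueKey -> bool
    source_id: str = ""

    def residue_keys(self) -> list:
        return sorted(self.residues, key=lambda k: (k[0], k[1], k[2]))

    def ligand_candidates(self) -> list:
        """Residue names of HETATM groups, excluding waters, in order."""
        seen, names = set(), []
        for key in self.residue_keys():
            if self.hetero.get(key) and key[2] not in WATER_NAMES:
                if key[2] not in seen:
                    seen.add(key[2])
                    names.append(key[2])
        return names

    def n_atoms(self) -> int:
        return sum(len(v) for v in self.residues.values())

    def get_fragment(self, resname: str) -> Fragment:
        """All atoms of residues with the given name as one fragment."""
        atoms = []
        ids = []
        for key in self.residue_keys():
            if key[2] == resname:
                atoms.extend(a.copy() for a in self.residues[key])
                ids.append((key[0], key[1]))
        if not atoms:
            raise ArgumentError(f"no residue named {resname!r} in structure")
        return Fragment(label=resname, atoms=atoms, source_residue_ids=ids)


WATER_NAMES = {"HOH", "WAT", "H2O", "DOD", "TIP3"}
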