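"""Pocket construction: residue selection, severing/capping, pair listing.

A pocket is the ligand plus every residue with at least one atom (heavy
or hydrogen) within a distance cutoff of any ligand atom — 5.0 Å by
default, the shell conventionally drawn around kinase inhibitors.
Selected residues are severed from the chain at their peptide bonds and
made chemically consistent with hydrogen caps: the neighboring backbone
atom across each severed bond is replaced by a hydrogen placed along
the bond vector at the standard X–H length (C–H 1.09 Å, N–H 1.01 Å).
Heavy atoms never move; fragment partial charges are shifted uniformly
so each fragment sums to its formal charge.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, NamedTuple, Optional

import numpy as np
from scipy.spatial.distance import cdist

from .errors import ArgumentError, CappingError
from .records import (AtomRecord, Fragment, MolecularStructure, Topology,
                      WATER_NAMES)

CAP_NH_LENGTH = 1.01   # Å, H replacing the previous residue's carbonyl C
CAP_CH_LENGTH = 1.09   # Å, H replacing the next residue's amide N
PEPTIDE_BOND_MAX = 1.8  # Å, C(i−1)–N(i) distance for a real peptide bond

# Physiological-default formal charges when the input carries no
# protonation information (Lys/Arg protonated, Asp/Glu deprotonated,
# His neutral).
RESIDUE_FORMAL_CHARGES = {"LYS": 1, "ARG": 1, "ASP": -1, "GLU": -1}

AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


@dataclass
class PocketModel:
    """Ligand + capped residue fragments + provenance."""

    ligand: Fragment
    residues: List[Fragment]
    cutoff: float = 5.0
    capping_scheme: str = "hydrogen-cap"
    source_id: str = ""
    include_waters: bool = False
    provenance: dict = field(default_factory=dict)

    def validate(self) -> None:
        """Check the pocket invariants: residues touch the ligand within
        the cutoff and fragments are atom-disjoint."""
        lig = self.ligand.coords
        seen = set()
        for frag in [self.ligand] + self.residues:
            for a in frag.atoms:
                key = tuple(np.round(a.coords, 6))
                if key in seen:
                    raise ArgumentError(
                        f"fragments are not atom-disjoint: duplicate atom "
                        f"at {key} in {frag.label!r}")
                seen.add(key)
        for frag in self.residues:
            d = cdist(frag.coords, lig).min()
            if d > self.cutoff + 1e-9:
                raise ArgumentError(
                    f"residue {frag.label!r} has no atom within "
                    f"{self.cutoff} Å of the ligand (closest {d:.2f} Å)")


def select_pocket_residues(structure: MolecularStructure, ligand: Fragment,
                           cutoff: float = 5.0,
                           include_waters: bool = False) -> list:
    """Residue keys whose minimum any-atom distance to the ligand is
    ≤ cutoff (inclusive), sorted by (chain, residue number).

    Waters are excluded unless ``include_waters``; the ligand's own
    residue records are never selected.
    """
    if cutoff <= 0:
        raise ArgumentError("cutoff must be positive")
    if not ligand.atoms:
        raise ArgumentError("ligand fragment is empty")
    lig_xyz = ligand.coords
    lig_ids = set(ligand.source_residue_ids)
    selected = []
    for key in structure.residue_keys():
        chain, resnum, resname = key
        if (chain, resnum) in lig_ids or resname == ligand.label:
            continue
        if resname in WATER_NAMES and not include_waters:
            continue
        xyz = np.array([a.coords for a in structure.residues[key]])
        if cdist(xyz, lig_xyz).min() <= cutoff + 1e-12:
            selected.append(key)
    return sorted(selected, key=lambda k: (k[0], k[1]))


def _find_atom(atoms, name: str) -> Optional[AtomRecord]:
    for a in atoms:
        if a.name == name:
            return a
    return None


def _make_cap(anchor: AtomRecord, removed_xyz: np.ndarray,
              length: float) -> AtomRecord:
    """Hydrogen replacing a severed backbone neighbor, placed along the
    severed bond vector at the standard X–H distance from the anchor."""
    v = removed_xyz - anchor.coords
    norm = float(np.linalg.norm(v))
    if norm == 0:
        raise CappingError("degenerate severed bond (zero length)")
    coords = anchor.coords + v / norm * length
    return AtomRecord(element="H", name="Hcap", coords=coords,
                      is_cap=True, mobile=True)


def cut_pocket(structure: MolecularStructure, residue_ids: list,
               ligand: Optional[Fragment] = None, cutoff: float = 5.0,
               include_waters: bool = False,
               scheme: str = "hydrogen-cap") -> PocketModel:
    """Sever the selected residues from the chain and cap them.

    Each residue id (chain, resnum, resname) becomes one Fragment.
    Severed peptide bonds gain a cap hydrogen; heavy-atom coordinates
    are taken unchanged from the structure.  Raises
    :class:`CappingError` naming the residue if backbone atoms needed
    for capping are missing.
    """
    if scheme != "hydrogen-cap":
        raise ArgumentError(f"unknown capping scheme {scheme!r}")
    by_key = structure.residues
    fragments = []
    for key in residue_ids:
        if key not in by_key:
            raise ArgumentError(f"residue {key} not present in structure")
        chain, resnum, resname = key
        label = f"{resname}{resnum}"
        atoms = [a.copy() for a in by_key[key]]
        for a in atoms:
            if a.is_hydrogen:
                a.mobile = True
        is_polymer = resname in AMINO_ACIDS and not structure.hetero.get(key)
        if is_polymer:
            n_atom = _find_atom(atoms, "N")
            c_atom = _find_atom(atoms, "C")
            ca_atom = _find_atom(atoms, "CA")
            if n_atom is None or c_atom is None or ca_atom is None:
                missing = [nm for nm, at in
                           (("N", n_atom), ("CA", ca_atom), ("C", c_atom))
                           if at is None]
                raise CappingError(
                    f"residue {label} (chain {chain!r}) is missing backbone "
                    f"atoms {missing}; cannot cap")
            prev_key = next((k for k in by_key
                             if k[0] == chain and k[1] == resnum - 1
                             and k[2] in AMINO_ACIDS), None)
            next_key = next((k for k in by_key
                             if k[0] == chain and k[1] == resnum + 1
                             and k[2] in AMINO_ACIDS), None)
            if prev_key is not None and prev_key not in residue_ids:
                prev_c = _find_atom(by_key[prev_key], "C")
                if prev_c is not None and np.linalg.norm(
                        prev_c.coords - n_atom.coords) <= PEPTIDE_BOND_MAX:
                    atoms.append(_make_cap(n_atom, prev_c.coords,
                                           CAP_NH_LENGTH))
            if next_key is not None and next_key not in residue_ids:
                next_n = _find_atom(by_key[next_key], "N")
                if next_n is not None and np.linalg.norm(
                        next_n.coords - c_atom.coords) <= PEPTIDE_BOND_MAX:
                    atoms.append(_make_cap(c_atom, next_n.coords,
                                           CAP_CH_LENGTH))
        frag = Fragment(label=label, atoms=atoms,
                        formal_charge=RESIDUE_FORMAL_CHARGES.get(resname, 0),
                        source_residue_ids=[(chain, resnum)])
        frag.normalize_charges()
        fragments.append(frag)
    return PocketModel(
        ligand=ligand if ligand is not None else _null_ligand(),
        residues=fragments, cutoff=cutoff, capping_scheme=scheme,
        source_id=structure.source_id, include_waters=include_waters)


def _null_ligand() -> Fragment:
    # placeholder for pockets cut without an explicit ligand
    return Fragment(label="LIG", atoms=[AtomRecord("C", "C1", (0, 0, 0))])


class PairContact(NamedTuple):
    """One ligand–residue pair with its shortest interatomic contact."""

    ligand: Fragment
    residue: Fragment
    closest_contact: float


def enumerate_pairs(pocket: PocketModel) -> List[PairContact]:
    """One pair per residue fragment, annotated with the minimum
    interatomic distance, ordered by ascending closest contact (ties by
    residue number)."""
    lig_xyz = pocket.ligand.coords
    out = []
    for frag in pocket.residues:
        d = float(cdist(frag.coords, lig_xyz).min())
        out.append(PairContact(pocket.ligand, frag, d))

    def key(pc: PairContact):
        ids = pc.residue.source_residue_ids
        resnum = ids[0][1] if ids else 1 << 30
        return (pc.closest_contact, resnum, pc.residue.label)

    return sorted(out, key=key)


# ---------------------------------------------------------------------------
# JSON serialization (the pocket exchange schema)
# ---------------------------------------------------------------------------

def _atom_to_dict(a: AtomRecord) -> dict:
    return {
        "element": a.element, "name": a.name,
        "coords": [float(v) for v in a.coords],
        "charge": a.charge, "lj_epsilon": a.lj_epsilon,
        "lj_sigma": a.lj_sigma, "born_radius": a.born_radius,
        "is_cap": a.is_cap, "mobile": a.mobile,
    }


def _atom_from_dict(d: dict) -> AtomRecord:
    return AtomRecord(
        element=d["element"], name=d["name"], coords=d["coords"],
        charge=d.get("charge", 0.0), lj_epsilon=d.get("lj_epsilon"),
        lj_sigma=d.get("lj_sigma"), born_radius=d.get("born_radius"),
        is_cap=d.get("is_cap", False), mobile=d.get("mobile", False))


def _fragment_to_dict(f: Fragment) -> dict:
    d = {
        "label": f.label, "formal_charge": f.formal_charge,
        "source_residue_ids": [list(t) for t in f.source_residue_ids],
        "atoms": [_atom_to_dict(a) for a in f.atoms],
    }
    if f.topology is not None:
        d["bonds"] = [list(b) for b in f.topology.bonds]
    return d


def _fragment_from_dict(d: dict) -> Fragment:
    topo = None
    if d.get("bonds"):
        topo = Topology(bonds=[tuple(b) for b in d["bonds"]])
    return Fragment(
        label=d["label"], atoms=[_atom_from_dict(a) for a in d["atoms"]],
        formal_charge=d.get("formal_charge", 0),
        source_residue_ids=[tuple(t) for t in
                            d.get("source_residue_ids", [])],
        topology=topo)


def pocket_to_dict(p: PocketModel) -> dict:
    return {
        "schema": "pocketedda-pocket v1",
        "source_id": p.source_id, "cutoff": p.cutoff,
        "capping_scheme": p.capping_scheme,
        "include_waters": p.include_waters,
        "provenance": p.provenance,
        "ligand": _fragment_to_dict(p.ligand),
        "residues": [_fragment_to_dict(f) for f in p.residues],
    }


def pocket_from_dict(d: dict) -> PocketModel:
    return PocketModel(
        ligand=_fragment_from_dict(d["ligand"]),
        residues=[_fragment_from_dict(f) for f in d["residues"]],
        cutoff=d.get("cutoff", 5.0),
        capping_scheme=d.get("capping_scheme", "hydrogen-cap"),
        source_id=d.get("source_id", ""),
        include_waters=d.get("include_waters", False),
        provenance=d.get("provenance", {}))


def write_pocket(p: PocketModel, path) -> None:
    Path(path).write_text(json.dumps(pocket_to_dict(p), indent=1))


def read_pocket(path) -> PocketModel:
    return pocket_from_dict(json.loads(Path(path).read_text()))
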