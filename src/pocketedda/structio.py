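"""Reading and writing molecular structures and interaction-map reports.

Supported inputs: fixed-column PDB (ATOM/HETATM), V2000 SDF (through
RDKit) and plain XYZ.  Interaction maps serialize to a diff-able CSV
dialect with the versioned header line ``pocketedda-map v1``; a write →
read round trip reproduces every numeric field exactly.

The PDB reader implements the fixed-column subset deliberately: format
errors must cite the offending line number and alternate locations
resolve to the highest-occupancy conformer (ties keep the first listed),
giving a deterministic single-conformer model.
"""

from __future__ import annotations

import csv
import io
from pathlib import Path
from typing import Optional

from .energy import EnergyComponents
from .errors import FormatError
from .maps import InteractionMap, PairInteraction
from .records import (AtomRecord, Fragment, KNOWN_ELEMENTS,
                      MolecularStructure)

MAP_HEADER = "pocketedda-map v1"

_TWO_LETTER = {"CL", "BR", "NA", "MG", "CA", "FE", "ZN", "SE", "HE", "LI",
               "BE", "NE", "AL", "SI", "AR"}


def _element_from_name(name: str) -> str:
    """Infer the element from a PDB atom name when columns 77-78 are blank."""
    s = name.strip().lstrip("0123456789")
    if not s:
        raise FormatError(f"cannot infer element from atom name {name!r}")
    if s[:2].upper() in _TWO_LETTER and len(s) > 1:
        return s[:2].capitalize()
    return s[0].upper()


def _parse_float(line: str, lo: int, hi: int, what: str, lineno: int) -> float:
    text = line[lo:hi].strip()
    try:
        return float(text)
    except ValueError:
        raise FormatError(
            f"line {lineno}: unparsable {what} field {text!r}")


def read_structure(path, format: str = "pdb") -> MolecularStructure:
    """Read a protein/ligand complex from a fixed-column PDB file.

    Every ATOM/HETATM record becomes an :class:`AtomRecord`; residues
    keep their 1-based PDB numbering and HETATM groups are retrievable
    as ligand candidates by residue name.
    """
    if format != "pdb":
        raise FormatError(f"unsupported structure format {format!r}")
    path = Path(path)
    residues: dict = {}
    hetero: dict = {}
    # (chain, resnum, resname, atomname) -> (occupancy, AtomRecord)
    best: dict = {}
    order: list = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec not in ("ATOM", "HETATM"):
                continue
            name = line[12:16].strip()
            resname = line[17:20].strip()
            chain = line[21].strip()
            try:
                resnum = int(line[22:26])
            except ValueError:
                raise FormatError(
                    f"line {lineno}: unparsable residue number "
                    f"{line[22:26].strip()!r}")
            x = _parse_float(line, 30, 38, "x coordinate", lineno)
            y = _parse_float(line, 38, 46, "y coordinate", lineno)
            z = _parse_float(line, 46, 54, "z coordinate", lineno)
            occ_text = line[54:60].strip()
            occ = float(occ_text) if occ_text else 1.0
            elem = line[76:78].strip() if len(line) >= 78 else ""
            element = elem.capitalize() if elem else _element_from_name(name)
            if element not in KNOWN_ELEMENTS:
                raise FormatError(
                    f"line {lineno}: unrecognized element {element!r}")
            atom = AtomRecord(element=element, name=name, coords=(x, y, z))
            key = (chain, resnum, resname, name)
            if key in best:
                if occ > best[key][0]:  # tie keeps the first listed
                    best[key] = (occ, atom)
            else:
                best[key] = (occ, atom)
                order.append(key)
            hetero.setdefault((chain, resnum, resname), rec == "HETATM")
    if not best:
        raise FormatError(f"{path}: no ATOM/HETATM records (empty structure)")
    for key in order:
        chain, resnum, resname, _ = key
        residues.setdefault((chain, resnum, resname), []).append(best[key][1])
    return MolecularStructure(residues=residues, hetero=hetero,
                              source_id=path.stem)


def _read_xyz(path) -> Fragment:
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty XYZ file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise FormatError(f"{path}: line 1: invalid atom count")
    body = [ln for ln in lines[2:] if ln.strip()]
    if len(body) < n:
        raise FormatError(
            f"{path}: header declares {n} atoms but only {len(body)} listed")
    charge = 0
    for token in lines[1].split() if len(lines) > 1 else []:
        if token.startswith("charge="):
            charge = int(token.split("=", 1)[1])
    atoms = []
    for i, ln in enumerate(body[:n]):
        parts = ln.split()
        if len(parts) < 4:
            raise FormatError(f"{path}: atom line {i + 1}: expected 4 fields")
        try:
            coords = tuple(float(v) for v in parts[1:4])
        except ValueError:
            raise FormatError(
                f"{path}: atom line {i + 1}: non-numeric coordinate")
        atoms.append(AtomRecord(element=parts[0], name=f"{parts[0]}{i + 1}",
                                coords=coords))
    return Fragment(label=Path(path).stem, atoms=atoms, formal_charge=charge)


def _read_sdf(path) -> Fragment:
    from rdkit import Chem

    mol = Chem.MolFromMolFile(str(path), sanitize=False, removeHs=False)
    if mol is None:
        raise FormatError(f"{path}: unreadable V2000 SDF "
                          f"(atom-count/bond-block mismatch or corrupt file)")
    conf = mol.GetConformer()
    atoms = []
    for i, atom in enumerate(mol.GetAtoms()):
        pos = conf.GetAtomPosition(i)
        atoms.append(AtomRecord(element=atom.GetSymbol(),
                                name=f"{atom.GetSymbol()}{i + 1}",
                                coords=(pos.x, pos.y, pos.z)))
    charge = sum(a.GetFormalCharge() for a in mol.GetAtoms())
    return Fragment(label=Path(path).stem, atoms=atoms, formal_charge=charge)


def read_ligand(path, format: Optional[str] = None) -> Fragment:
    """Read a ligand from SDF (V2000) or XYZ.

    Atoms keep file order; partial charges are zero until a parameter
    table or pocket preparation assigns them.
    """
    if format is None:
        format = Path(path).suffix.lstrip(".").lower()
    if format == "xyz":
        return _read_xyz(path)
    if format in ("sdf", "mol"):
        return _read_sdf(path)
    raise FormatError(f"unsupported ligand format {format!r}")


# ---------------------------------------------------------------------------
# Interaction-map reports
# ---------------------------------------------------------------------------

_MAP_COLUMNS = ["label", "chain", "resnum", "total", "electrostatic",
                "dispersion", "repulsion", "hbond", "desolvation",
                "closest_contact", "refined"]


def _fmt(v: float) -> str:
    return f"{v:.17g}"


def write_interaction_map(imap: InteractionMap, path) -> None:
    """Serialize a map: one row per residue sorted by (chain, residue
    number), then a SUM footer whose components equal the column sums."""
    imap.validate()
    buf = io.StringIO()
    buf.write(MAP_HEADER + "\n")
    buf.write(f"# mode={imap.mode_label}\n")
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(_MAP_COLUMNS)
    for p in sorted(imap.pairs, key=lambda p: p.sort_key):
        c = p.components
        w.writerow([p.residue_label, p.chain,
                    "" if p.resnum is None else p.resnum,
                    _fmt(c.total), _fmt(c.electrostatic), _fmt(c.dispersion),
                    _fmt(c.repulsion), _fmt(c.hbond), _fmt(c.desolvation),
                    _fmt(p.closest_contact), int(p.refined)])
    s = imap.summed
    w.writerow(["SUM", "", "", _fmt(s.total), _fmt(s.electrostatic),
                _fmt(s.dispersion), _fmt(s.repulsion), _fmt(s.hbond),
                _fmt(s.desolvation), "", ""])
    Path(path).write_text(buf.getvalue())


def read_interaction_map(path) -> InteractionMap:
    """Inverse of :func:`write_interaction_map`."""
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].strip() != MAP_HEADER:
        raise FormatError(f"{path}: missing '{MAP_HEADER}' header line")
    mode = ""
    idx = 1
    while idx < len(lines) and lines[idx].startswith("#"):
        if lines[idx].startswith("# mode="):
            mode = lines[idx][len("# mode="):]
        idx += 1
    rows = list(csv.reader(lines[idx:]))
    if not rows or rows[0] != _MAP_COLUMNS:
        raise FormatError(f"{path}: malformed column header")
    pairs = []
    summed = None
    for row in rows[1:]:
        if not row:
            continue
        label = row[0]
        comp = EnergyComponents(
            total=float(row[3]), electrostatic=float(row[4]),
            dispersion=float(row[5]), repulsion=float(row[6]),
            hbond=float(row[7]), desolvation=float(row[8]))
        if label == "SUM":
            summed = comp
            continue
        pairs.append(PairInteraction(
            residue_label=label, components=comp,
            closest_contact=float(row[9]), refined=bool(int(row[10])),
            chain=row[1], resnum=int(row[2]) if row[2] else None))
    imap = InteractionMap(mode_label=mode, pairs=pairs)
    imap.recompute_sum()
    if summed is not None and abs(summed.total - imap.summed.total) > 1e-9:
        raise FormatError(f"{path}: SUM footer inconsistent with rows")
    return imap
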