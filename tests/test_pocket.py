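"""Pocket selection, capping and pair enumeration."""

import numpy as np
import pytest

from pocketedda.errors import ArgumentError, CappingError
from pocketedda.pocket import (cut_pocket, enumerate_pairs,
                               select_pocket_residues)
from pocketedda.records import AtomRecord, Fragment
from pocketedda.structio import read_structure

from conftest import pdb_line, point_ion


def _shell_structure(tmp_path, distances, resname="GLY", water_at=None):
    """Single-atom residues at given distances from the origin."""
    lines = []
    serial = 1
    for i, d in enumerate(distances):
        lines.append(pdb_line("ATOM", serial, "CA", resname, "A", i + 1,
                              d, 0, 0, element="C"))
        serial += 1
    if water_at is not None:
        lines.append(pdb_line("HETATM", serial, "O", "HOH", "A", 50,
                              water_at, 0, 0, element="O"))
    p = tmp_path / "shell.pdb"
    p.write_text("\n".join(lines) + "\n")
    return read_structure(p)


@pytest.fixture
def origin_ligand():
    return point_ion("LIG", (0.0, 0.0, 0.0), 0.0)


class TestSelection:
    def test_inclusive_boundary(self, tmp_path, origin_ligand):
        s = _shell_structure(tmp_path, [4.9, 5.0, 5.1])
        ids = select_pocket_residues(s, origin_ligand, 5.0)
        assert [k[1] for k in ids] == [1, 2]

    def test_large_cutoff_selects_all(self, tmp_path, origin_ligand):
        s = _shell_structure(tmp_path, [4.9, 5.0, 5.1])
        ids = select_pocket_residues(s, origin_ligand, 100.0)
        assert len(ids) == 3

    @pytest.mark.parametrize("c1,c2", [(3.0, 5.0), (4.9, 5.0), (5.0, 6.0)])
    def test_monotone_in_cutoff(self, tmp_path, origin_ligand, c1, c2):
        s = _shell_structure(tmp_path, [2.5, 4.2, 4.95, 5.0, 5.5, 7.0])
        small = set(select_pocket_residues(s, origin_ligand, c1))
        large = set(select_pocket_residues(s, origin_ligand, c2))
        assert small <= large

    def test_waters_excluded_by_default(self, tmp_path, origin_ligand):
        s = _shell_structure(tmp_path, [4.0], water_at=3.0)
        ids = select_pocket_residues(s, origin_ligand, 5.0)
        assert all(k[2] != "HOH" for k in ids)
        ids_w = select_pocket_residues(s, origin_ligand, 5.0,
                                       include_waters=True)
        assert any(k[2] == "HOH" for k in ids_w)

    def test_empty_ligand_rejected(self, tmp_path, origin_ligand):
        s = _shell_structure(tmp_path, [4.0])
        with pytest.raises(ArgumentError):
            select_pocket_residues(s, origin_ligand, -1.0)


class TestCapping:
    def test_middle_residue_gains_two_caps(self, tripeptide_pdb):
        s = read_structure(tripeptide_pdb)
        pocket = cut_pocket(s, [("A", 2, "ALA")])
        frag = pocket.residues[0]
        caps = [a for a in frag.atoms if a.is_cap]
        assert len(caps) == 2
        assert all(a.is_hydrogen and a.mobile for a in caps)

    def test_terminal_residue_gains_one_cap(self, tripeptide_pdb):
        s = read_structure(tripeptide_pdb)
        pocket = cut_pocket(s, [("A", 1, "GLY")])
        caps = [a for a in pocket.residues[0].atoms if a.is_cap]
        assert len(caps) == 1

    def test_cap_bond_lengths_standard(self, tripeptide_pdb):
        s = read_structure(tripeptide_pdb)
        frag = cut_pocket(s, [("A", 2, "ALA")]).residues[0]
        n_atom = next(a for a in frag.atoms if a.name == "N")
        c_atom = next(a for a in frag.atoms if a.name == "C")
        caps = [a for a in frag.atoms if a.is_cap]
        dists = sorted(
            min(np.linalg.norm(cap.coords - x.coords)
                for x in (n_atom, c_atom)) for cap in caps)
        assert dists[0] == pytest.approx(1.01, abs=1e-9)   # N–H cap
        assert dists[1] == pytest.approx(1.09, abs=1e-9)   # C–H cap

    def test_heavy_atoms_bitwise_unchanged(self, tripeptide_pdb):
        s = read_structure(tripeptide_pdb)
        original = {a.name: a.coords.copy()
                    for a in s.residues[("A", 2, "ALA")]}
        frag = cut_pocket(s, [("A", 2, "ALA")]).residues[0]
        for a in frag.atoms:
            if not a.is_cap:
                assert np.array_equal(a.coords, original[a.name])

    def test_charge_sums_to_formal_charge(self, tmp_path):
        # a lone Lys-like residue: formal charge +1 by protonation default
        lines = [pdb_line("ATOM", i + 1, nm, "LYS", "A", 5, *xyz,
                          element=el)
                 for i, (nm, xyz, el) in enumerate([
                     ("N", (0, 0, 0), "N"), ("CA", (1.45, 0, 0), "C"),
                     ("C", (2.0, 1.3, 0), "C"), ("O", (1.4, 2.3, 0), "O"),
                     ("CB", (2.2, -1.2, 0), "C"),
                     ("NZ", (3.5, -2.0, 0), "N")])]
        p = tmp_path / "lys.pdb"
        p.write_text("\n".join(lines) + "\n")
        s = read_structure(p)
        frag = cut_pocket(s, [("A", 5, "LYS")]).residues[0]
        assert frag.formal_charge == 1
        assert sum(a.charge for a in frag.atoms) == pytest.approx(1.0,
                                                                  abs=1e-6)

    def test_missing_backbone_raises_naming_residue(self, tmp_path):
        lines = [pdb_line("ATOM", 1, "CA", "ALA", "A", 7, 0, 0, 0,
                          element="C")]
        p = tmp_path / "broken.pdb"
        p.write_text("\n".join(lines) + "\n")
        s = read_structure(p)
        with pytest.raises(CappingError, match="ALA7"):
            cut_pocket(s, [("A", 7, "ALA")])

    def test_adjacent_selected_residues_not_capped_between(
            self, tripeptide_pdb):
        s = read_structure(tripeptide_pdb)
        pocket = cut_pocket(s, [("A", 1, "GLY"), ("A", 2, "ALA")])
        caps = [a for f in pocket.residues for a in f.atoms if a.is_cap]
        # only the Ala2→Gly3 bond is severed; Gly1–Ala2 stays intact
        assert len(caps) == 1


class TestEnumeratePairs:
    def test_ordering_matches_brute_force(self):
        rng = np.random.default_rng(7)
        lig = point_ion("LIG", (0, 0, 0), 0.0)
        frags = []
        for i, d in enumerate([6.0, 3.0, 4.5]):
            frags.append(point_ion(f"R{i + 1}", rng.normal(size=3) * 0.01
                                   + np.array([d, 0, 0]), 1.0))
        from pocketedda.pocket import PocketModel
        pocket = PocketModel(ligand=lig, residues=frags, cutoff=10.0)
        pairs = enumerate_pairs(pocket)
        brute = sorted(
            frags, key=lambda f: min(
                np.linalg.norm(a.coords - b.coords)
                for a in f.atoms for b in lig.atoms))
        assert [p.residue.label for p in pairs] == [f.label for f in brute]
        for p in pairs:
            expect = min(np.linalg.norm(a.coords - b.coords)
                         for a in p.residue.atoms for b in lig.atoms)
            assert p.closest_contact == pytest.approx(expect, abs=1e-12)

    def test_empty_residue_list(self):
        from pocketedda.pocket import PocketModel
        pocket = PocketModel(ligand=point_ion("LIG", (0, 0, 0), 0.0),
                             residues=[], cutoff=5.0)
        assert enumerate_pairs(pocket) == []

    def test_bijection_onto_residues(self):
        from pocketedda.fixtures import FixtureSpec, make_toy_pocket
        pocket = make_toy_pocket(FixtureSpec(n_residues=4))
        pairs = enumerate_pairs(pocket)
        assert sorted(p.residue.label for p in pairs) == sorted(
            f.label for f in pocket.residues)

    def test_duplicate_fragment_rejected_by_invariant(self):
        from pocketedda.pocket import PocketModel
        ion = point_ion("R1", (3.0, 0, 0), 1.0)
        pocket = PocketModel(ligand=point_ion("LIG", (0, 0, 0), 0.0),
                             residues=[ion, ion.copy()], cutoff=5.0)
        with pytest.raises(ArgumentError, match="disjoint"):
            pocket.validate()
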