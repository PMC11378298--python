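"""Extract and cap a binding pocket from a small PDB file.

Builds a Gly-Ala-Gly tripeptide with a nearby HETATM ligand, selects
every residue within 5 Å of the ligand, severs the selected residues
from the chain and caps the broken peptide bonds with hydrogens.
"""

import tempfile
from pathlib import Path

from pocketedda import cut_pocket, read_structure, select_pocket_residues

PDB = """\
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.450   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1       2.000   1.300   0.000  1.00  0.00           C
ATOM      4  O   GLY A   1       1.400   2.350   0.000  1.00  0.00           O
ATOM      5  N   ALA A   2       3.330   1.300   0.000  1.00  0.00           N
ATOM      6  CA  ALA A   2       4.200   2.400   0.000  1.00  0.00           C
ATOM      7  CB  ALA A   2       4.100   3.300   1.200  1.00  0.00           C
ATOM      8  C   ALA A   2       5.650   2.000   0.000  1.00  0.00           C
ATOM      9  O   ALA A   2       6.000   0.850   0.000  1.00  0.00           O
ATOM     10  N   GLY A   3       6.550   3.000   0.000  1.00  0.00           N
ATOM     11  CA  GLY A   3       7.980   2.900   0.000  1.00  0.00           C
ATOM     12  C   GLY A   3       8.600   4.280   0.000  1.00  0.00           C
ATOM     13  O   GLY A   3       7.950   5.300   0.000  1.00  0.00           O
HETATM   99  C1  LIG A  90       4.200   4.500   2.500  1.00  0.00           C
END
"""

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "complex.pdb"
    path.write_text(PDB)
    structure = read_structure(path)
    print(f"ligand candidates: {structure.ligand_candidates()}")

    ligand = structure.get_fragment("LIG")
    for cutoff in (5.0, 3.5):
        ids = select_pocket_residues(structure, ligand, cutoff=cutoff)
        print(f"residues within {cutoff} Å: "
              f"{[f'{r}{n}' for _, n, r in ids]}")

    # the tighter shell keeps only the middle residue, severing both of
    # its peptide bonds
    ids = select_pocket_residues(structure, ligand, cutoff=3.5)
    pocket = cut_pocket(structure, ids, ligand=ligand, cutoff=3.5)
    for frag in pocket.residues:
        caps = sum(a.is_cap for a in frag.atoms)
        print(f"  {frag.label}: {len(frag.atoms)} atoms, {caps} cap "
              f"hydrogen(s), formal charge {frag.formal_charge:+d}")

# The cap count shows how many peptide bonds were severed for each
# residue: interior residues gain two caps, chain termini fewer.
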