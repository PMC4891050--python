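"""Shared fixtures: synthetic pocket, interaction map, planted screen inputs."""

import pytest

from pharmscreen import (
    build_interaction_map, make_planted_library, make_toy_pocket, parse_pdb,
    parse_sdf, planted_hypothesis, toy_pocket_sphere,
)
from pharmscreen.imap import MIN_PAIR_DIST


TWO_ATOM_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
END
"""

# The five triaged compounds of the original campaign: id, MW (Da), RU,
# MMP-2 secretion inhibition (% control).
TABLE1 = [
    ("AF-399/15392135", 416.493958, 22.0, 17.47725),
    ("AN-979/15448127", 348.352051, 43.0, 11.15524),
    ("AN-465/42834501", 319.36942, 63.0, 55.72601),
    ("AG-205/13358154", 413.463562, 9.0, 39.42461),
    ("AG-205/12140154", 431.354523, 13.0, 41.13764),
]

AC73_SMILES = "OC(c1cccc(O)c1)CNCc1ccc(-c2ccccc2)cc1"


@pytest.fixture(scope="session")
def toy_pocket():
    return make_toy_pocket(seed=1)


@pytest.fixture(scope="session")
def toy_structure(toy_pocket):
    return parse_pdb(toy_pocket.pdb_text, structure_id="toy")


@pytest.fixture(scope="session")
def pocket_sphere():
    return toy_pocket_sphere()


@pytest.fixture(scope="session")
def interaction_map(toy_structure, pocket_sphere):
    return build_interaction_map(toy_structure, pocket_sphere)


@pytest.fixture(scope="session")
def planted_hyp(interaction_map, pocket_sphere):
    return planted_hypothesis(interaction_map.features, pocket_sphere, 4.5,
                              MIN_PAIR_DIST)


@pytest.fixture(scope="session")
def planted_screen(planted_hyp):
    """(ligands, labels) for the default 5-active / 45-decoy planted library."""
    sdf, labels = make_planted_library(planted_hyp, 5, 45, displacement=0.5, seed=1)
    return parse_sdf(sdf), labels


def embedded(smiles: str, ligand_id: str = ""):
    """A ligand with one deterministic 3D conformer (for feature tests)."""
    from rdkit import Chem
    from rdkit.Chem import AllChem
    from pharmscreen import Ligand, parse_smiles

    lig = parse_smiles(smiles, ligand_id)
    mol = Chem.AddHs(lig.mol)
    AllChem.EmbedMolecule(mol, randomSeed=7)
    return Ligand(id=lig.id, mol=Chem.RemoveHs(mol), multi_fragment=lig.multi_fragment)
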