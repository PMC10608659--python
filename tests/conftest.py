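import numpy as np
import pytest
from rdkit import Chem

from quinoscreen.chem_core import MoleculeGraph, parse_smiles

#: small fixture molecules (<= 14 heavy atoms) used across test modules
FIXTURE_SMILES = {
    "ethane": "CC",
    "propane": "CCC",
    "ethylene": "C=C",
    "butadiene": "C=CC=C",
    "benzene": "c1ccccc1",
    "toluene": "Cc1ccccc1",
    "acetonitrile": "CC#N",
    "fluoromethane": "CF",
    "benzoquinone": "O=C1C=CC(=O)C=C1",
    "naphthoquinone": "O=C1C=CC(=O)c2ccccc12",
    "phenol": "Oc1ccccc1",
}


@pytest.fixture(scope="session")
def fixture_mols() -> dict[str, MoleculeGraph]:
    return {name: parse_smiles(smi, name=name) for name, smi in FIXTURE_SMILES.items()}


@pytest.fixture
def benzoquinone() -> MoleculeGraph:
    return parse_smiles(FIXTURE_SMILES["benzoquinone"])


@pytest.fixture
def naphthoquinone() -> MoleculeGraph:
    return parse_smiles(FIXTURE_SMILES["naphthoquinone"])


def permuted_copy(mol: MoleculeGraph, rng: np.random.Generator) -> MoleculeGraph:
    """The same molecule with atoms relabelled by a random permutation."""
    rd = mol.to_rdkit()
    perm = rng.permutation(rd.GetNumAtoms())
    renumbered = Chem.RenumberAtoms(rd, [int(i) for i in perm])
    return MoleculeGraph.from_rdkit(renumbered)
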