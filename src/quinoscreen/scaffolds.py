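"""Built-in quinone scaffold fixtures.

A small library of common para- and ortho-quinones (benzo-, naphtho-,
anthra- and phenanthrenequinones with typical ring substituents) standing
in for database-extracted backbones.  They are the seeds of the synthetic
derivative sets used throughout testing and simulation.
"""

from __future__ import annotations

from quinoscreen.chem_core import MoleculeGraph, parse_smiles

QUINONE_SCAFFOLD_SMILES: tuple[tuple[str, str], ...] = (
    ("1,4-benzoquinone", "O=C1C=CC(=O)C=C1"),
    ("1,2-benzoquinone", "O=C1C=CC=CC1=O"),
    ("2-methyl-1,4-benzoquinone", "CC1=CC(=O)C=CC1=O"),
    ("2,3-dimethyl-1,4-benzoquinone", "CC1=C(C)C(=O)C=CC1=O"),
    ("2,5-dimethyl-1,4-benzoquinone", "CC1=CC(=O)C(C)=CC1=O"),
    ("2,6-dimethyl-1,4-benzoquinone", "CC1=CC(=O)C=C(C)C1=O"),
    ("2-tert-butyl-1,4-benzoquinone", "CC(C)(C)C1=CC(=O)C=CC1=O"),
    ("2-chloro-1,4-benzoquinone", "ClC1=CC(=O)C=CC1=O"),
    ("2,5-dichloro-1,4-benzoquinone", "ClC1=CC(=O)C(Cl)=CC1=O"),
    ("2-fluoro-1,4-benzoquinone", "FC1=CC(=O)C=CC1=O"),
    ("2-methoxy-1,4-benzoquinone", "COC1=CC(=O)C=CC1=O"),
    ("2-hydroxy-1,4-benzoquinone", "OC1=CC(=O)C=CC1=O"),
    ("1,4-naphthoquinone", "O=C1C=CC(=O)c2ccccc12"),
    ("1,2-naphthoquinone", "O=C1C=Cc2ccccc2C1=O"),
    ("2-methyl-1,4-naphthoquinone", "CC1=CC(=O)c2ccccc2C1=O"),
    ("2,3-dichloro-1,4-naphthoquinone", "ClC1=C(Cl)C(=O)c2ccccc2C1=O"),
    ("5-hydroxy-1,4-naphthoquinone", "Oc1cccc2c1C(=O)C=CC2=O"),
    ("5,8-dihydroxy-1,4-naphthoquinone", "Oc1ccc(O)c2c1C(=O)C=CC2=O"),
    ("9,10-anthraquinone", "O=C1c2ccccc2C(=O)c2ccccc21"),
    ("9,10-phenanthrenequinone", "O=C1C(=O)c2ccccc2-c2ccccc21"),
)


def builtin_scaffolds(n: int | None = None) -> list[MoleculeGraph]:
    """The first ``n`` built-in scaffolds (all of them by default)."""
    pairs = QUINONE_SCAFFOLD_SMILES if n is None else QUINONE_SCAFFOLD_SMILES[:n]
    return [parse_smiles(smiles, name=name) for name, smiles in pairs]
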