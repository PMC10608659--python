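"""Molecular graph core: SMILES I/O, canonicalization, symmetry classes.

Molecules are represented at the 2D graph level (elements, charges, attached
hydrogens, bond orders, aromaticity); the descriptor panel used downstream is
purely topological, so no 3D embedding is ever required.  RDKit performs
parsing, aromaticity perception (its default model) and canonical ranking;
the :class:`MoleculeGraph` container decouples the rest of the package from
the toolkit's object model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

#: bond order codes used throughout the package
BOND_ORDERS = (1, 2, 3, "ar")

_RD_BOND = {
    1: Chem.BondType.SINGLE,
    2: Chem.BondType.DOUBLE,
    3: Chem.BondType.TRIPLE,
    "ar": Chem.BondType.AROMATIC,
}
_FROM_RD_BOND = {v: k for k, v in _RD_BOND.items()}


@dataclass(frozen=True)
class Atom:
    """One heavy atom: element symbol, formal charge, attached-H count, aromatic flag."""

    element: str
    charge: int = 0
    n_h: int = 0
    aromatic: bool = False


@dataclass
class MoleculeGraph:
    """Connected molecular graph over heavy atoms.

    Bonds are triples ``(i, j, order)`` with ``order`` in ``{1, 2, 3, "ar"}``.
    Hydrogens are implicit (per-atom counts), which is sufficient for every
    topological descriptor in the panel.
    """

    atoms: list[Atom]
    bonds: list[tuple[int, int, object]]
    name: str = ""

    def __post_init__(self) -> None:
        n = len(self.atoms)
        seen: set[tuple[int, int]] = set()
        for i, j, order in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i},{j}) references a missing atom")
            if i == j:
                raise ValueError(f"self-bond on atom {i}")
            if order not in BOND_ORDERS:
                raise ValueError(f"unknown bond order {order!r}")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"duplicate bond {key}")
            seen.add(key)
        if any(a.n_h < 0 for a in self.atoms):
            raise ValueError("negative attached-H count")
        if n > 1 and not _connected(n, self.bonds):
            raise ValueError("molecule graph is not connected")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def to_rdkit(self) -> Chem.Mol:
        """Rebuild a sanitized RDKit molecule (H counts preserved explicitly)."""
        rw = Chem.RWMol()
        for a in self.atoms:
            ra = Chem.Atom(a.element)
            ra.SetFormalCharge(a.charge)
            ra.SetNumExplicitHs(a.n_h)
            ra.SetNoImplicit(True)
            ra.SetIsAromatic(a.aromatic)
            rw.AddAtom(ra)
        for i, j, order in self.bonds:
            rw.AddBond(i, j, _RD_BOND[order])
        mol = rw.GetMol()
        Chem.SanitizeMol(mol)
        return mol

    @classmethod
    def from_rdkit(cls, mol: Chem.Mol, name: str = "") -> "MoleculeGraph":
        atoms = [
            Atom(
                element=a.GetSymbol(),
                charge=a.GetFormalCharge(),
                n_h=a.GetTotalNumHs(),
                aromatic=a.GetIsAromatic(),
            )
            for a in mol.GetAtoms()
        ]
        bonds = [
            (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), _FROM_RD_BOND[b.GetBondType()])
            for b in mol.GetBonds()
        ]
        return cls(atoms=atoms, bonds=bonds, name=name)


@dataclass(frozen=True)
class AtomSymmetryClasses:
    """Partition of atoms into automorphism-equivalence classes."""

    class_ids: tuple[int, ...]

    @property
    def n_classes(self) -> int:
        return len(set(self.class_ids))

    def members(self, class_id: int) -> list[int]:
        return [i for i, c in enumerate(self.class_ids) if c == class_id]


@dataclass(frozen=True)
class RejectedRecord:
    """A SMILES line the reader refused, with a diagnostic."""

    line_number: int
    text: str
    reason: str


class SmilesParseError(ValueError):
    pass


def _connected(n: int, bonds: Iterable[tuple[int, int, object]]) -> bool:
    adj: dict[int, list[int]] = {i: [] for i in range(n)}
    for i, j, _ in bonds:
        adj[i].append(j)
        adj[j].append(i)
    stack, seen = [0], {0}
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return len(seen) == n


def _check_species(mol: Chem.Mol) -> str | None:
    """Reason string if the species is outside pipeline scope, else None."""
    if any(a.GetFormalCharge() != 0 for a in mol.GetAtoms()):
        return "charged species rejected (formal charge present)"
    if any(a.GetNumRadicalElectrons() > 0 for a in mol.GetAtoms()):
        return "radical species rejected (unpaired electrons)"
    if len(Chem.GetMolFrags(mol)) > 1:
        return "disconnected structure rejected (multiple fragments)"
    return None


def parse_smiles(line: str, name: str = "", allow_charged: bool = False) -> MoleculeGraph:
    """Parse one SMILES string into a :class:`MoleculeGraph`.

    Charged, radical and multi-fragment species are rejected by default:
    the quinone screening pipeline models neutral closed-shell molecules.

    Raises
    ------
    SmilesParseError
        On syntactically invalid SMILES or out-of-scope species.
    """
    text = line.strip()
    if not text:
        raise SmilesParseError("empty SMILES")
    mol = Chem.MolFromSmiles(text)
    if mol is None:
        raise SmilesParseError(f"unparseable SMILES: {text!r}")
    if not allow_charged:
        reason = _check_species(mol)
        if reason is not None:
            raise SmilesParseError(f"{reason}: {text!r}")
    return MoleculeGraph.from_rdkit(mol, name=name or text)


def canonical_form(mol: MoleculeGraph | Chem.Mol) -> str:
    """Canonical SMILES, identical for every atom ordering of one molecule."""
    rd = mol.to_rdkit() if isinstance(mol, MoleculeGraph) else mol
    return Chem.MolToSmiles(rd)


def symmetry_classes(mol: MoleculeGraph | Chem.Mol) -> AtomSymmetryClasses:
    """Automorphism-equivalence classes of atoms (Morgan-style canonical ranks
    without tie-breaking).  Class ids are renumbered to be stable under atom
    reordering: classes are labelled 0..k-1 in order of their canonical rank.
    """
    rd = mol.to_rdkit() if isinstance(mol, MoleculeGraph) else mol
    ranks = list(Chem.CanonicalRankAtoms(rd, breakTies=False))
    relabel = {r: c for c, r in enumerate(sorted(set(ranks)))}
    return AtomSymmetryClasses(tuple(relabel[r] for r in ranks))


def read_smiles_lines(
    lines: Iterable[str], allow_charged: bool = False
) -> tuple[list[MoleculeGraph], list[RejectedRecord]]:
    """Read one-SMILES-per-line input; parse failures are collected, not fatal.

    Lines may carry an optional whitespace-separated name after the SMILES.
    Blank lines and ``#`` comments are skipped silently.
    """
    mols: list[MoleculeGraph] = []
    rejected: list[RejectedRecord] = []
    for lineno, raw in enumerate(lines, start=1):
        text = raw.strip()
        if not text or text.startswith("#"):
            continue
        parts = text.split(None, 1)
        smiles = parts[0]
        name = parts[1].strip() if len(parts) > 1 else ""
        try:
            mols.append(parse_smiles(smiles, name=name, allow_charged=allow_charged))
        except SmilesParseError as exc:
            logger.warning("line %d rejected: %s", lineno, exc)
            rejected.append(RejectedRecord(lineno, text, str(exc)))
    return mols, rejected


def read_smiles_file(
    path: str | Path, allow_charged: bool = False
) -> tuple[list[MoleculeGraph], list[RejectedRecord]]:
    """Read a .smi file (one SMILES per line, optional trailing name)."""
    with open(path) as fh:
        return read_smiles_lines(fh, allow_charged=allow_charged)


def write_smiles_file(path: str | Path, mols: Sequence[MoleculeGraph]) -> None:
    with open(path, "w") as fh:
        for m in mols:
            fh.write(f"{canonical_form(m)}\t{m.name}\n" if m.name else f"{canonical_form(m)}\n")
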