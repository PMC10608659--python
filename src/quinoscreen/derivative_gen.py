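"""Systematic generation of substituted quinone derivatives.

Given scaffold molecules and monovalent substituents (by default the
electron-withdrawing nitrile -CN and propynyl -C#CMe groups), every
symmetry-unique carbon-bound hydrogen is replaced, products are deduplicated
by canonical SMILES, and substitution is iterated up to a configurable
multiplicity.  Substituting only one representative per atom-symmetry class
produces exactly the same product set as brute-force substitution at every
C-H followed by deduplication, at a fraction of the cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from rdkit import Chem

from quinoscreen.chem_core import MoleculeGraph, canonical_form, symmetry_classes


@dataclass(frozen=True)
class SubstituentSpec:
    """A monovalent substituent: attachment happens at the fragment's first atom."""

    name: str
    fragment_smiles: str

    def fragment(self) -> Chem.Mol:
        frag = Chem.MolFromSmiles(self.fragment_smiles)
        if frag is None:
            raise ValueError(f"bad substituent fragment {self.fragment_smiles!r}")
        attach = frag.GetAtomWithIdx(0)
        if attach.GetTotalNumHs() < 1:
            raise ValueError(
                f"substituent {self.name!r} is not monovalent: "
                "first atom has no free valence"
            )
        return frag


#: the electron-withdrawing substituents of the quinone screening study
CYANO = SubstituentSpec("CN", "C#N")
PROPYNYL = SubstituentSpec("CCMe", "C#CC")
DEFAULT_SUBSTITUENTS = (CYANO, PROPYNYL)


@dataclass(frozen=True)
class DerivativeRecord:
    molecule: MoleculeGraph
    parent: str  # canonical form of the immediate parent
    position_class: int  # symmetry class id of the substituted carbon
    substituent: str  # substituent name
    n_substitutions: int  # total substitutions relative to the original scaffold


@dataclass
class DerivativeSet:
    """Deduplicated derivatives, sorted by canonical form for determinism."""

    records: list[DerivativeRecord] = field(default_factory=list)
    n_duplicates_removed: int = 0

    @property
    def molecules(self) -> list[MoleculeGraph]:
        return [r.molecule for r in self.records]

    def __len__(self) -> int:
        return len(self.records)


def substitutable_positions(mol: MoleculeGraph) -> list[int]:
    """Atom indices of one representative carbon per symmetry class bearing >=1 H.

    Only carbon-bound hydrogens are substitution sites: replacing O-H or N-H
    would change the compound class, while C-H substitution by -CN / -C#CMe
    is the electron-withdrawing design move the screening targets.
    """
    classes = symmetry_classes(mol)
    chosen: dict[int, int] = {}
    for idx, atom in enumerate(mol.atoms):
        if atom.element != "C" or atom.n_h < 1:
            continue
        cls = classes.class_ids[idx]
        if cls not in chosen:
            chosen[cls] = idx
    return sorted(chosen.values())


def _attach(mol: MoleculeGraph, position: int, sub: SubstituentSpec) -> MoleculeGraph:
    """Replace one H on `position` with the substituent fragment."""
    scaffold = mol.to_rdkit()
    frag = sub.fragment()
    combined = Chem.RWMol(Chem.CombineMols(scaffold, frag))
    attach_idx = scaffold.GetNumAtoms()  # fragment atom 0 in the combined mol
    target = combined.GetAtomWithIdx(position)
    if target.GetNumExplicitHs() < 1:
        raise ValueError(f"atom {position} has no hydrogen to replace")
    target.SetNumExplicitHs(target.GetNumExplicitHs() - 1)
    frag_atom = combined.GetAtomWithIdx(attach_idx)
    free_h = frag_atom.GetTotalNumHs()
    frag_atom.SetNoImplicit(True)
    frag_atom.SetNumExplicitHs(free_h - 1)
    combined.AddBond(position, attach_idx, Chem.BondType.SINGLE)
    product = combined.GetMol()
    Chem.SanitizeMol(product)
    return MoleculeGraph.from_rdkit(product)


def enumerate_derivatives(
    scaffolds: Sequence[MoleculeGraph],
    subs: Sequence[SubstituentSpec] = DEFAULT_SUBSTITUENTS,
    max_substitutions: int = 1,
) -> DerivativeSet:
    """All distinct derivatives carrying 1..max_substitutions substituents.

    Substituents are validated monovalent.  Dedup is global (across scaffolds,
    substitution orders and multiplicities); output is sorted by canonical
    form so runs are deterministic regardless of input order.
    """
    if max_substitutions < 1:
        raise ValueError("max_substitutions must be >= 1")
    for sub in subs:
        sub.fragment()  # raises on non-monovalent configuration

    seen: set[str] = {canonical_form(s) for s in scaffolds}
    all_records: dict[str, DerivativeRecord] = {}
    attempts = 0
    frontier: list[MoleculeGraph] = list(scaffolds)
    for depth in range(1, max_substitutions + 1):
        next_frontier: list[MoleculeGraph] = []
        for parent in frontier:
            parent_canon = canonical_form(parent)
            classes = symmetry_classes(parent)
            for pos in substitutable_positions(parent):
                for sub in subs:
                    attempts += 1
                    child = _attach(parent, pos, sub)
                    canon = canonical_form(child)
                    if canon in seen:
                        continue
                    seen.add(canon)
                    child.name = canon
                    all_records[canon] = DerivativeRecord(
                        molecule=child,
                        parent=parent_canon,
                        position_class=classes.class_ids[pos],
                        substituent=sub.name,
                        n_substitutions=depth,
                    )
                    next_frontier.append(child)
        frontier = next_frontier
    ordered = [all_records[c] for c in sorted(all_records)]
    return DerivativeSet(records=ordered, n_duplicates_removed=attempts - len(ordered))


def brute_force_derivatives(
    scaffold: MoleculeGraph, subs: Sequence[SubstituentSpec]
) -> set[str]:
    """Oracle: substitute at EVERY C-H atom (ignoring symmetry), dedup canonically.

    Used to verify that symmetry-aware enumeration loses nothing.
    """
    out: set[str] = set()
    for idx, atom in enumerate(scaffold.atoms):
        if atom.element != "C" or atom.n_h < 1:
            continue
        for sub in subs:
            out.add(canonical_form(_attach(scaffold, idx, sub)))
    return out
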