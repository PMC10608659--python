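"""Pseudo-LUMO from a Hückel pi-electron model.

A simple-Hückel Hamiltonian is built over the molecule's conjugated
framework (atoms that are aromatic or engaged in double/triple bonds, plus
conjugating lone-pair donors bridging two such atoms).  Heteroatoms enter
through the standard Coulomb/resonance corrections

    H_ii = alpha + h_X * beta,        H_ij = k_XY * beta,

with Streitwieser-style h and k parameters, and the orbital energies are
reported in eV via configurable alpha and beta.  The lowest unoccupied
eigenvalue is the "pseudo-LUMO": a deterministic, desk-scale stand-in for a
semi-empirical LUMO that preserves the trend the screening relies on
(electron-withdrawing -CN substitution lowers it).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem

from quinoscreen.chem_core import MoleculeGraph

#: default orbital-energy scale (eV); alpha is the carbon 2p Coulomb
#: integral, beta the C-C resonance integral.  Both negative.
ALPHA_EV = -6.6
BETA_EV = -2.7


class NoPiSystemError(ValueError):
    """Molecule has no conjugated pi framework; pseudo-LUMO is undefined."""


@dataclass(frozen=True)
class PiAtomParams:
    h: float  # Coulomb correction, units of beta
    electrons: int  # pi electrons contributed


# one-pi-electron atoms (in multiple bonds / aromatic rings)
_H_PARAMS_PI1 = {"C": 0.0, "N": 0.5, "O": 1.0, "S": 0.5}
# two-electron lone-pair donors (pyrrole N, furan/ether O, halogens)
_H_PARAMS_PI2 = {"N": 1.5, "O": 2.0, "S": 1.5, "F": 3.0, "Cl": 2.0, "Br": 1.5}

# resonance corrections k by element pair (symmetric); default 1.0 for C-C
_K_PARAMS = {
    frozenset({"C"}): 1.0,
    frozenset({"C", "N"}): 1.0,
    frozenset({"C", "O"}): 1.0,
    frozenset({"C", "S"}): 0.7,
    frozenset({"N"}): 0.8,
    frozenset({"N", "O"}): 0.9,
    frozenset({"O"}): 0.8,
    frozenset({"C", "F"}): 0.7,
    frozenset({"C", "Cl"}): 0.4,
    frozenset({"C", "Br"}): 0.3,
}


def _pi_atoms(rd: Chem.Mol) -> dict[int, PiAtomParams]:
    """Conjugated atoms with their Hückel parameters.

    Pass 1 collects atoms in aromatic rings or multiple bonds (one pi
    electron each).  Pass 2 adds lone-pair donors: heteroatoms bonded to at
    least one pass-1 atom by a single bond (two pi electrons).
    """
    core: set[int] = set()
    for b in rd.GetBonds():
        if b.GetBondType() in (Chem.BondType.DOUBLE, Chem.BondType.TRIPLE, Chem.BondType.AROMATIC):
            core.add(b.GetBeginAtomIdx())
            core.add(b.GetEndAtomIdx())
    params: dict[int, PiAtomParams] = {}
    for idx in core:
        sym = rd.GetAtomWithIdx(idx).GetSymbol()
        if sym in _H_PARAMS_PI1:
            params[idx] = PiAtomParams(_H_PARAMS_PI1[sym], 1)
    for atom in rd.GetAtoms():
        idx = atom.GetIdx()
        if idx in params:
            continue
        sym = atom.GetSymbol()
        if sym not in _H_PARAMS_PI2:
            continue
        if any(nb.GetIdx() in params for nb in atom.GetNeighbors()):
            params[idx] = PiAtomParams(_H_PARAMS_PI2[sym], 2)
    return params


def huckel_orbital_energies(
    mol: MoleculeGraph | Chem.Mol, alpha: float = ALPHA_EV, beta: float = BETA_EV
) -> tuple[np.ndarray, int]:
    """Hückel orbital energies (ascending, eV) and pi-electron count."""
    rd = mol.to_rdkit() if isinstance(mol, MoleculeGraph) else mol
    params = _pi_atoms(rd)
    if not params:
        raise NoPiSystemError("no conjugated pi system")
    order = sorted(params)
    pos = {idx: i for i, idx in enumerate(order)}
    n = len(order)
    H = np.zeros((n, n))
    for idx in order:
        H[pos[idx], pos[idx]] = alpha + params[idx].h * beta
    for b in rd.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if i in params and j in params:
            pair = frozenset({rd.GetAtomWithIdx(i).GetSymbol(), rd.GetAtomWithIdx(j).GetSymbol()})
            k = _K_PARAMS.get(pair, 0.7)
            H[pos[i], pos[j]] = H[pos[j], pos[i]] = k * beta
    energies = np.sort(np.linalg.eigvalsh(H))
    n_electrons = sum(p.electrons for p in params.values())
    return energies, n_electrons


def pseudo_lumo(
    mol: MoleculeGraph | Chem.Mol, alpha: float = ALPHA_EV, beta: float = BETA_EV
) -> float:
    """Energy (eV) of the lowest unoccupied Hückel orbital.

    Orbitals are filled pairwise from the bottom; with an odd electron count
    the singly-occupied orbital is treated as occupied.
    """
    energies, n_el = huckel_orbital_energies(mol, alpha=alpha, beta=beta)
    n_occ = (n_el + 1) // 2
    if n_occ >= len(energies):
        raise NoPiSystemError("pi system has no virtual orbital")
    return float(energies[n_occ])
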