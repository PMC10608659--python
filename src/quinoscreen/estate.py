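"""Kier-Hall electrotopological state (E-state) indices and atom typing.

The intrinsic state of a heavy atom encodes its valence-electron richness
relative to its topological embedding:

    I = ((2/N)^2 * delta_v + 1) / delta

where ``N`` is the principal quantum number of the valence shell, ``delta_v``
the valence-electron connectivity (valence electrons minus attached
hydrogens) and ``delta`` the number of heavy-atom neighbours.  The E-state of
atom i adds distance-damped perturbations from every other heavy atom:

    S_i = I_i + sum_j (I_i - I_j) / d_ij^2,      d_ij = graph distance + 1.

Hydrogens are treated as graph nodes of their own for the hydrogen E-state:
an H has N = 1, delta_v = delta = 1, hence I_H = 5, and is perturbed by all
heavy atoms at distance (heavy-graph distance to the carrier) + 1.  This
keeps the whole formalism inside one formula; it is not intended to be
bit-compatible with any particular descriptor-software dialect.

Atom types follow the Kier-Hall bond-type grammar: ``s`` single, ``d``
double, ``t`` triple, ``a`` aromatic bonds on the atom, e.g. ``dssC`` is
=C<, ``aasC`` an aromatic carbon carrying a non-hydrogen substituent and
``tN`` a nitrile-type nitrogen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import GetDistanceMatrix, GetPeriodicTable

from quinoscreen.chem_core import MoleculeGraph

_PT = GetPeriodicTable()

#: principal quantum number by period
_PERIOD_BREAKS = (2, 10, 18, 36, 54, 86)


def principal_quantum_number(atomic_num: int) -> int:
    for n, upper in enumerate(_PERIOD_BREAKS, start=1):
        if atomic_num <= upper:
            return n
    return 7


def intrinsic_state_of(atom: Chem.Atom) -> float:
    """Kier-Hall intrinsic state of one heavy atom."""
    z = atom.GetAtomicNum()
    n = principal_quantum_number(z)
    delta_v = _PT.GetNOuterElecs(z) - atom.GetTotalNumHs()
    delta = atom.GetDegree()  # heavy-atom neighbours (implicit-H molecule)
    if delta == 0:
        raise ValueError("intrinsic state undefined for an isolated atom")
    return ((2.0 / n) ** 2 * delta_v + 1.0) / delta


@dataclass
class IntrinsicStateTable:
    """Per-heavy-atom intrinsic states I, E-states S, and per-H hydrogen E-states.

    ``hydrogen_estates[i]`` is the E-state of one hydrogen attached to heavy
    atom i (all H on the same heavy atom are equivalent at graph level);
    entries exist only for atoms carrying hydrogens.
    """

    intrinsic: np.ndarray  # (n_heavy,)
    estate: np.ndarray  # (n_heavy,)
    hydrogen_estates: dict[int, float]

    @property
    def mean_intrinsic(self) -> float:
        return float(np.mean(self.intrinsic))


def intrinsic_states(mol: MoleculeGraph | Chem.Mol) -> IntrinsicStateTable:
    """Intrinsic and E-states for every heavy atom, plus hydrogen E-states.

    Raises ``ValueError`` for single-heavy-atom molecules (delta = 0); callers
    flag the descriptor as undefined for those.
    """
    rd = mol.to_rdkit() if isinstance(mol, MoleculeGraph) else mol
    n = rd.GetNumAtoms()
    if n < 2:
        raise ValueError("E-state requires >= 2 heavy atoms")
    I = np.array([intrinsic_state_of(a) for a in rd.GetAtoms()])
    dist = np.asarray(GetDistanceMatrix(rd))  # topological distances, bonds
    d = dist + 1.0
    np.fill_diagonal(d, np.inf)
    # S_i = I_i + sum_j (I_i - I_j) / d_ij^2
    diff = I[:, None] - I[None, :]
    S = I + (diff / d**2).sum(axis=1)

    I_H = 5.0  # ((2/1)^2 * 1 + 1) / 1: H as its own Kier-Hall node
    hydrogen: dict[int, float] = {}
    for atom in rd.GetAtoms():
        if atom.GetTotalNumHs() < 1:
            continue
        i = atom.GetIdx()
        # distance from the H to heavy atom j: (carrier->j in bonds) + 1 bond,
        # then the Kier-Hall +1 offset
        d_h = dist[i] + 2.0
        hydrogen[i] = float(I_H + ((I_H - I) / d_h**2).sum())
    return IntrinsicStateTable(intrinsic=I, estate=S, hydrogen_estates=hydrogen)


def _bond_profile(atom: Chem.Atom) -> tuple[int, int, int, int]:
    """(n_single, n_double, n_triple, n_aromatic) bonds on the atom."""
    s = d = t = a = 0
    for b in atom.GetBonds():
        bt = b.GetBondType()
        if bt == Chem.BondType.SINGLE:
            s += 1
        elif bt == Chem.BondType.DOUBLE:
            d += 1
        elif bt == Chem.BondType.TRIPLE:
            t += 1
        elif bt == Chem.BondType.AROMATIC:
            a += 1
    return s, d, t, a


def atom_type(atom: Chem.Atom) -> str | None:
    """Kier-Hall type label for the atom types the descriptor panel uses.

    Returns one of ``dsCH, dCH2, dssC, aasC, aaCH, tN, dO`` or None.
    """
    sym = atom.GetSymbol()
    n_h = atom.GetTotalNumHs()
    s, d, t, a = _bond_profile(atom)
    if sym == "C":
        if a == 2 and s == 1 and n_h == 0:
            return "aasC"
        if a == 2 and s == 0 and n_h == 1:
            return "aaCH"
        if d == 1 and s == 1 and n_h == 1:
            return "dsCH"
        if d == 1 and s == 0 and n_h == 2:
            return "dCH2"
        if d == 1 and s == 2 and n_h == 0:
            return "dssC"
    elif sym == "N":
        if t == 1 and s == 0 and n_h == 0:
            return "tN"
    elif sym == "O":
        if d == 1 and s == 0 and n_h == 0:
            return "dO"
    return None


#: atom types whose hydrogens feed the "Hother" hydrogen E-state descriptors
HOTHER_TYPES = ("aaCH", "dCH2", "dsCH")


def max_intrinsic_differences(rd: Chem.Mol, I: np.ndarray) -> tuple[float, float]:
    """(MAXDN2, MAXDP2): largest negative / positive per-atom intrinsic-state
    variation, where the variation of atom i is the sum of (I_i - I_j) over
    its bonded neighbours j.  Zero for molecules with all atoms equivalent.
    """
    delta = np.zeros(len(I))
    for b in rd.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        delta[i] += I[i] - I[j]
        delta[j] += I[j] - I[i]
    maxdn = float(max(0.0, -delta.min()))
    maxdp = float(max(0.0, delta.max()))
    return maxdn, maxdp
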