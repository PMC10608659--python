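"""The 32-descriptor panel used for quinone redox-potential QSPR.

All descriptors are topological/graph-level and computed natively from the
molecular graph: electrotopological-state families (:mod:`quinoscreen.estate`),
Burden-matrix charge extremes (BCUT), eccentric-connectivity and charge-index
topology, the Zhao additive van der Waals volume, Ertl's TPSA (via RDKit) and
a Hückel pseudo-LUMO (:mod:`quinoscreen.huckel`).

Units: MW in g/mol, TopoPSA in A^2, VABC in A^3, LUMO in eV; everything else
is dimensionless.

Descriptors that can be undefined for a molecule (no pi system, no matching
atom type, element outside the volume table) are emitted as 0 with a paired
``<name>_missing`` flag column, so downstream selection can treat them
uniformly instead of dropping rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import GetDistanceMatrix, rdMolDescriptors, Descriptors
from rdkit.Chem.rdPartialCharges import ComputeGasteigerCharges

from quinoscreen.chem_core import MoleculeGraph, canonical_form
from quinoscreen.estate import (
    HOTHER_TYPES,
    IntrinsicStateTable,
    atom_type,
    intrinsic_states,
    max_intrinsic_differences,
)
from quinoscreen.huckel import ALPHA_EV, BETA_EV, NoPiSystemError, pseudo_lumo

#: canonical column order of the descriptor panel
DESCRIPTOR_NAMES = (
    "BCUTc-1l",
    "BCUTc-1h",
    "nBondsD2",
    "C1SP1",
    "C3SP2",
    "ECCEN",
    "nHother",
    "ndssC",
    "naasC",
    "ntN",
    "SwHBa",
    "SHdsCH",
    "SHother",
    "SdssC",
    "SaasC",
    "StN",
    "minHother",
    "minaasC",
    "mindO",
    "maxHother",
    "maxaasC",
    "meanI",
    "MAXDN2",
    "MAXDP2",
    "fragC",
    "nRing",
    "topoDiameter",
    "JGI2",
    "TopoPSA",
    "VABC",
    "MW",
    "LUMO",
)

#: descriptors that may be undefined; each gets a "<name>_missing" flag column
FLAGGABLE = (
    "BCUTc-1l",
    "BCUTc-1h",
    "meanI",
    "minHother",
    "minaasC",
    "mindO",
    "maxHother",
    "maxaasC",
    "VABC",
    "LUMO",
)

# Zhao et al. additive atomic van der Waals volumes (A^3)
_ZHAO_VOLUME = {
    "H": 7.24, "C": 20.58, "N": 15.60, "O": 14.71, "F": 13.31,
    "Cl": 22.45, "Br": 26.52, "I": 32.52, "P": 24.43, "S": 24.43,
    "As": 26.52, "B": 40.48, "Si": 38.79, "Se": 28.73, "Te": 36.62,
}

#: default weak hydrogen-bond-acceptor atom set for SwHBa: heteroatoms whose
#: lone pairs are pi-delocalized (hence weak acceptors) plus fluorine
def _is_weak_hba(atom: Chem.Atom) -> bool:
    sym = atom.GetSymbol()
    if sym == "F":
        return True
    if sym in ("O", "S") and atom.GetIsAromatic():
        return True
    if sym == "N" and atom_type(atom) == "tN":
        return True
    return False


@dataclass
class DescriptorConfig:
    """Tunables of the descriptor panel."""

    huckel_alpha_ev: float = ALPHA_EV
    huckel_beta_ev: float = BETA_EV
    gasteiger_iterations: int = 8
    weak_hba_predicate: object = field(default=_is_weak_hba, repr=False)


DEFAULT_CONFIG = DescriptorConfig()


@dataclass
class DescriptorVector:
    canonical: str
    values: dict[str, float]
    missing: dict[str, bool]


# ---------------------------------------------------------------------------
# individual descriptor families
# ---------------------------------------------------------------------------

def burden_matrix(rd: Chem.Mol, diagonal: np.ndarray) -> np.ndarray:
    """Burden connectivity matrix: given diagonal property, bonded entries
    0.1 x bond order (0.15 aromatic) with +0.01 for terminal bonds, and 0.001
    for all non-bonded pairs."""
    n = rd.GetNumAtoms()
    B = np.full((n, n), 0.001)
    np.fill_diagonal(B, diagonal)
    weight = {
        Chem.BondType.SINGLE: 0.1,
        Chem.BondType.DOUBLE: 0.2,
        Chem.BondType.TRIPLE: 0.3,
        Chem.BondType.AROMATIC: 0.15,
    }
    for b in rd.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        w = weight[b.GetBondType()]
        if rd.GetAtomWithIdx(i).GetDegree() == 1 or rd.GetAtomWithIdx(j).GetDegree() == 1:
            w += 0.01
        B[i, j] = B[j, i] = w
    return B


def bcut_extremes(
    mol: MoleculeGraph | Chem.Mol, n_iterations: int = 8
) -> tuple[float, float]:
    """(lowest, highest) eigenvalue of the Gasteiger-charge-weighted Burden matrix."""
    rd = mol.to_rdkit() if isinstance(mol, MoleculeGraph) else Chem.Mol(mol)
    ComputeGasteigerCharges(rd, nIter=n_iterations)
    q = np.array([a.GetDoubleProp("_GasteigerCharge") for a in rd.GetAtoms()])
    if not np.all(np.isfinite(q)):
        raise ValueError("Gasteiger charges did not converge to finite values")
    eig = np.linalg.eigvalsh(burden_matrix(rd, q))
    return float(eig[0]), float(eig[-1])


def vabc_volume(mol: MoleculeGraph | Chem.Mol) -> float:
    """Zhao additive van der Waals volume (A^3):
    sum of atom contributions - 5.92 N_bonds - 14.7 R_aromatic - 3.8 R_nonaromatic,
    with hydrogens and their bonds counted explicitly."""
    rd = mol.to_rdkit() if isinstance(mol, MoleculeGraph) else mol
    total = 0.0
    n_h = 0
    for atom in rd.GetAtoms():
        sym = atom.GetSymbol()
        if sym not in _ZHAO_VOLUME:
            raise ValueError(f"element {sym} outside the Zhao volume table")
        total += _ZHAO_VOLUME[sym]
        n_h += atom.GetTotalNumHs()
    total += n_h * _ZHAO_VOLUME["H"]
    n_bonds = rd.GetNumBonds() + n_h
    ring_info = rd.GetRingInfo()
    n_arom = n_nonarom = 0
    for ring in ring_info.BondRings():
        if all(rd.GetBondWithIdx(b).GetIsAromatic() for b in ring):
            n_arom += 1
        else:
            n_nonarom += 1
    return total - 5.92 * n_bonds - 14.7 * n_arom - 3.8 * n_nonarom


def eccentric_connectivity(rd: Chem.Mol, dist: np.ndarray) -> tuple[float, float]:
    """(ECCEN, topoDiameter): sum of eccentricity x degree, and max eccentricity."""
    ecc = dist.max(axis=1)
    deg = np.array([a.GetDegree() for a in rd.GetAtoms()])
    return float((ecc * deg).sum()), float(ecc.max())


def mean_topological_charge_index(rd: Chem.Mol, dist: np.ndarray, order: int = 2) -> float:
    """Galvez mean topological charge index J_k = G_k / (N - 1), where
    G_k sums |m_ij - m_ji| over atom pairs at topological distance k and
    M = A Q with A the adjacency matrix and Q the inverse-square distance
    matrix (zero diagonal)."""
    n = rd.GetNumAtoms()
    if n < 2:
        return 0.0
    A = np.zeros((n, n))
    for b in rd.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        A[i, j] = A[j, i] = 1.0
    with np.errstate(divide="ignore"):
        Q = np.where(dist > 0, 1.0 / np.maximum(dist, 1) ** 2, 0.0)
    np.fill_diagonal(Q, 0.0)
    M = A @ Q
    CT = M - M.T
    iu = np.triu_indices(n, k=1)
    mask = dist[iu] == order
    return float(np.abs(CT[iu])[mask].sum() / (n - 1))


def fragment_complexity(rd: Chem.Mol) -> float:
    """Structural complexity |B^2 - A^2 + A| + H/100 over heavy atoms A,
    heavy bonds B and heteroatoms H."""
    a = rd.GetNumAtoms()
    b = rd.GetNumBonds()
    h = sum(1 for at in rd.GetAtoms() if at.GetSymbol() not in ("C", "H"))
    return float(abs(b**2 - a**2 + a) + h / 100.0)


def _carbon_hybrid_counts(rd: Chem.Mol) -> tuple[int, int]:
    """(C1SP1, C3SP2): triply-bound carbons with one carbon neighbour, and
    doubly-bound carbons with three carbon neighbours."""
    c1sp1 = c3sp2 = 0
    for atom in rd.GetAtoms():
        if atom.GetSymbol() != "C":
            continue
        bts = [b.GetBondType() for b in atom.GetBonds()]
        n_c = sum(1 for nb in atom.GetNeighbors() if nb.GetSymbol() == "C")
        if Chem.BondType.TRIPLE in bts and n_c == 1:
            c1sp1 += 1
        if Chem.BondType.DOUBLE in bts and n_c == 3:
            c3sp2 += 1
    return c1sp1, c3sp2


def _estate_panel(
    rd: Chem.Mol, states: IntrinsicStateTable, config: DescriptorConfig
) -> tuple[dict[str, float], dict[str, bool]]:
    """Count / sum / min / max atom-type E-state descriptors (Table panel)."""
    by_type: dict[str, list[float]] = {}
    h_by_type: dict[str, list[float]] = {}
    h_counts: dict[str, int] = {}
    swhba = 0.0
    for atom in rd.GetAtoms():
        i = atom.GetIdx()
        t = atom_type(atom)
        if t is not None:
            by_type.setdefault(t, []).append(float(states.estate[i]))
            n_h = atom.GetTotalNumHs()
            if n_h and i in states.hydrogen_estates:
                h_by_type.setdefault(t, []).extend([states.hydrogen_estates[i]] * n_h)
                h_counts[t] = h_counts.get(t, 0) + n_h
        if config.weak_hba_predicate(atom):
            swhba += float(states.estate[i])

    def agg(typ: str, fn, hydrogen: bool = False) -> tuple[float, bool]:
        pool: list[float] = []
        if hydrogen:
            pool = h_by_type.get(typ, [])
        else:
            pool = by_type.get(typ, [])
        if not pool:
            return 0.0, True
        return float(fn(pool)), False

    hother = [v for t in HOTHER_TYPES for v in h_by_type.get(t, [])]
    values: dict[str, float] = {}
    missing: dict[str, bool] = {}
    values["nHother"] = float(sum(h_counts.get(t, 0) for t in HOTHER_TYPES))
    values["ndssC"] = float(len(by_type.get("dssC", [])))
    values["naasC"] = float(len(by_type.get("aasC", [])))
    values["ntN"] = float(len(by_type.get("tN", [])))
    values["SwHBa"] = swhba
    values["SHdsCH"], _ = agg("dsCH", sum, hydrogen=True)
    values["SHother"] = float(sum(hother))
    values["SdssC"], _ = agg("dssC", sum)
    values["SaasC"], _ = agg("aasC", sum)
    values["StN"], _ = agg("tN", sum)
    values["minHother"], missing["minHother"] = (
        (float(min(hother)), False) if hother else (0.0, True)
    )
    values["maxHother"], missing["maxHother"] = (
        (float(max(hother)), False) if hother else (0.0, True)
    )
    values["minaasC"], missing["minaasC"] = agg("aasC", min)
    values["maxaasC"], missing["maxaasC"] = agg("aasC", max)
    values["mindO"], missing["mindO"] = agg("dO", min)
    return values, missing


# ---------------------------------------------------------------------------
# panel assembly
# ---------------------------------------------------------------------------

def compute_descriptors(
    mol: MoleculeGraph, config: DescriptorConfig = DEFAULT_CONFIG
) -> DescriptorVector:
    """Full descriptor panel for one molecule."""
    rd = mol.to_rdkit()
    canon = canonical_form(rd)
    dist = np.asarray(GetDistanceMatrix(rd))
    values: dict[str, float] = {}
    missing: dict[str, bool] = {name: False for name in FLAGGABLE}

    try:
        lo, hi = bcut_extremes(rd, n_iterations=config.gasteiger_iterations)
        values["BCUTc-1l"], values["BCUTc-1h"] = lo, hi
    except ValueError:
        values["BCUTc-1l"] = values["BCUTc-1h"] = 0.0
        missing["BCUTc-1l"] = missing["BCUTc-1h"] = True

    values["nBondsD2"] = float(
        sum(1 for b in rd.GetBonds() if b.GetBondType() == Chem.BondType.DOUBLE)
    )
    c1sp1, c3sp2 = _carbon_hybrid_counts(rd)
    values["C1SP1"], values["C3SP2"] = float(c1sp1), float(c3sp2)

    eccen, diameter = eccentric_connectivity(rd, dist)
    values["ECCEN"], values["topoDiameter"] = eccen, diameter

    try:
        states = intrinsic_states(rd)
    except ValueError:
        # single heavy atom: the whole E-state family is undefined
        for name in (
            "nHother", "ndssC", "naasC", "ntN", "SwHBa", "SHdsCH", "SHother",
            "SdssC", "SaasC", "StN", "minHother", "minaasC", "mindO",
            "maxHother", "maxaasC", "meanI", "MAXDN2", "MAXDP2",
        ):
            values[name] = 0.0
        for name in ("meanI", "minHother", "minaasC", "mindO", "maxHother", "maxaasC"):
            missing[name] = True
    else:
        est_values, est_missing = _estate_panel(rd, states, config)
        values.update(est_values)
        missing.update(est_missing)
        values["meanI"] = states.mean_intrinsic
        maxdn, maxdp = max_intrinsic_differences(rd, states.intrinsic)
        values["MAXDN2"], values["MAXDP2"] = maxdn, maxdp

    values["fragC"] = fragment_complexity(rd)
    values["nRing"] = float(rd.GetNumBonds() - rd.GetNumAtoms() + 1)
    values["JGI2"] = mean_topological_charge_index(rd, dist, order=2)
    values["TopoPSA"] = float(rdMolDescriptors.CalcTPSA(rd))
    try:
        values["VABC"] = vabc_volume(rd)
    except ValueError:
        values["VABC"] = 0.0
        missing["VABC"] = True
    values["MW"] = float(Descriptors.MolWt(rd))
    try:
        values["LUMO"] = pseudo_lumo(
            rd, alpha=config.huckel_alpha_ev, beta=config.huckel_beta_ev
        )
    except NoPiSystemError:
        values["LUMO"] = 0.0
        missing["LUMO"] = True

    ordered = {name: values[name] for name in DESCRIPTOR_NAMES}
    return DescriptorVector(canonical=canon, values=ordered, missing=missing)


def compute_descriptor_table(
    mols: list[MoleculeGraph], config: DescriptorConfig = DEFAULT_CONFIG
) -> pd.DataFrame:
    """One row per molecule (index = canonical SMILES), fixed panel column
    order, with ``<name>_missing`` flag columns appended.

    Per-molecule failures never drop rows: affected descriptors are zeroed
    and flagged.
    """
    flag_cols = [f"{name}_missing" for name in FLAGGABLE]
    rows, index = [], []
    for mol in mols:
        vec = compute_descriptors(mol, config=config)
        row = dict(vec.values)
        for name in FLAGGABLE:
            row[f"{name}_missing"] = int(vec.missing.get(name, False))
        rows.append(row)
        index.append(vec.canonical)
    table = pd.DataFrame(rows, index=pd.Index(index, name="canonical_smiles"))
    if table.empty:
        table = pd.DataFrame(
            columns=list(DESCRIPTOR_NAMES) + flag_cols,
            index=pd.Index([], name="canonical_smiles"),
        )
    return table[list(DESCRIPTOR_NAMES) + flag_cols]
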