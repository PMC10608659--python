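"""Gibbs free-energy bookkeeping and the Nernst conversion to electrode potentials.

The redox label of a quinone Q is the potential of its two-electron,
two-lithium reduction Q + 2 Li -> Li2Q:

    dG = G(Li2Q) - G(Q) - 2 G(Li)
    dE = -dG / (n F)            (n = 2 electrons by default)

Species free energies are assembled from standard gas-phase statistical
thermodynamics components:

    H = E0 + ZPE + H_trans + H_rot + H_vib + R T
    S = S_trans + S_rot + S_vib + S_el
    G = H - T S

The quantum-chemistry computation that produces the components is outside
this package; only the bookkeeping and unit handling live here.  Internal
unit is J/mol; readers accept hartree and eV with explicit unit tags.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

#: physical constants
FARADAY = 96485.332  # C/mol
GAS_CONSTANT = 8.31446  # J/(mol K)
HARTREE_TO_J_PER_MOL = 2625499.6
EV_TO_J_PER_MOL = 96485.332

_ENERGY_UNIT_FACTORS = {
    "J/mol": 1.0,
    "hartree": HARTREE_TO_J_PER_MOL,
    "eV": EV_TO_J_PER_MOL,
}

_ENERGY_FIELDS = ("E0", "ZPE", "H_trans", "H_rot", "H_vib")
_ENTROPY_FIELDS = ("S_trans", "S_rot", "S_vib", "S_el")


@dataclass(frozen=True)
class ThermoRecord:
    """Thermochemistry components for one species, J/mol and J/(mol K)."""

    species_id: str
    E0: float
    ZPE: float = 0.0
    H_trans: float = 0.0
    H_rot: float = 0.0
    H_vib: float = 0.0
    S_trans: float = 0.0
    S_rot: float = 0.0
    S_vib: float = 0.0
    S_el: float = 0.0
    T: float = 298.0

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("temperature must be positive")
        for name in _ENERGY_FIELDS + _ENTROPY_FIELDS:
            v = getattr(self, name)
            if not (v == v and abs(v) != float("inf")):
                raise ValueError(f"non-finite thermo component {name}")


@dataclass(frozen=True)
class RedoxLabel:
    """Electrode potential of one molecule's reduction reaction."""

    canonical: str
    delta_e_volts: float
    delta_g_j_per_mol: float
    n_electrons: int = 2


def gibbs_free_energy(rec: ThermoRecord) -> tuple[float, float, float]:
    """(H, S, G) in J/mol, J/(mol K), J/mol; includes the R T work term."""
    h = rec.E0 + rec.ZPE + rec.H_trans + rec.H_rot + rec.H_vib + GAS_CONSTANT * rec.T
    s = rec.S_trans + rec.S_rot + rec.S_vib + rec.S_el
    return h, s, h - rec.T * s


def reaction_free_energy(g_reduced: float, g_oxidized: float, g_li: float) -> float:
    """dG of Q + 2 Li -> Li2Q from species free energies (J/mol)."""
    return g_reduced - g_oxidized - 2.0 * g_li


def redox_potential(delta_g: float, n: int = 2) -> float:
    """Nernst conversion dE = -dG / (n F), volts."""
    if n < 1:
        raise ValueError("number of exchanged electrons must be >= 1")
    return -delta_g / (n * FARADAY)


def label_from_records(
    canonical: str,
    oxidized: ThermoRecord,
    reduced: ThermoRecord,
    lithium: ThermoRecord,
    n: int = 2,
) -> RedoxLabel:
    """Full chain: three species records -> dG -> dE."""
    _, _, g_ox = gibbs_free_energy(oxidized)
    _, _, g_red = gibbs_free_energy(reduced)
    _, _, g_li = gibbs_free_energy(lithium)
    dg = reaction_free_energy(g_red, g_ox, g_li)
    return RedoxLabel(
        canonical=canonical,
        delta_e_volts=redox_potential(dg, n=n),
        delta_g_j_per_mol=dg,
        n_electrons=n,
    )


# ---------------------------------------------------------------------------
# JSON I/O
# ---------------------------------------------------------------------------

def record_to_dict(rec: ThermoRecord, units: str = "J/mol") -> dict:
    factor = _ENERGY_UNIT_FACTORS[units]
    out = {"id": rec.species_id, "units": units, "T": rec.T}
    for name in _ENERGY_FIELDS:
        out[name] = getattr(rec, name) / factor
    for name in _ENTROPY_FIELDS:
        out[name] = getattr(rec, name)  # entropies stay in J/(mol K)
    return out


def record_from_dict(d: dict) -> ThermoRecord:
    """Parse one species record; the ``units`` tag applies to energy fields
    (entropies are always J/(mol K))."""
    units = d.get("units", "J/mol")
    if units not in _ENERGY_UNIT_FACTORS:
        raise ValueError(f"unknown energy unit {units!r} (use J/mol, hartree or eV)")
    factor = _ENERGY_UNIT_FACTORS[units]
    kwargs = {name: float(d.get(name, 0.0)) * factor for name in _ENERGY_FIELDS}
    kwargs.update({name: float(d.get(name, 0.0)) for name in _ENTROPY_FIELDS})
    return ThermoRecord(species_id=str(d["id"]), T=float(d.get("T", 298.0)), **kwargs)


def write_records(path: str | Path, records: Iterable[ThermoRecord]) -> None:
    with open(path, "w") as fh:
        json.dump([record_to_dict(r) for r in records], fh, indent=1)


def read_records(path: str | Path) -> list[ThermoRecord]:
    with open(path) as fh:
        return [record_from_dict(d) for d in json.load(fh)]
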