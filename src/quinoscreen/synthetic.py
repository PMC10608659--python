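"""Synthetic datasets with the statistical structure the analysis assumes.

The generator builds a real derivative population (built-in quinone
scaffolds, -CN / -C#CMe substitution up to multiplicity 2) and computes the
real descriptor panel for it; only the labels are synthesized.  The label
model is linear in chemistry-driven quantities,

    dE = b0 + b_CN n_CN + b_alk n_alk + b_L LUMO + eps,   eps ~ N(0, sigma^2),

with electron-withdrawing -CN raising the potential and a negative
pseudo-LUMO coefficient (lower LUMO -> stronger oxidant -> higher
potential).  Labels are clipped to the physically sensible window
(0.3-2.8 V); defaults put the bulk of the distribution between 0.75 and
1.60 V with a right tail of strongly substituted, low-LUMO compounds.
Thermochemistry records are back-solved so that the free-energy
bookkeeping reproduces every label exactly.

A second generator plants a known ground truth for the feature-selection
pipeline: informative columns entering the label linearly, independent
noise columns (including one constant), and duplicate copies of
informative columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from rdkit import Chem

from quinoscreen.derivative_gen import (
    DEFAULT_SUBSTITUENTS,
    DerivativeRecord,
    enumerate_derivatives,
)
from quinoscreen.descriptors import compute_descriptor_table
from quinoscreen.scaffolds import builtin_scaffolds
from quinoscreen.thermo import (
    FARADAY,
    GAS_CONSTANT,
    RedoxLabel,
    ThermoRecord,
    gibbs_free_energy,
)

_CN_PATTERN = Chem.MolFromSmarts("[#6]#[#7]")
_ALKYNYL_PATTERN = Chem.MolFromSmarts("[#6]#[#6]-[CH3]")


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions of the simulated screening campaign."""

    seed: int = 0
    n_scaffolds: int = 15
    max_substitutions: int = 2
    intercept_v: float = -1.2
    cn_effect_v: float = 0.30
    alkynyl_effect_v: float = 0.10
    lumo_coeff_v_per_ev: float = -0.30
    noise_sd_v: float = 0.12
    clip_range_v: tuple[float, float] = (0.3, 2.8)
    n_electrons: int = 2

    def __post_init__(self) -> None:
        if self.noise_sd_v < 0:
            raise ValueError("noise sd must be >= 0")
        if self.clip_range_v[0] >= self.clip_range_v[1]:
            raise ValueError("clip range must be (low, high) with low < high")


@dataclass
class SyntheticDataset:
    features: pd.DataFrame  # descriptor panel, index = canonical SMILES
    labels: pd.Series  # dE in volts, same index
    label_records: list[RedoxLabel]
    thermo_records: list[ThermoRecord]
    truth: dict = field(default_factory=dict)
    derivative_records: list[DerivativeRecord] = field(default_factory=list)
    n_clipped: int = 0


@lru_cache(maxsize=4)
def _base_population(n_scaffolds: int, max_substitutions: int):
    """Derivatives + descriptors for the deterministic molecular population.

    Cached: the molecules and their descriptors do not depend on the seed,
    only the synthetic labels do.
    """
    scaffolds = builtin_scaffolds(n_scaffolds)
    if not scaffolds:
        raise ValueError("empty scaffold fixture set")
    derivatives = enumerate_derivatives(
        scaffolds, DEFAULT_SUBSTITUENTS, max_substitutions=max_substitutions
    )
    mols = derivatives.molecules
    features = compute_descriptor_table(mols)
    n_cn = np.array(
        [len(m.to_rdkit().GetSubstructMatches(_CN_PATTERN)) for m in mols]
    )
    n_alk = np.array(
        [len(m.to_rdkit().GetSubstructMatches(_ALKYNYL_PATTERN)) for m in mols]
    )
    return derivatives.records, features, n_cn, n_alk


# reference free energies used when back-solving thermochemistry (J/mol);
# arbitrary but fixed gas-phase anchors for Li and per-molecule baselines
_G_LITHIUM = -19_691_247.0
_G_OXIDIZED_BASE = -1.2e9


def _backsolve_records(
    canon: str, index: int, delta_e: float, n_electrons: int
) -> tuple[ThermoRecord, ThermoRecord]:
    """ThermoRecords for the oxidized/reduced pair reproducing delta_e exactly.

    Component values are typical gas-phase magnitudes; E0 absorbs whatever
    remains so that G works out to the target.
    """
    T = 298.0
    g_ox = _G_OXIDIZED_BASE - 1.0e6 * index
    g_red = g_ox + 2.0 * _G_LITHIUM - n_electrons * FARADAY * delta_e

    def make(species_id: str, g_target: float) -> ThermoRecord:
        zpe, ht, hr, hv = 3.0e5, 3716.0, 3716.0, 1.2e4
        s_tr, s_rot, s_vib, s_el = 170.0, 120.0, 80.0, 0.0
        s_total = s_tr + s_rot + s_vib + s_el
        e0 = g_target - (zpe + ht + hr + hv + GAS_CONSTANT * T) + T * s_total
        return ThermoRecord(
            species_id=species_id, E0=e0, ZPE=zpe, H_trans=ht, H_rot=hr,
            H_vib=hv, S_trans=s_tr, S_rot=s_rot, S_vib=s_vib, S_el=s_el, T=T,
        )

    return make(f"{canon}|oxidized", g_ox), make(f"{canon}|reduced", g_red)


def lithium_record() -> ThermoRecord:
    """The gas-phase lithium reference species (G = fixed anchor)."""
    T = 298.0
    s_total = 133.0
    e0 = _G_LITHIUM - GAS_CONSTANT * T + T * s_total
    return ThermoRecord(species_id="Li(g)", E0=e0, S_trans=s_total, T=T)


def generate_dataset(spec: SyntheticSpec = SyntheticSpec()) -> SyntheticDataset:
    """Full synthetic screening dataset, bit-reproducible from the seed."""
    records, features, n_cn, n_alk = _base_population(
        spec.n_scaffolds, spec.max_substitutions
    )
    rng = np.random.default_rng(spec.seed)
    lumo = features["LUMO"].to_numpy()
    clean = (
        spec.intercept_v
        + spec.cn_effect_v * n_cn
        + spec.alkynyl_effect_v * n_alk
        + spec.lumo_coeff_v_per_ev * lumo
    )
    noisy = clean + rng.normal(0.0, spec.noise_sd_v, size=len(clean))
    lo, hi = spec.clip_range_v
    labels = np.clip(noisy, lo, hi)
    n_clipped = int(np.sum((noisy < lo) | (noisy > hi)))

    li = lithium_record()
    _, _, g_li = gibbs_free_energy(li)
    label_records: list[RedoxLabel] = []
    thermo: list[ThermoRecord] = [li]
    for i, (canon, de) in enumerate(zip(features.index, labels)):
        ox, red = _backsolve_records(canon, i, float(de), spec.n_electrons)
        thermo.extend([ox, red])
        _, _, g_ox = gibbs_free_energy(ox)
        _, _, g_red = gibbs_free_energy(red)
        dg = g_red - g_ox - 2.0 * g_li
        label_records.append(
            RedoxLabel(
                canonical=canon,
                delta_e_volts=float(de),
                delta_g_j_per_mol=dg,
                n_electrons=spec.n_electrons,
            )
        )
    return SyntheticDataset(
        features=features,
        labels=pd.Series(labels, index=features.index, name="delta_E_V"),
        label_records=label_records,
        thermo_records=thermo,
        truth={
            "intercept_v": spec.intercept_v,
            "cn_effect_v": spec.cn_effect_v,
            "alkynyl_effect_v": spec.alkynyl_effect_v,
            "lumo_coeff_v_per_ev": spec.lumo_coeff_v_per_ev,
            "noise_sd_v": spec.noise_sd_v,
            "n_cn": n_cn.tolist(),
            "n_alkynyl": n_alk.tolist(),
        },
        derivative_records=list(records),
        n_clipped=n_clipped,
    )


def planted_selection_dataset(
    seed: int = 0,
    n_informative: int = 5,
    n_noise: int = 10,
    n_duplicates: int = 5,
    n_rows: int = 300,
    effect_size: float = 1.0,
    noise_sd: float = 1.0,
    duplicate_jitter_sd: float = 0.0,
) -> tuple[pd.DataFrame, np.ndarray, dict[str, list[str]]]:
    """Feature table with a planted ground truth for selection testing.

    Informative columns enter the label linearly with equal weight; noise
    columns are independent of the label (the first is constant whenever
    ``n_noise >= 1``); duplicate columns copy informative ones, exactly by
    default or with Gaussian jitter (still correlated r > 0.95 for small
    jitter).  Returns (table, labels, role mask).
    """
    if n_rows <= n_informative + 2:
        raise ValueError("need n_rows > n_informative + 2")
    rng = np.random.default_rng(seed)
    cols: dict[str, np.ndarray] = {}
    mask: dict[str, list[str]] = {"informative": [], "noise": [], "duplicate": []}

    informative = rng.normal(size=(n_rows, n_informative))
    for j in range(n_informative):
        name = f"inf_{j}"
        cols[name] = informative[:, j]
        mask["informative"].append(name)
    y = effect_size * informative.sum(axis=1) + rng.normal(0.0, noise_sd, size=n_rows)

    for j in range(n_duplicates):
        src = j % n_informative
        name = f"dup_{j}"
        col = informative[:, src].copy()
        if duplicate_jitter_sd > 0:
            col = col + rng.normal(0.0, duplicate_jitter_sd, size=n_rows)
        cols[name] = col
        mask["duplicate"].append(name)

    for j in range(n_noise):
        name = f"noise_{j}"
        cols[name] = (
            np.zeros(n_rows) if j == 0 else rng.normal(size=n_rows)
        )
        mask["noise"].append(name)

    return pd.DataFrame(cols), y, mask
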