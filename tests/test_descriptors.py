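"""Descriptor panel: hand-derived values, oracles and invariances."""

import numpy as np
import pytest
from rdkit import Chem

from quinoscreen.chem_core import parse_smiles
from quinoscreen.derivative_gen import enumerate_derivatives
from quinoscreen.descriptors import (
    DESCRIPTOR_NAMES,
    FLAGGABLE,
    burden_matrix,
    compute_descriptor_table,
    compute_descriptors,
    eccentric_connectivity,
    mean_topological_charge_index,
    vabc_volume,
)
from quinoscreen.estate import intrinsic_states, max_intrinsic_differences
from quinoscreen.huckel import ALPHA_EV, BETA_EV, NoPiSystemError, pseudo_lumo
from tests.conftest import FIXTURE_SMILES, permuted_copy


class TestIntrinsicStates:
    def test_ethane_carbons(self):
        # I = ((2/2)^2 * 1 + 1) / 1 = 2 for each CH3 carbon
        states = intrinsic_states(parse_smiles("CC"))
        assert states.intrinsic == pytest.approx([2.0, 2.0])

    def test_fluoromethane_fluorine(self):
        # F: delta_v = 7, delta = 1 -> I = 8
        states = intrinsic_states(parse_smiles("CF"))
        by_element = dict(zip(("C", "F"), states.intrinsic))
        assert by_element["F"] == pytest.approx(8.0)

    def test_equivalent_atoms_zero_differences(self):
        mol = parse_smiles("CC").to_rdkit()
        states = intrinsic_states(mol)
        maxdn, maxdp = max_intrinsic_differences(mol, states.intrinsic)
        assert maxdn == 0.0 and maxdp == 0.0

    @pytest.mark.parametrize("name", sorted(FIXTURE_SMILES))
    def test_perturbations_sum_to_zero(self, fixture_mols, name):
        """The E-state field terms are pairwise antisymmetric, so
        sum_i (S_i - I_i) = 0 exactly."""
        mol = fixture_mols[name]
        if mol.n_atoms < 2:
            pytest.skip("undefined for single heavy atom")
        states = intrinsic_states(mol)
        assert abs(float(np.sum(states.estate - states.intrinsic))) < 1e-10


class TestAtomTypePanel:
    def test_acetonitrile_nitrile_nitrogen(self):
        vec = compute_descriptors(parse_smiles("CC#N"))
        assert vec.values["ntN"] == 1

    def test_benzoquinone_carbonyl_carbons(self, benzoquinone):
        vec = compute_descriptors(benzoquinone)
        assert vec.values["ndssC"] == 2

    def test_benzene_aromatic_types(self):
        vec = compute_descriptors(parse_smiles("c1ccccc1"))
        # aaC- requires a non-H substituent; all six carbons are aaCH
        assert vec.values["naasC"] == 0
        assert vec.values["nHother"] == 6

    def test_toluene_substituted_aromatic_carbon(self):
        vec = compute_descriptors(parse_smiles("Cc1ccccc1"))
        assert vec.values["naasC"] == 1
        assert vec.values["nHother"] == 5

    def test_counts_match_brute_force_typing(self, fixture_mols):
        """Count descriptors equal direct atom-by-atom pattern matching."""
        from quinoscreen.estate import atom_type

        for mol in fixture_mols.values():
            if mol.n_atoms < 2:
                continue
            rd = mol.to_rdkit()
            types = [atom_type(a) for a in rd.GetAtoms()]
            vec = compute_descriptors(mol)
            assert vec.values["ndssC"] == types.count("dssC")
            assert vec.values["naasC"] == types.count("aasC")
            assert vec.values["ntN"] == types.count("tN")


class TestTopological:
    def test_ethane_path(self):
        rd = parse_smiles("CC").to_rdkit()
        dist = np.asarray(Chem.GetDistanceMatrix(rd))
        eccen, diameter = eccentric_connectivity(rd, dist)
        assert (eccen, diameter) == (2.0, 1.0)

    def test_propane_path(self):
        rd = parse_smiles("CCC").to_rdkit()
        dist = np.asarray(Chem.GetDistanceMatrix(rd))
        eccen, _ = eccentric_connectivity(rd, dist)
        assert eccen == 6.0  # 2*1 + 1*2 + 2*1

    @pytest.mark.parametrize("name", sorted(FIXTURE_SMILES))
    def test_eccen_against_shortest_path_oracle(self, fixture_mols, name):
        import networkx as nx

        mol = fixture_mols[name]
        rd = mol.to_rdkit()
        g = nx.Graph([(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in rd.GetBonds()])
        g.add_nodes_from(range(rd.GetNumAtoms()))
        if rd.GetNumAtoms() > 1:
            sp = dict(nx.all_pairs_shortest_path_length(g))
            ecc = [max(sp[i].values()) for i in range(rd.GetNumAtoms())]
            expected_eccen = sum(
                e * rd.GetAtomWithIdx(i).GetDegree() for i, e in enumerate(ecc)
            )
            vec = compute_descriptors(mol)
            assert vec.values["ECCEN"] == expected_eccen
            assert vec.values["topoDiameter"] == max(ecc)

    def test_benzoquinone_rings_and_double_bonds(self, benzoquinone):
        vec = compute_descriptors(benzoquinone)
        assert vec.values["nRing"] == 1
        assert vec.values["nBondsD2"] == 4  # 2 C=O + 2 ring C=C, none aromatic

    def test_jgi2_two_atom_molecule_is_zero(self):
        rd = parse_smiles("CC").to_rdkit()
        dist = np.asarray(Chem.GetDistanceMatrix(rd))
        assert mean_topological_charge_index(rd, dist, order=2) == 0.0


class TestBcut:
    def test_ordering_invariant(self, fixture_mols):
        for mol in fixture_mols.values():
            vec = compute_descriptors(mol)
            if not vec.missing["BCUTc-1l"]:
                assert vec.values["BCUTc-1l"] <= vec.values["BCUTc-1h"]

    def test_symmetric_two_by_two_eigenvalues(self):
        """With equal diagonal q and off-diagonal w the spectrum is q +/- w."""
        rd = parse_smiles("CC").to_rdkit()
        B = burden_matrix(rd, np.zeros(2))
        w = 0.1 + 0.01  # single bond, both atoms terminal
        assert np.linalg.eigvalsh(B) == pytest.approx([-w, w])


class TestVabc:
    def test_methane(self):
        assert vabc_volume(parse_smiles("C")) == pytest.approx(25.86, abs=1e-3)

    def test_benzene_single_aromatic_ring_correction(self):
        # 6C + 6H atoms, 12 bonds, one aromatic ring
        expected = 6 * 20.58 + 6 * 7.24 - 5.92 * 12 - 14.7
        assert vabc_volume(parse_smiles("c1ccccc1")) == pytest.approx(expected, abs=1e-9)

    def test_cyano_substitution_increases_volume(self, benzoquinone):
        base = vabc_volume(benzoquinone)
        for rec in enumerate_derivatives([benzoquinone], max_substitutions=1).records:
            assert vabc_volume(rec.molecule) > base

    def test_element_outside_table_flagged(self):
        vec = compute_descriptors(parse_smiles("C[GeH3]"))
        assert vec.missing["VABC"]


class TestPseudoLumo:
    def test_ethylene_analytic(self):
        assert pseudo_lumo(parse_smiles("C=C")) == pytest.approx(ALPHA_EV - BETA_EV)

    def test_butadiene_analytic(self):
        golden = (np.sqrt(5) - 1) / 2  # 0.618...
        expected = ALPHA_EV - golden * BETA_EV
        assert pseudo_lumo(parse_smiles("C=CC=C")) == pytest.approx(expected, abs=1e-9)

    def test_no_pi_system_raises(self):
        with pytest.raises(NoPiSystemError):
            pseudo_lumo(parse_smiles("CCC"))

    def test_cyano_substitution_lowers_lumo(self, benzoquinone):
        base = pseudo_lumo(benzoquinone)
        cn = [
            r.molecule
            for r in enumerate_derivatives([benzoquinone], max_substitutions=1).records
            if r.substituent == "CN"
        ]
        assert pseudo_lumo(cn[0]) < base


class TestPanelAssembly:
    def test_empty_input_empty_table_with_header(self):
        table = compute_descriptor_table([])
        assert table.shape[0] == 0
        assert list(table.columns[: len(DESCRIPTOR_NAMES)]) == list(DESCRIPTOR_NAMES)

    def test_duplicate_molecules_identical_rows(self, benzoquinone):
        table = compute_descriptor_table([benzoquinone, benzoquinone])
        assert table.iloc[0].equals(table.iloc[1])

    def test_mw_increases_with_substitution(self, benzoquinone):
        derivs = enumerate_derivatives([benzoquinone], max_substitutions=1)
        table = compute_descriptor_table([benzoquinone] + derivs.molecules)
        base = table["MW"].iloc[0]
        assert (table["MW"].iloc[1:] > base).all()

    def test_single_heavy_atom_flagged_not_dropped(self):
        table = compute_descriptor_table([parse_smiles("C")])
        assert table.shape[0] == 1
        assert table["meanI_missing"].iloc[0] == 1
        assert np.isfinite(table[list(DESCRIPTOR_NAMES)].to_numpy()).all()

    @pytest.mark.parametrize("name", ["benzoquinone", "naphthoquinone", "toluene"])
    def test_panel_invariant_under_relabeling(self, fixture_mols, name):
        rng = np.random.default_rng(11)
        mol = fixture_mols[name]
        reference = compute_descriptors(mol).values
        for _ in range(25):
            permuted = compute_descriptors(permuted_copy(mol, rng)).values
            for key in DESCRIPTOR_NAMES:
                assert permuted[key] == pytest.approx(reference[key], abs=1e-9), key
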