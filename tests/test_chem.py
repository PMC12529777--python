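"""Standardization, fingerprints, scaffolds, descriptors, graphs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import splitshift as ss
from splitshift.chem import Rejection


class TestStandardize:
    def test_canonical_input_is_fixed_point(self):
        assert ss.standardize("CCO") == "CCO"

    def test_keeps_largest_organic_fragment(self):
        # oracle: enumerate fragments, keep the max-heavy-atom organic one
        raw = "CCO.[Na+].[Cl-]"
        frags = raw.split(".")
        from rdkit import Chem

        organic = max(
            (f for f in frags if "Na" not in f and "Cl" not in f),
            key=lambda f: Chem.MolFromSmiles(f).GetNumHeavyAtoms(),
        )
        assert ss.standardize(raw) == organic == "CCO"

    def test_unparseable_yields_rejection_not_drop(self):
        out = ss.standardize("not_a_smiles")
        assert isinstance(out, Rejection)
        assert out.raw_smiles == "not_a_smiles"

    def test_empty_string_is_an_input_error(self):
        with pytest.raises(ValueError):
            ss.standardize("")

    def test_idempotent_on_survivors(self, lib400):
        for rec in lib400[:40]:
            once = ss.standardize(rec.smiles)
            assert ss.standardize(once) == once

    def test_ph_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ss.StandardizationConfig(protonate_ph=15.0)


class TestDeduplicate:
    def _rec(self, i, smi, label):
        return ss.MoleculeRecord(id=f"r{i}", smiles=smi, label=label)

    def test_identical_smiles_same_label_collapse(self):
        recs = [self._rec(0, "CCO", 1), self._rec(1, "CCO", 1)]
        out = ss.deduplicate(recs)
        assert len(out) == 1 and out[0].id == "r0"

    def test_conflicting_labels_drop_both(self):
        recs = [
            self._rec(0, "CCO", 0),
            self._rec(1, "CCO", 1),
            self._rec(2, "CCN", 1),
        ]
        out = ss.deduplicate(recs)
        # brute-force count: only the non-conflicting molecule survives
        assert [r.smiles for r in out] == ["CCN"]

    def test_all_unique_is_identity(self):
        recs = [self._rec(i, smi, 1) for i, smi in enumerate(["C", "CC", "CCC"])]
        assert ss.deduplicate(recs) == recs

    def test_output_smiles_strictly_unique(self, lib400):
        doubled = list(lib400) + [
            ss.MoleculeRecord(id=f"dup_{r.id}", smiles=r.smiles, label=r.label)
            for r in lib400[:50]
        ]
        out = ss.deduplicate(doubled)
        smiles = [r.smiles for r in out]
        assert len(smiles) == len(set(smiles)) == len(lib400)


class TestDownsample:
    def _records(self, n_act, n_inact):
        return [
            ss.MoleculeRecord(id=f"a{i}", smiles="C", label=1) for i in range(n_act)
        ] + [
            ss.MoleculeRecord(id=f"i{i}", smiles="O", label=0)
            for i in range(n_inact)
        ]

    def test_closed_form_count(self):
        out = ss.downsample_majority(self._records(100, 300), 0.50, seed=0)
        labels = [r.label for r in out]
        assert labels.count(1) == 100 and labels.count(0) == 100

    def test_already_balanced_noop(self):
        recs = self._records(100, 100)
        assert ss.downsample_majority(recs, 0.50, seed=0) == recs

    def test_seed_reproducible(self):
        recs = self._records(50, 200)
        a = ss.downsample_majority(recs, 0.5, seed=3)
        b = ss.downsample_majority(recs, 0.5, seed=3)
        assert a == b

    def test_unreachable_target_warns_and_noops(self):
        # lowering the active fraction would require removing the minority
        # class (actives), which majority downsampling cannot do
        recs = self._records(40, 60)
        with pytest.warns(UserWarning):
            out = ss.downsample_majority(recs, 0.3, seed=0)
        assert len(out) == 100

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            ss.downsample_majority(self._records(5, 5), 1.5, seed=0)


class TestFingerprints:
    def test_deterministic(self):
        a = ss.ecfp("c1ccccc1O")
        b = ss.ecfp("c1ccccc1O")
        assert np.array_equal(a.bits, b.bits)

    def test_distinct_structures_differ(self):
        assert not np.array_equal(ss.ecfp("C").bits, ss.ecfp("CCCCCCCC").bits)

    def test_length_contract(self):
        assert ss.ecfp("CCO", n_bits=1024).bits.shape == (1024,)
        assert ss.ecfp("CCO", n_bits=2048).bits.shape == (2048,)

    def test_invalid_molecule_errors(self):
        with pytest.raises(ValueError):
            ss.ecfp("not_a_smiles")


class TestTanimoto:
    def _fp(self, on_bits, n=16):
        bits = np.zeros(n, dtype=np.uint8)
        bits[list(on_bits)] = 1
        return ss.Fingerprint(bits=bits, n_bits=n, radius=2)

    def test_identity_disjoint_and_formula(self):
        a, b = self._fp({0, 1, 2}), self._fp({1, 2, 3})
        assert ss.tanimoto(a, a) == 1.0
        assert ss.tanimoto(self._fp({0, 1}), self._fp({2, 3})) == 0.0
        assert ss.tanimoto(a, b) == 0.5  # 2 / 4

    def test_both_empty_convention(self):
        assert ss.tanimoto(self._fp(set()), self._fp(set())) == 1.0

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            ss.tanimoto(self._fp({0}, n=16), self._fp({0}, n=32))

    @settings(max_examples=50, deadline=None)
    @given(
        a=st.lists(st.integers(0, 15), max_size=16),
        b=st.lists(st.integers(0, 15), max_size=16),
    )
    def test_symmetric_and_bounded(self, a, b):
        fa, fb = self._fp(set(a)), self._fp(set(b))
        s = ss.tanimoto(fa, fb)
        assert 0.0 <= s <= 1.0
        assert s == ss.tanimoto(fb, fa)

    def test_matrix_agrees_with_scalar(self, lib400):
        fps = ss.ecfp_matrix(lib400[:15])
        S = ss.tanimoto_matrix(fps, fps)
        for i in (0, 4, 9):
            for j in (2, 7, 14):
                a = ss.ecfp(lib400[i])
                b = ss.ecfp(lib400[j])
                assert S[i, j] == pytest.approx(ss.tanimoto(a, b), abs=1e-6)


class TestScaffolds:
    def test_side_chain_pruning(self):
        assert ss.murcko_scaffold("CCc1ccccc1") == "c1ccccc1"

    def test_acyclic_gives_empty(self):
        assert ss.murcko_scaffold("CCO") == ""
        assert ss.generic_scaffold("CCO") == ""

    def test_ring_fixed_point(self):
        assert ss.murcko_scaffold("c1ccccc1") == "c1ccccc1"
        assert ss.generic_scaffold("C1CCCCC1") == "C1CCCCC1"

    def test_side_chain_invariance(self):
        assert ss.murcko_scaffold("CCc1ccccc1") == ss.murcko_scaffold("CCCc1ccccc1")

    def test_generic_maps_atoms_and_bonds(self):
        assert ss.generic_scaffold("c1ccncc1") == "C1CCCCC1"

    def test_generic_contains_only_carbon_single_bonds(self, lib400):
        from rdkit import Chem

        for rec in lib400[:40]:
            smi = ss.generic_scaffold(rec)
            if not smi:
                continue
            mol = Chem.MolFromSmiles(smi)
            assert all(a.GetSymbol() == "C" for a in mol.GetAtoms())
            assert all(
                b.GetBondType() == Chem.BondType.SINGLE for b in mol.GetBonds()
            )


class TestDescriptors:
    def test_water_monoisotopic_mass(self):
        # sum of monoisotopic masses: 2 x 1.00783 + 15.99491
        assert ss.mol_weight("O") == pytest.approx(18.011, abs=1e-3)

    def test_weight_monotone_in_atoms(self):
        assert ss.mol_weight("CCCC") > ss.mol_weight("CC")

    def test_alkane_more_lipophilic_than_diol(self):
        assert ss.clogp("CCCCCCCC") > ss.clogp("OCCO")


class TestToGraph:
    def test_benzene_ring(self):
        g = ss.to_graph("c1ccccc1")
        assert g.n_nodes == 6 and g.n_edges == 6

    def test_single_heavy_atom(self):
        g = ss.to_graph("C")
        assert g.n_nodes == 1 and g.n_edges == 0

    def test_deterministic(self):
        a, b = ss.to_graph("CC(=O)Nc1ccccc1"), ss.to_graph("CC(=O)Nc1ccccc1")
        assert np.array_equal(a.node_features, b.node_features)
        assert np.array_equal(a.edge_list, b.edge_list)
        assert np.array_equal(a.edge_features, b.edge_features)

    def test_unknown_scheme_errors(self):
        with pytest.raises(ValueError):
            ss.to_graph("CCO", feature_scheme="nope")

    def test_uniform_feature_dims(self, lib400):
        dims = {ss.to_graph(r).node_features.shape[1] for r in lib400[:20]}
        assert dims == {13}
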