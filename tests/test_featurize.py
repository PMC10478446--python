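"""Featurization: atom/bond features, pKa channels, fingerprints, splits."""

import numpy as np
import pytest
from rdkit import Chem
from rdkit.DataStructs import ExplicitBitVect

from rtlogd.featurize import (
    ACID_SENTINEL,
    ATOM_FDIM,
    BASE_SENTINEL,
    PkaAnnotation,
    assign_pka_sites,
    base_atom_features,
    dissimilarity_prioritized_sample,
    ecfp4,
    max_similarity_to_set,
    mol_to_graph,
    murcko_scaffold,
    normalize_pka,
    rule_based_pka,
    scaffold_split,
    tanimoto,
)

# (start, width) of the one-hot blocks inside the 74-dim base layout
ONE_HOT_BLOCKS = [(0, 43), (43, 11), (54, 7), (63, 5), (69, 5)]


class TestAtomFeatures:
    def test_width_and_aromatic_flag(self):
        mol = Chem.MolFromSmiles("c1ccccc1")
        v = base_atom_features(mol.GetAtomWithIdx(0))
        assert v.shape == (74,)
        assert v[68] == 1.0  # aromatic flag

    def test_methane_carbon_blocks(self):
        mol = Chem.MolFromSmiles("C")
        v = base_atom_features(mol.GetAtomWithIdx(0))
        assert v[43] == 1.0      # degree 0 heavy neighbors
        assert v[69 + 4] == 1.0  # four attached hydrogens

    def test_exactly_one_hot_per_block(self, small_library):
        for smi in small_library:
            mol = Chem.MolFromSmiles(smi)
            for atom in mol.GetAtoms():
                v = base_atom_features(atom)
                for start, width in ONE_HOT_BLOCKS:
                    assert v[start : start + width].sum() == 1.0, (smi, atom.GetIdx())

    def test_unknown_element_hits_other_slot(self):
        mol = Chem.MolFromSmiles("[U]")
        v = base_atom_features(mol.GetAtomWithIdx(0))
        assert v[42] == 1.0


class TestPkaSites:
    def test_ethanol_oxygen_acidic_only(self):
        sites = assign_pka_sites(Chem.MolFromSmiles("CCO"))
        assert sites[2] == (True, False)

    def test_pyridine_nitrogen_basic_only(self):
        mol = Chem.MolFromSmiles("c1ccncc1")
        n_idx = next(a.GetIdx() for a in mol.GetAtoms() if a.GetSymbol() == "N")
        assert sites_at(mol, n_idx) == (False, True)

    def test_carbons_never_eligible(self, small_library):
        for smi in small_library:
            mol = Chem.MolFromSmiles(smi)
            sites = assign_pka_sites(mol)
            for atom in mol.GetAtoms():
                if atom.GetSymbol() == "C":
                    assert sites[atom.GetIdx()] == (False, False)

    def test_protonated_nitrogen_not_basic(self):
        mol = Chem.MolFromSmiles("C[NH3+]")
        n_idx = next(a.GetIdx() for a in mol.GetAtoms() if a.GetSymbol() == "N")
        acidic, basic = sites_at(mol, n_idx)
        assert not basic  # positive formal charge excludes the basic rule


def sites_at(mol, idx):
    return assign_pka_sites(mol)[idx]


class TestNormalizePka:
    @pytest.mark.parametrize("value,expected", [(-10.0, 0.0), (20.0, 1.0), (5.0, 0.5)])
    def test_affine_map(self, value, expected):
        assert normalize_pka(value) == pytest.approx(expected)

    def test_clipping(self):
        assert normalize_pka(-50.0) == 0.0
        assert normalize_pka(99.0) == 1.0

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            normalize_pka(float("nan"))


class TestMolToGraph:
    def test_width_is_76_and_pka_in_unit_interval(self, small_library):
        for smi in small_library:
            g = mol_to_graph(smi)
            assert g.atom_features.shape == (g.n_atoms, ATOM_FDIM)
            assert (g.atom_features[:, 74:] >= 0).all()
            assert (g.atom_features[:, 74:] <= 1).all()

    def test_no_ionizable_sites_all_sentinel(self):
        g = mol_to_graph("CCCC")
        assert (g.atom_features[:, 74] == ACID_SENTINEL).all()
        assert (g.atom_features[:, 75] == BASE_SENTINEL).all()

    def test_node_count_matches_heavy_atoms(self, small_library):
        for smi in small_library:
            assert mol_to_graph(smi).n_atoms == Chem.MolFromSmiles(smi).GetNumHeavyAtoms()

    def test_carboxylic_acid_channel_set(self):
        g = mol_to_graph("CC(=O)O")
        mol = Chem.MolFromSmiles("CC(=O)O")
        oh = next(a.GetIdx() for a in mol.GetAtoms()
                  if a.GetSymbol() == "O" and a.GetTotalNumHs() == 1)
        assert g.atom_features[oh, 74] < ACID_SENTINEL  # a real acidic pKa, not sentinel

    def test_annotation_override_and_range_check(self):
        ann = PkaAnnotation(acidic={99: 4.0})
        with pytest.raises(ValueError, match="out of range"):
            mol_to_graph("CCO", pka=ann)

    def test_featurization_deterministic(self):
        a = mol_to_graph("c1ccc(C(=O)O)cc1")
        b = mol_to_graph("c1ccc(C(=O)O)cc1")
        assert (a.atom_features == b.atom_features).all()
        assert (a.bond_features == b.bond_features).all()


class TestFingerprints:
    def test_tanimoto_identity_and_symmetry(self, small_library):
        fps = [ecfp4(s) for s in small_library[:10]]
        for fp in fps:
            assert tanimoto(fp, fp) == 1.0
        for a, b in zip(fps, fps[1:]):
            assert tanimoto(a, b) == tanimoto(b, a)
            assert 0.0 <= tanimoto(a, b) <= 1.0

    def test_bit_arithmetic(self):
        a, b = ExplicitBitVect(4), ExplicitBitVect(4)
        for i in (0, 1):
            a.SetBit(i)
        for i in (0, 2):
            b.SetBit(i)
        assert tanimoto(a, b) == pytest.approx(1 / 3)
        empty = ExplicitBitVect(4)
        assert tanimoto(empty, empty) == 0.0

    def test_fingerprint_length(self):
        assert ecfp4("CCO").GetNumBits() == 2048

    def test_max_similarity_empty_ref_raises(self):
        with pytest.raises(ValueError):
            max_similarity_to_set(ecfp4("CCO"), [])


class TestScaffoldSplit:
    def test_distinct_scaffolds_8_1_1(self):
        # ten single-ring systems with ten distinct frameworks
        smis = ["c1ccccc1", "c1ccncc1", "C1CCCCC1", "C1CCNCC1", "c1ccc2ccccc2c1",
                "c1cncnc1", "C1CCOC1", "c1cc[nH]c1", "c1ccsc1", "c1ccoc1"]
        sp = scaffold_split(smis, (8, 1, 1), seed=0)
        assert (len(sp.train), len(sp.valid), len(sp.test)) == (8, 1, 1)

    def test_single_scaffold_degenerate(self):
        smis = ["c1ccccc1", "c1ccc(Cl)cc1", "c1ccc(F)cc1"]
        sp = scaffold_split(smis, (8, 1, 1), seed=0)
        assert len(sp.train) == 3 and not sp.valid and not sp.test

    def test_partitions_exhaustive_disjoint_coherent(self, small_library):
        sp = scaffold_split(small_library, (8, 1, 1), seed=3)
        parts = sp.partitions()
        all_idx = sorted(i for idx in parts.values() for i in idx)
        assert all_idx == list(range(len(small_library)))
        scaffs = [{sp.scaffold_of[i] for i in idx} for idx in parts.values()]
        assert not (scaffs[0] & scaffs[1] or scaffs[0] & scaffs[2] or scaffs[1] & scaffs[2])

    def test_deterministic_under_seed(self, small_library):
        a = scaffold_split(small_library, (8, 1, 1), seed=9)
        b = scaffold_split(small_library, (8, 1, 1), seed=9)
        assert a.train == b.train and a.valid == b.valid and a.test == b.test

    def test_acyclic_molecules_share_bucket(self):
        smis = ["CCO", "CCCC", "c1ccccc1"]
        sp = scaffold_split(smis, (8, 1, 1), seed=0)
        assert murcko_scaffold("CCO") == murcko_scaffold("CCCC") == ""
        parts = {name for name, idx in sp.partitions().items() if 0 in idx or 1 in idx}
        assert len(parts) == 1


class TestDissimilaritySampling:
    def test_whole_pool(self, small_library):
        pool, ref = small_library[:20], small_library[20:30]
        assert set(dissimilarity_prioritized_sample(pool, ref, 20)) == set(pool)

    def test_nested_prefixes(self, small_library):
        pool, ref = small_library[:30], small_library[30:40]
        s10 = dissimilarity_prioritized_sample(pool, ref, 10)
        s20 = dissimilarity_prioritized_sample(pool, ref, 20)
        assert s20[:10] == s10

    def test_ref_duplicate_selected_last(self, small_library):
        ref = small_library[40:45]
        pool = small_library[:10] + [ref[0]]
        out = dissimilarity_prioritized_sample(pool, ref, len(pool))
        assert out[-1] == ref[0]

    def test_oversampling_raises(self):
        with pytest.raises(ValueError):
            dissimilarity_prioritized_sample(["CCO"], ["CCN"], 2)
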