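import numpy as np
import pytest

import carcstack as cs
from carcstack.descriptors import (
    DescriptorError, load_smiles_table, morgan_substructure_ids, write_drop_report,
)
from rdkit import Chem


class TestDescriptorMatrix:
    def test_rejects_duplicate_ids(self):
        with pytest.raises(DescriptorError, match="duplicate"):
            cs.DescriptorMatrix(["a", "a"], [[1.0], [2.0]], ["f"], cs.CONTINUOUS)

    def test_rejects_nonbinary_fingerprint(self):
        with pytest.raises(DescriptorError, match="outside"):
            cs.DescriptorMatrix(["a"], [[0.5]], ["f"], cs.BINARY)

    def test_subset_rows_preserves_order(self):
        m = cs.DescriptorMatrix(["a", "b", "c"], np.arange(6.0).reshape(3, 2),
                                ["f1", "f2"], cs.CONTINUOUS)
        sub = m.subset_rows(["c", "a"])
        assert sub.compound_ids == ["c", "a"]
        np.testing.assert_array_equal(sub.values, [[4, 5], [0, 1]])


class TestMaccs:
    def test_identical_smiles_identical_rows(self):
        m = cs.compute_maccs(["CCO", "CCO"])
        np.testing.assert_array_equal(m.values[0], m.values[1])

    def test_methane_vs_benzene(self):
        m = cs.compute_maccs(["C", "c1ccccc1"])
        assert not np.array_equal(m.values[0], m.values[1])
        assert m.values[1].sum() > m.values[0].sum()

    def test_166_keys_binary(self):
        m = cs.compute_maccs(["CC(=O)O"])
        assert m.n_features == 166
        assert m.kind == cs.BINARY
        assert m.metadata["n_keys"] == 166

    def test_kekulization_invariance(self):
        # same molecule, aromatic vs kekulized spelling
        m = cs.compute_maccs(["c1ccccc1", "C1=CC=CC=C1"])
        np.testing.assert_array_equal(m.values[0], m.values[1])

    def test_bad_smiles_names_record(self):
        with pytest.raises(DescriptorError, match="record 1"):
            cs.compute_maccs(["C", "not_a_smiles"])


class TestMol2vecEmbedding:
    def test_zero_table_gives_zero_rows(self):
        ids = morgan_substructure_ids(Chem.MolFromSmiles("CCO"))
        table = cs.EmbeddingTable({i: np.zeros(4) for i in ids})
        m = cs.embed_mol2vec(["CCO"], table)
        np.testing.assert_array_equal(m.values, np.zeros((1, 4)))

    def test_unknown_ids_use_unk_vector(self):
        table = cs.EmbeddingTable({"UNK": np.array([1.0, 0.0])})
        m = cs.embed_mol2vec(["C"], table)
        # methane contributes one radius-0 identifier, all unknown -> n * UNK
        n_ids = len(morgan_substructure_ids(Chem.MolFromSmiles("C")))
        np.testing.assert_allclose(m.values[0], [n_ids, 0.0])

    @pytest.mark.parametrize("smiles", ["CCO", "c1ccccc1O", "CC(=O)Nc1ccc(O)cc1"])
    def test_row_equals_naive_summation(self, smiles):
        ids = morgan_substructure_ids(Chem.MolFromSmiles(smiles))
        rng = np.random.default_rng(1)
        table = cs.EmbeddingTable({i: rng.normal(size=5) for i in set(ids)})
        m = cs.embed_mol2vec([smiles], table)
        expected = np.zeros(5)
        for i in ids:  # brute-force loop oracle
            expected += table.vectors[i]
        np.testing.assert_allclose(m.values[0], expected)


class TestLoadDescriptorTable:
    def test_well_formed_csv(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("compound_id,f1,f2,f3\na1,1,2,3\nb2,4,5,6\n")
        m = cs.load_descriptor_table(p)
        assert m.values.shape == (2, 3)
        assert m.kind == cs.CONTINUOUS

    def test_binary_kind_inferred(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("compound_id,f1,f2\na,0,1\nb,1,0\n")
        assert cs.load_descriptor_table(p).kind == cs.BINARY

    def test_duplicate_id_errors(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("compound_id,f1\na,1\na,2\n")
        with pytest.raises(DescriptorError, match="duplicate"):
            cs.load_descriptor_table(p)

    def test_blank_cell_names_location(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("compound_id,f1,f2\na,1,2\nb,,3\n")
        with pytest.raises(DescriptorError, match="'b'.*'f1'"):
            cs.load_descriptor_table(p)


class TestPreprocessing:
    def _m(self, arr, names=None):
        arr = np.asarray(arr, dtype=float)
        names = names or [f"f{i}" for i in range(arr.shape[1])]
        ids = [f"c{i}" for i in range(arr.shape[0])]
        return cs.DescriptorMatrix(ids, arr, names, cs.CONTINUOUS)

    def test_constant_column_dropped(self):
        m = self._m([[1, 5, 2], [2, 5, 1], [3, 5, 7]])
        out = cs.remove_zero_variance(m)
        assert out.feature_names == ["f0", "f2"]
        assert out.metadata["dropped_zero_variance"] == ["f1"]

    def test_no_constant_columns_identity(self):
        m = self._m([[1, 2], [2, 1], [3, 5]])
        np.testing.assert_array_equal(cs.remove_zero_variance(m).values, m.values)

    def test_all_constant_errors(self):
        with pytest.raises(DescriptorError, match="zero variance"):
            cs.remove_zero_variance(self._m([[1, 2], [1, 2]]))

    def test_duplicated_column_kept_once(self):
        m = self._m([[1, 1, 3], [2, 2, 1], [3, 3, 4], [4, 4, 0]])
        out = cs.correlation_filter(m)
        assert out.feature_names == ["f0", "f2"]
        assert out.metadata["dropped_correlated"] == {"f1": "f0"}

    def test_perfectly_correlated_pair_keeps_first(self):
        f1 = np.array([1.0, 2, 3, 4])
        m = self._m(np.column_stack([f1, 2 * f1, [9, 1, 4, 7]]))
        out = cs.correlation_filter(m)
        assert out.feature_names == ["f0", "f2"]

    def test_independent_columns_untouched(self):
        rng = np.random.default_rng(0)
        m = self._m(rng.normal(size=(200, 6)))
        out = cs.correlation_filter(m)
        assert out.feature_names == m.feature_names
        corr = np.corrcoef(out.values, rowvar=False)
        assert (np.abs(corr - np.eye(6)) <= 0.9).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_filter_matches_greedy_oracle(self, seed):
        """No surviving pair exceeds the threshold, and the survivor set equals
        a brute-force left-to-right scan recomputing correlations pairwise."""
        rng = np.random.default_rng(seed)
        base = rng.normal(size=(60, 8))
        extra = base[:, :4] + rng.normal(scale=0.05, size=(60, 4))  # near-duplicates
        m = self._m(np.column_stack([base, extra])[:, rng.permutation(12)][:, :12])
        out = cs.correlation_filter(m)
        kept = []
        for j, name in enumerate(m.feature_names):  # oracle: independent scan
            if all(abs(np.corrcoef(m.values[:, j], m.values[:, k])[0, 1]) <= 0.9
                   for k in kept):
                kept.append(j)
        assert out.feature_names == [m.feature_names[k] for k in kept]
        surv = np.corrcoef(out.values, rowvar=False)
        assert (np.abs(surv[~np.eye(len(kept), dtype=bool)]) <= 0.9).all()

    def test_preprocess_idempotent(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(50, 5))
        mat = np.column_stack([base, base[:, 0] * 3, np.full(50, 7.0)])
        m = self._m(mat)
        once = cs.preprocess(m)
        twice = cs.preprocess(once)
        assert once.feature_names == twice.feature_names
        np.testing.assert_array_equal(once.values, twice.values)

    def test_drop_report_sidecar(self, tmp_path):
        m = self._m([[1, 1, 5], [2, 2, 5], [3, 3, 5], [4, 4, 5]])
        pre = cs.preprocess(m)
        out = tmp_path / "report.json"
        write_drop_report(pre, out)
        import json
        report = json.loads(out.read_text())
        assert report["zero_variance"] == ["f2"]
        assert report["correlated_with"] == {"f1": "f0"}
        assert report["retained"] == ["f0"]


def test_smiles_table_roundtrip(tmp_path):
    p = tmp_path / "cmp.csv"
    p.write_text("compound_id,smiles,label\nx1,CCO,0\nx2,c1ccccc1,1\n")
    df = load_smiles_table(p)
    assert list(df["compound_id"]) == ["x1", "x2"]


def test_sdf_roundtrip(tmp_path):
    from rdkit.Chem import SDWriter
    p = tmp_path / "lib.sdf"
    w = SDWriter(str(p))
    for cid, smi in (("s1", "CCO"), ("s2", "c1ccncc1")):
        mol = Chem.MolFromSmiles(smi)
        mol.SetProp("compound_id", cid)
        mol.SetProp("label", "1")
        w.write(mol)
    w.close()
    df = cs.descriptors.load_sdf(p)
    assert list(df["compound_id"]) == ["s1", "s2"]
    assert Chem.MolFromSmiles(df["smiles"][1]) is not None
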