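import numpy as np
import pytest
from hypothesis import given, strategies as st

from drabal import datasets
from drabal.exceptions import (
    DataError,
    DataFormatError,
    EmptyDatasetError,
    ParameterError,
)


def _write(tmp_path, text, name="assay.tsv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadAssayTable:
    def test_outcome_mapping_and_dropping(self, tmp_path):
        p = _write(tmp_path, "compound_id\toutcome\nA\tActive\nB\tInactive\nC\tInconclusive\n")
        rs = datasets.read_assay_table(p, "AID1")
        assert rs.records == {"A": 1, "B": -1}

    def test_header_only_file(self, tmp_path):
        p = _write(tmp_path, "compound_id\toutcome\n")
        rs = datasets.read_assay_table(p, "AID1")
        assert len(rs) == 0

    def test_conflicting_duplicate_raises(self, tmp_path):
        p = _write(tmp_path, "compound_id\toutcome\nA\tActive\nA\tInactive\n")
        with pytest.raises(DataError, match="A"):
            datasets.read_assay_table(p, "AID1")

    def test_missing_column_raises(self, tmp_path):
        p = _write(tmp_path, "cid\toutcome\nA\tActive\n")
        with pytest.raises(DataFormatError):
            datasets.read_assay_table(p, "AID1")

    def test_case_insensitive(self, tmp_path):
        p = _write(tmp_path, "compound_id\toutcome\nA\tACTIVE\nB\tinactive\n")
        rs = datasets.read_assay_table(p, "AID1")
        assert rs.records == {"A": 1, "B": -1}


class TestMergeAssays:
    def _features(self, cids, d=3):
        return {c: np.arange(d, dtype=float) + i for i, c in enumerate(cids)}

    def test_label_matrix_definition(self):
        a1 = datasets.AssayRecordSet("A1", {"c1": 1, "c2": -1})
        a2 = datasets.AssayRecordSet("A2", {"c2": 1})
        ds = datasets.merge_assays([a1, a2], self._features(["c1", "c2"]))
        assert ds.assay_ids == ["A1", "A2"]
        np.testing.assert_array_equal(ds.labels, [[1, 0], [-1, 1]])

    def test_identical_assays_no_missing(self):
        recs = {"c1": 1, "c2": -1}
        ds = datasets.merge_assays(
            [datasets.AssayRecordSet("A1", recs), datasets.AssayRecordSet("A2", recs)],
            self._features(["c1", "c2"]),
        )
        assert (ds.labels != 0).all()

    def test_compound_without_features_dropped(self):
        a1 = datasets.AssayRecordSet("A1", {"c1": 1, "c2": -1})
        ds = datasets.merge_assays([a1], self._features(["c1"]))
        assert ds.compound_ids == ["c1"]
        assert ds.n_compounds == 1

    def test_no_surviving_compounds(self):
        a1 = datasets.AssayRecordSet("A1", {"c1": 1})
        with pytest.raises(EmptyDatasetError):
            datasets.merge_assays([a1], {})

    def test_interaction_accounting(self):
        # sum of per-assay class sizes plus zeros covers the full matrix
        a1 = datasets.AssayRecordSet("A1", {"c1": 1, "c2": -1, "c3": 1})
        a2 = datasets.AssayRecordSet("A2", {"c2": 1})
        ds = datasets.merge_assays([a1, a2], self._features(["c1", "c2", "c3"]))
        s = datasets.dataset_summary(ds)
        zeros = int((ds.labels == 0).sum())
        assert s.total_interactions + zeros == ds.n_compounds * ds.n_assays


class TestImbalanceRatio:
    def test_rare_actives_percent_matches_printed_convention(self):
        pct, _ = datasets.imbalance_ratio(77, 424852)
        assert pct == 0.01

    def test_fold_form(self):
        _, fold = datasets.imbalance_ratio(5854, 193105)
        assert fold == 33

    def test_symmetric(self):
        assert datasets.imbalance_ratio(10, 10) == (50.0, 1)

    def test_no_actives(self):
        pct, fold = datasets.imbalance_ratio(0, 10)
        assert pct == 0.0 and fold is None

    def test_both_zero_raises(self):
        with pytest.raises(ParameterError):
            datasets.imbalance_ratio(0, 0)

    @given(st.integers(0, 10**6), st.integers(0, 10**6))
    def test_percent_bounds(self, na, ni):
        if na + ni == 0:
            return
        pct, _ = datasets.imbalance_ratio(na, ni)
        assert 0.0 <= pct <= 100.0
        # truncation never exceeds the exact value
        assert pct <= 100.0 * na / (na + ni) + 1e-9


class TestDatasetSummary:
    def test_from_counts_total(self):
        s = datasets.DatasetSummary.from_counts(
            ["a", "b", "c", "d", "e"],
            [5854, 9143, 7586, 25159, 64212],
            [193105, 301951, 304846, 304600, 243136],
        )
        assert s.total_interactions == 1_459_592

    def test_all_missing_assay(self):
        ds = datasets.MultiLabelDataset(
            compound_ids=["c1", "c2"],
            features=np.zeros((2, 2)),
            labels=np.array([[1, 0], [-1, 0]]),
            assay_ids=["A", "B"],
        )
        s = datasets.dataset_summary(ds)
        row = s.per_assay.set_index("assay_id").loc["B"]
        assert row["n_active"] == 0 and row["n_inactive"] == 0

    def test_single_assay_all_active(self):
        ds = datasets.MultiLabelDataset(
            ["c1", "c2", "c3"], np.zeros((3, 1)), np.ones((3, 1)), ["A"]
        )
        assert datasets.dataset_summary(ds).total_interactions == 3

    def test_agrees_with_brute_recount(self, chain_dataset):
        ds, _ = chain_dataset
        s = datasets.dataset_summary(ds)
        for j, assay in enumerate(ds.assay_ids):
            col = ds.labels[:, j]
            row = s.per_assay.set_index("assay_id").loc[assay]
            assert row["n_active"] == sum(1 for v in col if v == 1)
            assert row["n_inactive"] == sum(1 for v in col if v == -1)
        assert s.total_interactions == int((ds.labels != 0).sum())


class TestCVFolds:
    def test_equal_sizes(self):
        split = datasets.make_cv_folds(10, 5, seed=0)
        assert sorted(len(f) for f in split.folds) == [2] * 5

    def test_deterministic(self):
        a = datasets.make_cv_folds(37, 5, seed=3)
        b = datasets.make_cv_folds(37, 5, seed=3)
        for fa, fb in zip(a.folds, b.folds):
            np.testing.assert_array_equal(fa, fb)

    def test_near_equal_sizes(self):
        split = datasets.make_cv_folds(11, 5, seed=1)
        assert sorted(len(f) for f in split.folds) == [2, 2, 2, 2, 3]

    @given(st.integers(4, 60), st.integers(2, 6), st.integers(0, 10))
    def test_partition_property(self, M, k, seed):
        if k > M:
            return
        split = datasets.make_cv_folds(M, k, seed)
        allidx = np.concatenate(split.folds)
        assert sorted(allidx.tolist()) == list(range(M))
        assert max(len(f) for f in split.folds) - min(len(f) for f in split.folds) <= 1

    def test_k_too_large(self):
        with pytest.raises(ParameterError):
            datasets.make_cv_folds(3, 5, seed=0)


class TestRoundTrip:
    def test_tsv_round_trip_exact(self, tmp_path, chain_dataset):
        ds, _ = chain_dataset
        ds.to_tsv(tmp_path / "labels.tsv", tmp_path / "features.tsv")
        back = datasets.MultiLabelDataset.from_tsv(
            tmp_path / "labels.tsv", tmp_path / "features.tsv"
        )
        assert back.compound_ids == ds.compound_ids
        assert back.assay_ids == ds.assay_ids
        np.testing.assert_array_equal(back.labels, ds.labels)
        np.testing.assert_allclose(back.features, ds.features)

    def test_invariant_rejects_all_missing_row(self):
        with pytest.raises(DataError):
            datasets.MultiLabelDataset(
                ["c1"], np.zeros((1, 2)), np.array([[0, 0]]), ["A", "B"]
            )
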