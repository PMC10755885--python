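"""Windowing arithmetic, stratified splitting, and group selection."""

import numpy as np
import pytest

from mfocnn.exceptions import DataError
from mfocnn.windowing import (
    EEGSegment,
    WindowedDataset,
    build_windowed_dataset,
    kfold_indices,
    split_dataset,
    subset_selector,
    window_segment,
)


class TestWindowSegment:
    def test_bonn_length_gives_23_chunks(self):
        chunks = window_segment(np.arange(4097.0), 178)
        assert chunks.shape == (23, 178)

    def test_identity_when_exact(self):
        x = np.arange(178.0)
        chunks = window_segment(x, 178)
        np.testing.assert_array_equal(chunks, x[None, :])

    def test_exhaustive_index_check(self):
        x = np.arange(356.0)
        chunks = window_segment(x, 178)
        assert chunks.shape == (2, 178)
        np.testing.assert_array_equal(chunks[1], np.arange(178.0, 356.0))

    def test_round_trip_prefix(self):
        x = np.arange(4097.0)
        chunks = window_segment(x, 178)
        np.testing.assert_array_equal(chunks.ravel(), x[: 23 * 178])

    def test_short_segment_yields_empty(self, caplog):
        out = window_segment(np.arange(10.0), 178)
        assert out.shape == (0, 178)

    def test_conservation_over_random_lengths(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 1000))
            clen = int(rng.integers(1, 200))
            chunks = window_segment(rng.normal(size=n), clen)
            assert chunks.shape[0] == n // clen


class TestBuildWindowedDataset:
    def test_full_corpus_dimensions(self, mini_corpus):
        # 5 subsets x 2 segments x floor(4097/178)=23 chunks
        ds = build_windowed_dataset(mini_corpus.subsets)
        assert ds.X.shape == (5 * 2 * 23, 178)
        counts = np.bincount(ds.y)
        assert (counts == 46).all()

    def test_single_subset(self, mini_corpus):
        ds = build_windowed_dataset({"A": mini_corpus.subsets["A"]})
        assert len(ds) == 46
        assert set(ds.y) == {0}

    def test_two_minimal_segments(self):
        segs = [np.arange(178.0), np.arange(178.0) + 1]
        ds = build_windowed_dataset([segs])
        assert len(ds) == 2

    def test_too_short_segment_names_offender(self):
        segs = [np.arange(178.0), np.arange(50.0)]
        with pytest.raises(DataError, match="segment 1"):
            build_windowed_dataset({"A": segs})

    def test_csv_round_trip(self, tmp_path, mini_dataset):
        path = tmp_path / "w.csv"
        mini_dataset.save_csv(path)
        back = WindowedDataset.load_csv(path)
        np.testing.assert_allclose(back.X, mini_dataset.X)
        np.testing.assert_array_equal(back.y, mini_dataset.y)


class TestSplitDataset:
    def test_80_20_per_class_counts(self, mini_dataset):
        train, test = split_dataset(mini_dataset, 0.8, seed=1)
        for cls in range(5):
            assert (train.y == cls).sum() == round(0.8 * 46)
            assert (test.y == cls).sum() == 46 - round(0.8 * 46)

    def test_full_fraction_empty_test(self, mini_dataset):
        train, test = split_dataset(mini_dataset, 1.0, seed=1)
        assert len(test) == 0 and len(train) == len(mini_dataset)

    def test_seeds_change_membership_not_counts(self, mini_dataset):
        t1, _ = split_dataset(mini_dataset, 0.8, seed=1)
        t2, _ = split_dataset(mini_dataset, 0.8, seed=2)
        assert np.bincount(t1.y).tolist() == np.bincount(t2.y).tolist()
        assert not np.allclose(t1.X, t2.X)

    def test_disjoint_exhaustive(self, mini_dataset):
        train, test = split_dataset(mini_dataset, 0.8, seed=3)
        assert len(train) + len(test) == len(mini_dataset)
        stacked = np.vstack([train.X, test.X])
        assert stacked.shape[0] == np.unique(stacked, axis=0).shape[0]

    def test_stratification_proportions(self, mini_dataset):
        train, test = split_dataset(mini_dataset, 0.8, seed=4)
        for part in (train, test):
            props = np.bincount(part.y) / len(part)
            assert np.abs(props - 0.2).max() < 1 / len(part)

    def test_by_segment_no_leakage(self, mini_dataset):
        train, test = split_dataset(mini_dataset, 0.5, seed=0, by_segment=True)
        assert set(train.segment_ids) & set(test.segment_ids) == set()


class TestKFold:
    def test_equal_fold_sizes(self):
        y = np.zeros(2300, dtype=int)
        folds = kfold_indices(y, k=10, seed=0)
        assert [f.size for f in folds] == [230] * 10

    def test_leave_one_out_tiny(self):
        y = np.arange(4) % 2
        folds = kfold_indices(y, k=2, seed=0)
        union = np.sort(np.concatenate(folds))
        np.testing.assert_array_equal(union, np.arange(4))

    def test_seeded_reproducibility(self):
        y = np.repeat([0, 1, 2], 30)
        f1 = kfold_indices(y, k=5, seed=7)
        f2 = kfold_indices(y, k=5, seed=7)
        for a, b in zip(f1, f2):
            np.testing.assert_array_equal(a, b)

    def test_k_too_small_rejected(self):
        with pytest.raises(ValueError):
            kfold_indices(np.zeros(10, dtype=int), k=1)


class TestSubsetSelector:
    def test_two_class_selection(self, mini_dataset):
        ds = subset_selector(mini_dataset, "A vs E")
        assert len(ds) == 2 * 46
        assert set(ds.y) == {0, 1}

    def test_imbalanced_groups(self, mini_dataset):
        ds = subset_selector(mini_dataset, "AB vs CDE")
        assert (ds.y == 0).sum() == 2 * 46
        assert (ds.y == 1).sum() == 3 * 46

    def test_overlap_rejected(self, mini_dataset):
        with pytest.raises(ValueError, match="overlap"):
            subset_selector(mini_dataset, "A vs A")

    def test_three_way_groups(self, mini_dataset):
        ds = subset_selector(mini_dataset, "AB vs CD vs E")
        assert set(ds.y) == {0, 1, 2}
        assert ds.label_names == ("AB", "CD", "E")
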