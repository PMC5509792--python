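"""ECOC classification, cross-validation bookkeeping, pooled confusion
metrics (with brute-force oracle), block averaging and sweeps."""

import numpy as np
import pandas as pd
import pytest
from sklearn.multiclass import OneVsOneClassifier
from sklearn.svm import SVC

from neuroload.evaluate import (PairwiseECOC, confusion_metrics, crossvalidate,
                                grand_block_average, metrics_table,
                                sweep_nfeatures, train_binary)
from neuroload.types import (EEG_CHANNELS, FeatureTable, Recording, Block,
                             Window)


def plv_meta(n):
    """Metadata marking every column PLV: passthrough, no PCA."""
    return pd.DataFrame({
        "subgroup": ["PLV"] * n, "nv_type": [""] * n,
        "band": [str(i) for i in range(n)], "chromophore": [""] * n,
        "channel": ["F7-F8"] * n,
    })


def gaussian_blobs(rng, n_per, centers, spread=1.0):
    X = np.vstack([c + spread * rng.standard_normal((n_per, len(c)))
                   for c in centers])
    y = np.repeat(np.arange(len(centers)), n_per)
    return X, y


class TestPairwiseECOC:
    def test_five_classes_ten_learners(self, rng):
        X, y = gaussian_blobs(rng, 10, np.eye(5) * 4)
        m = PairwiseECOC().fit(X, y)
        assert len(m.learners_) == 10        # C(5,2)

    def test_two_classes_equals_binary_svm(self, rng):
        X, y = gaussian_blobs(rng, 20, [np.zeros(3), np.full(3, 2.0)])
        m = PairwiseECOC(balance=None).fit(X, y)
        assert len(m.learners_) == 1
        Xte = rng.standard_normal((30, 3))
        np.testing.assert_array_equal(m.predict(Xte),
                                      train_binary(X, y).predict(Xte))

    def test_well_separated_three_class_accuracy(self, rng):
        centers = [np.r_[4, 0, np.zeros(8)], np.r_[0, 4, np.zeros(8)],
                   np.r_[-4, -4, np.zeros(8)]]
        Xtr, ytr = gaussian_blobs(rng, 100, centers)
        Xte, yte = gaussian_blobs(rng, 50, centers)
        m = PairwiseECOC().fit(Xtr, ytr)
        assert np.mean(m.predict(Xte) == yte) >= 0.95

    def test_agrees_with_sklearn_ovo_cross_check(self, rng):
        """Independent route: sklearn's one-vs-one on well-separated data."""
        centers = [np.r_[3, 0, 0], np.r_[0, 3, 0], np.r_[0, 0, 3],
                   np.r_[-3, -3, -3]]
        Xtr, ytr = gaussian_blobs(rng, 40, centers)
        Xte, _ = gaussian_blobs(rng, 25, centers)
        ours = PairwiseECOC(balance=None).fit(Xtr, ytr).predict(Xte)
        ref = OneVsOneClassifier(SVC(kernel="linear", C=1.0)).fit(
            Xtr, ytr).predict(Xte)
        assert np.mean(ours == ref) == 1.0

    def test_single_class_fatal(self, rng):
        with pytest.raises(ValueError):
            PairwiseECOC().fit(rng.standard_normal((10, 2)), np.zeros(10))


class TestBinarySVM:
    def test_separable_toy_trains_perfectly(self, rng):
        X, y = gaussian_blobs(rng, 30, [np.zeros(2), np.full(2, 10.0)], 0.5)
        clf = train_binary(X, y)
        assert np.mean(clf.predict(X) == y) == 1.0

    def test_duplicated_rows_same_boundary(self, rng):
        X, y = gaussian_blobs(rng, 25, [np.zeros(2), np.full(2, 4.0)])
        a = train_binary(X, y)
        b = train_binary(np.vstack([X, X]), np.concatenate([y, y]))
        np.testing.assert_allclose(a.coef_, b.coef_, atol=1e-6)
        np.testing.assert_allclose(a.intercept_, b.intercept_, atol=1e-6)

    def test_label_permutation_near_chance(self, rng):
        """Binary CV on permuted labels stays inside the binomial band."""
        correct = total = 0
        from sklearn.model_selection import KFold
        for rep in range(10):
            X = rng.standard_normal((60, 20))
            y = rng.permutation(np.repeat([0, 1], 30))
            for tr, te in KFold(6, shuffle=True, random_state=rep).split(X):
                clf = train_binary(X[tr], y[tr])
                correct += (clf.predict(X[te]) == y[te]).sum()
                total += len(te)
        acc = correct / total
        band = 2.576 * np.sqrt(0.25 / total)
        assert abs(acc - 0.5) < band


class TestCrossvalidate:
    def _table(self, rng, n=100, d=12, informative=True):
        X = rng.standard_normal((n, d))
        y = np.tile([0, 4], n // 2)
        if informative:
            X[:, 0] += 3.0 * (y == 4)
        windows = [Window(label="rest" if c == 0 else "3back",
                          t_start=5.0 * i, t_end=5.0 * i + 5.0,
                          source_block=i // 2)
                   for i, c in enumerate(y)]
        return FeatureTable(X, plv_meta(d), y, windows)

    def test_fold_bookkeeping(self, rng):
        rep = crossvalidate(self._table(rng), ["rest", "3back"], k=10, seed=0)
        assert len(rep.fold_accuracies) == 10
        assert rep.n_test == 100                 # every window tested once
        conf = rep.pooled_confusion.to_numpy()
        np.testing.assert_array_equal(conf.sum(axis=1), [50, 50])
        assert rep.pooled_accuracy == pytest.approx(np.trace(conf) / 100)

    def test_perfect_separation(self, rng):
        X = np.zeros((40, 3))
        y = np.tile([0, 4], 20)
        X[:, 1] = np.where(y == 4, 10.0, -10.0)
        X += 0.01 * rng.standard_normal(X.shape)
        table = FeatureTable(X, plv_meta(3), y)
        rep = crossvalidate(table, ["rest", "3back"], k=10, seed=1)
        assert rep.mean_accuracy == 1.0
        assert rep.sd_accuracy == 0.0

    def test_same_seed_reproducible(self, rng):
        table = self._table(rng, informative=False)
        a = crossvalidate(table, ["rest", "3back"], k=10, seed=7)
        b = crossvalidate(table, ["rest", "3back"], k=10, seed=7)
        assert a.fold_accuracies == b.fold_accuracies
        assert a.pooled_confusion.equals(b.pooled_confusion)

    def test_k_exceeding_windows_fatal(self, rng):
        with pytest.raises(ValueError, match="exceeds"):
            crossvalidate(self._table(rng, n=8), ["rest", "3back"], k=10)

    def test_block_partition_keeps_blocks_together(self, rng):
        from neuroload.evaluate import _fold_indices
        table = self._table(rng)
        blocks = np.array([w.source_block for w in table.windows])
        for tr, te in _fold_indices(table, 5, 0, "block"):
            assert set(blocks[tr]).isdisjoint(set(blocks[te]))


class TestConfusionMetrics:
    def test_worked_binary_example(self):
        pooled = np.array([[8, 2], [1, 9]])
        m = confusion_metrics(pooled, 0)
        assert m["Sens"] == pytest.approx(0.8)
        assert m["Spec"] == pytest.approx(0.9)
        assert m["PPV"] == pytest.approx(8 / 9)
        assert m["NPV"] == pytest.approx(9 / 11)

    def test_binary_complement_identities(self, rng):
        pooled = rng.integers(1, 30, size=(2, 2))
        a = confusion_metrics(pooled, 0)
        b = confusion_metrics(pooled, 1)
        assert a["Sens"] == pytest.approx(b["Spec"])
        assert a["PPV"] == pytest.approx(b["NPV"])

    def test_zero_denominator_reported_absent(self):
        pooled = np.array([[0, 0], [5, 5]])    # class 0 never occurs
        m = confusion_metrics(pooled, 0)
        assert m["Sens"] is None
        assert m["Spec"] is not None

    def test_matches_counting_oracle(self, rng):
        pooled = rng.integers(0, 25, size=(5, 5))
        for cls in range(5):
            got = confusion_metrics(pooled, cls)
            tp = fn = fp = tn = 0
            for i in range(5):           # explicit counting, no slicing
                for j in range(5):
                    v = int(pooled[i, j])
                    if i == cls and j == cls:
                        tp += v
                    elif i == cls:
                        fn += v
                    elif j == cls:
                        fp += v
                    else:
                        tn += v
            for key, num, den in (("Sens", tp, tp + fn), ("Spec", tn, tn + fp),
                                  ("PPV", tp, tp + fp), ("NPV", tn, tn + fn)):
                if den == 0:
                    assert got[key] is None
                else:
                    assert got[key] == pytest.approx(num / den, rel=1e-9)


class TestGrandBlockAverage:
    def _rec(self, data):
        return Recording("eeg", EEG_CHANNELS, 10.0, data)

    def test_identical_blocks_zero_sd(self):
        seg = np.tile(np.sin(np.arange(100) / 5.0), (19, 1))
        data = np.concatenate([seg, seg], axis=1)
        blocks = [Block("task", "3back", 0.0, 10.0, 0),
                  Block("task", "3back", 10.0, 20.0, 1)]
        mean, sd = grand_block_average([self._rec(data)], [blocks], "3back")
        assert np.allclose(sd, 0.0, atol=1e-9)

    def test_opposite_blocks_zero_mean(self):
        seg = np.tile(np.sin(np.arange(100) / 5.0), (19, 1))
        data = np.concatenate([seg, -seg], axis=1)
        blocks = [Block("task", "2back", 0.0, 10.0, 0),
                  Block("task", "2back", 10.0, 20.0, 1)]
        mean, _ = grand_block_average([self._rec(data)], [blocks], "2back",
                                      normalize=False)
        assert np.allclose(mean, 0.0, atol=1e-9)


def test_sweep_full_size_matches_untruncated(rng):
    X = rng.standard_normal((60, 8))
    y = np.tile([0, 4], 30)
    X[:, 2] += 2.5 * (y == 4)
    table = FeatureTable(X, plv_meta(8), y)
    curve = sweep_nfeatures(table, ["rest", "3back"], systems=("eeg",),
                            grid=[8], k=5, seed=3)
    ref = crossvalidate(table, ["rest", "3back"], system="eeg", k=5, seed=3)
    assert curve["accuracy"].iloc[0] == pytest.approx(ref.mean_accuracy)
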