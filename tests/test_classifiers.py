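"""Classifier families, metrics, cross-validation, prediction surfaces."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from affectmap.classifiers import (
    DEFAULT_GRIDS, KNNConfig, NNConfig, SVMConfig, accuracy, cohens_kappa,
    classify_points, cross_validate, model_view_map, probability_surface,
    split_train_test, train_knn, train_nn, train_svm,
)
from affectmap.core import TERMS, ClassificationDataset, to_model_space
from tests.conftest import make_dataset


def _cloud_dataset(centers, n_per, sd=6.0, seed=0):
    """Tight per-term clouds; centers is a dict term -> (v, a)."""
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_per):
        for t, (mv, ma) in centers.items():
            v = np.clip(rng.normal(mv, sd), 0, 500)
            a = np.clip(rng.normal(ma, sd), 0, 500)
            rows.append((f"p{p:03d}", t, v, a))
    return make_dataset(rows)


FOUR_CLOUDS = {
    "happy": (420, 330), "sad": (90, 170), "angry": (80, 420),
    "calm": (380, 150),
}


class TestSplit:
    def test_seventy_thirty_by_participant(self, medium_dataset):
        train, test = split_train_test(medium_dataset, seed=0)
        assert train.n_participants == 140 and test.n_participants == 60
        assert not set(train.participants) & set(test.participants)
        # both sides stay class-balanced
        for side in (train, test):
            counts = side.df.groupby("term").size()
            assert counts.nunique() == 1

    def test_deterministic(self, medium_dataset):
        a1, _ = split_train_test(medium_dataset, seed=4)
        a2, _ = split_train_test(medium_dataset, seed=4)
        assert a1.participants == a2.participants

    def test_too_few_participants(self):
        ds = make_dataset([("p", t, 250.0, 250.0) for t in TERMS])
        with pytest.raises(ValueError):
            split_train_test(ds)


class TestNN:
    def test_separable_clouds_high_accuracy(self):
        train = _cloud_dataset(FOUR_CLOUDS, 40, seed=1)
        test = _cloud_dataset(FOUR_CLOUDS, 20, seed=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf = train_nn(train, NNConfig(hidden_size=10))
        pred = clf.predict_terms(test.to_xy())
        assert accuracy(pred, test.df["term"].to_numpy()) > 0.95

    def test_probabilities_normalized(self):
        train = _cloud_dataset(FOUR_CLOUDS, 10)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf = train_nn(train, NNConfig(hidden_size=5))
        rng = np.random.default_rng(0)
        p = clf.predict_proba(rng.uniform(0, 500, (50, 2)))
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-9)
        assert (p >= 0).all()

    def test_huge_decay_flattens_to_class_frequencies(self):
        # L2 decay drives the weights to ~0; softmax of the bias-only model
        # reproduces the (uniform) training class frequencies everywhere
        train = _cloud_dataset(FOUR_CLOUDS, 25)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf = train_nn(train, NNConfig(hidden_size=5, decay=1e6))
        p = clf.predict_proba(np.array([[50.0, 50.0], [450.0, 450.0]]))
        trained = p[:, p[0] > 0]
        assert np.allclose(trained, 0.25, atol=0.01)


class TestKNN:
    def test_pure_neighborhood(self):
        rows = [(f"p{i}", "happy", 100.0 + i, 100.0) for i in range(5)]
        rows += [(f"q{i}", "sad", 400.0 + i, 400.0) for i in range(5)]
        clf = train_knn(make_dataset(rows), KNNConfig(k=5))
        p = clf.predict_proba(np.array([[102.0, 101.0]]))[0]
        assert p[TERMS.index("happy")] == 1.0

    def test_mixed_neighborhood_proportions(self):
        # 100 "happy" nearer than 75 "satisfied"; k=175 covers exactly both
        rows = [(f"h{i}", "happy", 240.0 + (i % 10), 240.0 + i // 10)
                for i in range(100)]
        rows += [(f"s{i}", "satisfied", 400.0 + (i % 10), 400.0 + i // 10)
                 for i in range(75)]
        clf = train_knn(make_dataset(rows), KNNConfig(k=175))
        p = clf.predict_proba(np.array([[245.0, 245.0]]))[0]
        assert p[TERMS.index("happy")] == pytest.approx(100 / 175)
        assert p[TERMS.index("satisfied")] == pytest.approx(75 / 175)

    def test_self_prediction_k1(self):
        rows = [(f"p{i}", t, 100.0 * (i + 1), 50.0 * (i + 1))
                for i, t in enumerate(["happy", "sad", "angry"])]
        clf = train_knn(make_dataset(rows), KNNConfig(k=1))
        p = clf.predict_proba(np.array([[200.0, 100.0]]))[0]
        assert p[TERMS.index("sad")] == 1.0

    def test_distance_ties_included_beyond_k(self):
        # two training points equidistant from the query with k=1: both join
        rows = [("a", "happy", 200.0, 250.0), ("b", "sad", 300.0, 250.0)]
        clf = train_knn(make_dataset(rows), KNNConfig(k=1))
        p = clf.predict_proba(np.array([[250.0, 250.0]]))[0]
        assert p[TERMS.index("happy")] == p[TERMS.index("sad")] == 0.5

    def test_matches_bruteforce_oracle(self, medium_dataset):
        clf = train_knn(medium_dataset, KNNConfig(k=175))
        rng = np.random.default_rng(8)
        queries = rng.uniform(0, 500, (200, 2))
        got = clf.predict_proba(queries)
        X = to_model_space(medium_dataset.to_xy())
        y = medium_dataset.labels()
        Q = to_model_space(queries)
        for qi in range(len(Q)):
            d = np.sqrt(((X - Q[qi]) ** 2).sum(axis=1))
            order = np.argsort(d, kind="stable")
            dk = d[order[174]]
            idx = np.flatnonzero(d <= dk)  # tie-inclusive neighborhood
            expect = np.bincount(y[idx], minlength=20) / len(idx)
            assert np.allclose(got[qi], expect, atol=1e-12)

    def test_k_larger_than_train_rejected(self):
        rows = [(f"p{i}", "happy", 10.0 * i, 10.0) for i in range(5)]
        with pytest.raises(ValueError):
            train_knn(make_dataset(rows), KNNConfig(k=6))


class TestSVM:
    def test_separable_two_class(self):
        centers = {"happy": (420, 330), "sad": (90, 170)}
        train = _cloud_dataset(centers, 30, seed=3)
        clf = train_svm(train, SVMConfig(cost=1.0))
        pred = clf.predict_terms(train.to_xy())
        assert accuracy(pred, train.df["term"].to_numpy()) == 1.0

    def test_vote_shares_sum_to_one(self, small_dataset):
        clf = train_svm(small_dataset, SVMConfig())
        rng = np.random.default_rng(1)
        p = clf.predict_proba(rng.uniform(0, 500, (30, 2)))
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-9)

    def test_degenerate_class_rejected(self):
        rows = [("a", "happy", 100.0, 100.0), ("b", "happy", 105.0, 100.0),
                ("a", "sad", 400.0, 400.0)]
        with pytest.raises(ValueError, match="degenerate"):
            train_svm(make_dataset(rows))

    def test_underperforms_nn_on_overlapping_circumplex(self, medium_dataset):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            train, test = split_train_test(medium_dataset, seed=0)
            nn = train_nn(train)
            svm = train_svm(train)
        truth = test.df["term"].to_numpy()
        acc_nn = accuracy(nn.predict_terms(test.to_xy()), truth)
        acc_svm = accuracy(svm.predict_terms(test.to_xy()), truth)
        assert acc_svm < acc_nn


class TestMetrics:
    def test_accuracy_exact(self):
        assert accuracy(["a"] * 20, ["a"] * 20) == 1.0
        pred = ["a"] * 7 + ["b"] * 13
        true = ["a"] * 20
        assert accuracy(pred, true) == 0.35

    def test_accuracy_mismatch(self):
        with pytest.raises(ValueError):
            accuracy([1, 2], [1])

    def test_kappa_perfect_and_chance(self):
        true = np.repeat(np.arange(20), 5)
        assert cohens_kappa(true, true) == 1.0
        # constant guessing on balanced truth sits exactly at chance
        assert cohens_kappa(np.zeros_like(true), true) == pytest.approx(0.0)

    @given(st.integers(0, 2 ** 20 - 1))
    @settings(deadline=None, max_examples=40)
    def test_balanced_truth_identity(self, bits):
        # kappa = (acc - 1/20) / (1 - 1/20) for ANY prediction vector when
        # the truth is balanced over the 20 classes
        true = np.repeat(np.arange(20), 3)
        rng = np.random.default_rng(bits)
        pred = rng.integers(0, 20, true.size)
        acc = np.mean(pred == true)
        assert cohens_kappa(pred, true) == pytest.approx(
            (acc - 0.05) / 0.95, abs=1e-12
        )


class TestCrossValidate:
    def test_single_config_returned(self, small_dataset):
        best, table = cross_validate("knn", small_dataset, [KNNConfig(k=20)],
                                     seed=0)
        assert best == KNNConfig(k=20)
        assert len(table) == 1
        accs = table.loc[0, "fold_accuracies"]
        assert all(0.0 <= a <= 1.0 for a in accs)
        assert table.loc[0, "cv_accuracy"] == pytest.approx(np.mean(accs))

    def test_selects_small_k_on_tight_clouds(self):
        # Bayes-optimal smoothing is small for tight, well-separated clouds
        rng = np.random.default_rng(0)
        rows = []
        centers = {t: (60 + 95 * (i % 5), 70 + 120 * (i // 5))
                   for i, t in enumerate(TERMS)}
        for p in range(40):
            for t, (mv, ma) in centers.items():
                rows.append((f"p{p:03d}", t,
                             float(np.clip(rng.normal(mv, 8), 0, 500)),
                             float(np.clip(rng.normal(ma, 8), 0, 500))))
        ds = make_dataset(rows)
        grid = [KNNConfig(k=1), KNNConfig(k=5), KNNConfig(k=500)]
        best, _ = cross_validate("knn", ds, grid, seed=1)
        assert best.k in (1, 5)

    def test_default_grids_include_canonical_configs(self):
        assert NNConfig(hidden_size=27, decay=0.035) in [
            NNConfig(hidden_size=c.hidden_size, decay=c.decay)
            for c in DEFAULT_GRIDS["nn"]
        ]
        assert KNNConfig(k=175) in DEFAULT_GRIDS["knn"]
        assert SVMConfig(cost=0.01) in DEFAULT_GRIDS["svm"]


class TestSurfaces:
    @pytest.fixture(scope="class")
    def knn_clf(self):
        centers = {"happy": (420, 330), "sad": (90, 170), "angry": (80, 420)}
        return train_knn(_cloud_dataset(centers, 30, seed=5), KNNConfig(k=7))

    def test_view_matches_surface_argmax(self, knn_clf):
        res = 21
        view = model_view_map(knn_clf, res)
        stack = np.stack([probability_surface(knn_clf, t, res) for t in TERMS])
        assert np.array_equal(view, np.argmax(stack, axis=0))
        assert np.allclose(stack.sum(axis=0), 1.0, atol=1e-9)

    def test_three_class_map_has_three_connected_regions(self, knn_clf):
        view = model_view_map(knn_clf, 41)
        present = np.unique(view)
        assert len(present) == 3
        for cls in present:
            _, n_comp = ndimage.label(view == cls)
            assert n_comp == 1

    def test_training_set_consistency(self, small_dataset):
        clf = train_knn(small_dataset, KNNConfig(k=10))
        pred = np.array(TERMS)[
            np.argmax(classify_points(clf, small_dataset.to_xy()), axis=1)
        ]
        acc1 = accuracy(pred, small_dataset.df["term"].to_numpy())
        acc2 = accuracy(clf.predict_terms(small_dataset.to_xy()),
                        small_dataset.df["term"].to_numpy())
        assert acc1 == acc2
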