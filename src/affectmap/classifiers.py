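"""Supervised 2D -> 20-class emotion classifiers and their evaluation.

Three families, all consuming (valence, arousal) points and emitting a
20-entry probability vector over the canonical terms:

* ``nn`` — a feed-forward single-hidden-layer network (2 -> H -> 20,
  logistic hidden units, softmax output) trained by full-batch L-BFGS on
  cross-entropy with L2 weight decay;
* ``knn`` — neighborhood class proportions among the k nearest training
  points (Euclidean, model space), with all points tied at the k-th
  distance included;
* ``svm`` — one-vs-one RBF soft-margin machines over all 190 class
  pairs; probabilities are normalized pairwise vote shares.

Points are scaled to model space [-1, 1]^2 internally, so the
scale-sensitive hyperparameters (weight decay, cost) are reproducible.
Model selection uses participant-level 10-fold cross-validation on a
70-30 participant-level train-test split, scored by accuracy; Cohen's
kappa is reported alongside (with balanced truth over the 20 classes the
chance agreement is exactly 1/20).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .core import TERMS, ClassificationDataset, to_model_space, validate_points

N_CLASSES = len(TERMS)


# ---------------------------------------------------------------------------
# Configs


@dataclass(frozen=True)
class NNConfig:
    hidden_size: int = 27
    decay: float = 0.035
    max_iter: int = 500
    init_seed: int = 0

    def __post_init__(self):
        if self.hidden_size < 1:
            raise ValueError("hidden_size must be >= 1")
        if self.decay < 0:
            raise ValueError("decay must be >= 0")


@dataclass(frozen=True)
class KNNConfig:
    k: int = 175

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass(frozen=True)
class SVMConfig:
    cost: float = 0.01

    def __post_init__(self):
        if self.cost <= 0:
            raise ValueError("cost must be > 0")


# ---------------------------------------------------------------------------
# Trained classifiers


class TrainedClassifier:
    """Base class: a fitted 2D -> 20-class probabilistic classifier."""

    family: str = ""

    def __init__(self, config, metadata: dict | None = None):
        self.config = config
        self.metadata = dict(metadata or {})

    def predict_proba(self, points: np.ndarray) -> np.ndarray:
        """(n, 20) probability matrix in canonical term order; rows sum to 1."""
        raise NotImplementedError

    def predict_terms(self, points: np.ndarray) -> np.ndarray:
        """Argmax term name per point (first term wins exact ties)."""
        idx = np.argmax(self.predict_proba(points), axis=1)
        return np.array(TERMS)[idx]


class NNClassifier(TrainedClassifier):
    family = "nn"

    def __init__(self, config: NNConfig, mlp: MLPClassifier, metadata=None):
        super().__init__(config, metadata)
        self._mlp = mlp
        # Weights exported for JSON round-tripping and direct replay.
        self.coefs = [w.copy() for w in mlp.coefs_]
        self.intercepts = [b.copy() for b in mlp.intercepts_]
        self._classes = np.asarray(mlp.classes_)

    def predict_proba(self, points: np.ndarray) -> np.ndarray:
        X = to_model_space(validate_points(points))
        hidden = 1.0 / (1.0 + np.exp(-(X @ self.coefs[0] + self.intercepts[0])))
        logits = hidden @ self.coefs[1] + self.intercepts[1]
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        p /= p.sum(axis=1, keepdims=True)
        # Classes absent from training (unbalanced toy data) get probability 0.
        out = np.zeros((len(X), N_CLASSES))
        out[:, self._classes] = p
        return out


class KNNClassifier(TrainedClassifier):
    family = "knn"

    def __init__(self, config: KNNConfig, X_model: np.ndarray, y: np.ndarray,
                 metadata=None):
        super().__init__(config, metadata)
        self.X_model = np.asarray(X_model, dtype=float)
        self.y = np.asarray(y, dtype=int)
        self._tree = cKDTree(self.X_model)

    def predict_proba(self, points: np.ndarray) -> np.ndarray:
        Q = to_model_space(validate_points(points))
        k = self.config.k
        dist, _ = self._tree.query(Q, k=k)
        dk = dist.reshape(len(Q), k)[:, -1]
        out = np.zeros((len(Q), N_CLASSES))
        for i, (q, r) in enumerate(zip(Q, dk)):
            # Candidates from the tree with a slightly inflated radius, then
            # exact distances: all points tied with the k-th neighbor are
            # included, so the effective neighborhood may exceed k.
            cand = np.asarray(
                self._tree.query_ball_point(q, r * (1 + 1e-9) + 1e-12), dtype=int
            )
            d = np.sqrt(((self.X_model[cand] - q) ** 2).sum(axis=1))
            kth = np.partition(d, k - 1)[k - 1]
            idx = cand[d <= kth]
            counts = np.bincount(self.y[idx], minlength=N_CLASSES)
            out[i] = counts / counts.sum()
        return out


class SVMClassifier(TrainedClassifier):
    family = "svm"

    def __init__(self, config: SVMConfig, svc: SVC, X_model=None, y=None,
                 metadata=None):
        super().__init__(config, metadata)
        self._svc = svc
        self._classes = np.asarray(svc.classes_)
        # Training set retained for deterministic JSON round-tripping.
        self.X_model = None if X_model is None else np.asarray(X_model, dtype=float)
        self.y = None if y is None else np.asarray(y, dtype=int)

    def predict_proba(self, points: np.ndarray) -> np.ndarray:
        X = to_model_space(validate_points(points))
        df = self._svc.decision_function(X)
        k = len(self._classes)
        if k == 2:
            # binary SVC emits a single column with positive -> classes_[1]
            df = -df.reshape(-1, 1)
        votes = np.zeros((len(X), k))
        pair = 0
        # libsvm pair order (0,1),(0,2),...; a positive margin votes the
        # first class of the pair.
        for i in range(k):
            for j in range(i + 1, k):
                pos = df[:, pair] > 0
                votes[pos, i] += 1
                votes[~pos, j] += 1
                pair += 1
        out = np.zeros((len(X), N_CLASSES))
        out[:, self._classes] = votes / votes.sum(axis=1, keepdims=True)
        return out


# ---------------------------------------------------------------------------
# Training


def split_train_test(
    dataset: ClassificationDataset, train_fraction: float = 0.70, seed: int | None = 0
) -> tuple[ClassificationDataset, ClassificationDataset]:
    """Participant-level split: all 20 rows of a participant stay together.

    Class balance is preserved automatically (each term appears once per
    included participant).  Deterministic given the seed.
    """
    pids = dataset.participants
    if len(pids) < 2:
        raise ValueError("need at least 2 participants to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(pids))
    n_train = int(round(train_fraction * len(pids)))
    n_train = min(max(n_train, 1), len(pids) - 1)
    train_ids = [pids[i] for i in perm[:n_train]]
    test_ids = [pids[i] for i in perm[n_train:]]
    return dataset.subset(train_ids), dataset.subset(test_ids)


def train_nn(train: ClassificationDataset, config: NNConfig = NNConfig()) -> NNClassifier:
    """Fit the single-hidden-layer network (2 -> hidden -> 20).

    Full-batch L-BFGS on softmax cross-entropy with L2 weight decay
    ``config.decay``; deterministic given ``config.init_seed``.  If the
    optimizer hits ``max_iter`` a convergence warning is emitted and the
    model is still returned.
    """
    if len(train) == 0:
        raise ValueError("empty training set")
    X = to_model_space(train.to_xy())
    y = train.labels()
    mlp = MLPClassifier(
        hidden_layer_sizes=(config.hidden_size,),
        activation="logistic",
        solver="lbfgs",
        alpha=config.decay,
        max_iter=config.max_iter,
        random_state=config.init_seed,
    )
    mlp.fit(X, y)
    return NNClassifier(config, mlp, metadata={"n_train": len(train)})


def train_knn(train: ClassificationDataset, config: KNNConfig = KNNConfig()) -> KNNClassifier:
    if config.k > len(train):
        raise ValueError(f"k={config.k} exceeds training-set size {len(train)}")
    return KNNClassifier(
        config, to_model_space(train.to_xy()), train.labels(),
        metadata={"n_train": len(train)},
    )


def median_heuristic_gamma(X: np.ndarray, max_points: int = 2000, seed: int = 0) -> float:
    """RBF gamma = 1 / (2 sigma^2) with sigma the median pairwise distance."""
    rng = np.random.default_rng(seed)
    if len(X) > max_points:
        X = X[rng.choice(len(X), max_points, replace=False)]
    d2 = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=-1)
    med = np.sqrt(np.median(d2[np.triu_indices(len(X), k=1)]))
    return 1.0 / (2.0 * med ** 2)


def train_svm(train: ClassificationDataset, config: SVMConfig = SVMConfig()) -> SVMClassifier:
    """One-vs-one RBF SVMs over all class pairs present in the data."""
    counts = train.df["term"].value_counts()
    thin = counts[counts < 2]
    if len(thin):
        raise ValueError(f"degenerate class with < 2 points: {thin.index.tolist()}")
    X = to_model_space(train.to_xy())
    y = train.labels()
    gamma = median_heuristic_gamma(X)
    svc = SVC(C=config.cost, kernel="rbf", gamma=gamma,
              decision_function_shape="ovo")
    svc.fit(X, y)
    return SVMClassifier(config, svc, X_model=X, y=y,
                         metadata={"kernel": "rbf", "gamma": gamma,
                                   "n_train": len(train)})


_TRAINERS = {"nn": train_nn, "knn": train_knn, "svm": train_svm}


def train(family: str, dataset: ClassificationDataset, config=None) -> TrainedClassifier:
    if family not in _TRAINERS:
        raise ValueError(f"unknown classifier family {family!r}")
    default = {"nn": NNConfig, "knn": KNNConfig, "svm": SVMConfig}[family]
    return _TRAINERS[family](dataset, config if config is not None else default())


# ---------------------------------------------------------------------------
# Metrics


def accuracy(predicted: Sequence, true: Sequence) -> float:
    """Proportion of correct classifications."""
    predicted = np.asarray(predicted)
    true = np.asarray(true)
    if predicted.shape != true.shape:
        raise ValueError("length mismatch between predictions and truth")
    if predicted.size == 0:
        raise ValueError("empty label vectors")
    return float(np.mean(predicted == true))


def cohens_kappa(predicted: Sequence, true: Sequence) -> float:
    """Chance-corrected agreement, kappa = (p_o - p_e) / (1 - p_e).

    p_e is the product-marginal chance agreement.  When the truth is
    balanced over the 20 terms, p_e = 1/20 exactly regardless of the
    prediction marginals, so kappa = (acc - 0.05) / 0.95.
    """
    predicted = np.asarray(predicted)
    true = np.asarray(true)
    if predicted.shape != true.shape:
        raise ValueError("length mismatch between predictions and truth")
    n = predicted.size
    p_o = np.mean(predicted == true)
    labels = np.union1d(predicted, true)
    p_e = sum(
        np.mean(true == lab) * np.mean(predicted == lab) for lab in labels
    )
    if p_e >= 1.0:
        raise ValueError("degenerate agreement: chance agreement is 1")
    return float((p_o - p_e) / (1.0 - p_e))


# ---------------------------------------------------------------------------
# Cross-validation


def _participant_folds(pids: list, n_folds: int, rng: np.random.Generator):
    perm = rng.permutation(len(pids))
    return [sorted(pids[i] for i in fold) for fold in np.array_split(perm, n_folds)]


def _complexity_key(family: str, config):
    # Ties in CV accuracy resolve toward the simpler model: fewer hidden
    # nodes then stronger decay (nn), smaller k (knn), smaller cost (svm).
    if family == "nn":
        return (config.hidden_size, -config.decay)
    if family == "knn":
        return (config.k,)
    return (config.cost,)


def cross_validate(
    family: str,
    train_ds: ClassificationDataset,
    grid: Sequence,
    folds: int = 10,
    seed: int | None = 0,
) -> tuple[object, pd.DataFrame]:
    """Participant-level k-fold CV over a hyperparameter grid.

    Returns ``(best_config, table)`` where the table holds one row per
    grid point with the mean held-fold accuracy.  The argmax config is
    returned; exact ties resolve to the smallest-complexity config.
    """
    if not grid:
        raise ValueError("empty hyperparameter grid")
    pids = train_ds.participants
    rng = np.random.default_rng(seed)
    fold_ids = _participant_folds(pids, min(folds, len(pids)), rng)
    fold_sets = [train_ds.subset(f) for f in fold_ids]
    fold_rest = [
        train_ds.subset([p for p in pids if p not in set(f)]) for f in fold_ids
    ]
    records = []
    for config in grid:
        accs = []
        for held, rest in zip(fold_sets, fold_rest):
            if len(held) == 0:
                continue
            if set(rest.df["term"]) != set(TERMS):
                warnings.warn("fold with a missing class; accuracy still computed")
            clf = train(family, rest, config)
            pred = clf.predict_terms(held.to_xy())
            accs.append(accuracy(pred, held.df["term"].to_numpy()))
        records.append({"config": config, "cv_accuracy": float(np.mean(accs)),
                        "fold_accuracies": accs})
    table = pd.DataFrame(records)
    best_acc = table["cv_accuracy"].max()
    tied = table.index[table["cv_accuracy"] == best_acc]
    best = min((table.loc[i, "config"] for i in tied),
               key=lambda c: _complexity_key(family, c))
    return best, table


DEFAULT_GRIDS = {
    "nn": [NNConfig(hidden_size=h, decay=d)
           for h in (5, 10, 15, 20, 25, 27, 30, 35, 40, 45, 50)
           for d in (0.001, 0.0035, 0.01, 0.035, 0.1)],
    "knn": [KNNConfig(k=k) for k in (5, 25, 75, 125, 175, 225, 325)],
    "svm": [SVMConfig(cost=c) for c in (0.001, 0.01, 0.1, 1.0, 10.0)],
}


# ---------------------------------------------------------------------------
# Prediction surfaces


def classify_points(classifier: TrainedClassifier, points: np.ndarray) -> np.ndarray:
    """One valid probability vector per input point."""
    return classifier.predict_proba(points)


def _lattice(resolution: int) -> tuple[np.ndarray, np.ndarray]:
    if resolution < 2:
        raise ValueError("resolution must be >= 2")
    g = np.linspace(0.0, 500.0, resolution)
    vv, aa = np.meshgrid(g, g)
    return g, np.column_stack([vv.ravel(), aa.ravel()])


def model_view_map(classifier: TrainedClassifier, resolution: int = 101) -> np.ndarray:
    """Most-likely term index at each lattice point; shape (res, res).

    Row index runs along arousal, column index along valence (both low to
    high, matching the y-up grid convention).
    """
    g, pts = _lattice(resolution)
    idx = np.argmax(classifier.predict_proba(pts), axis=1)
    return idx.reshape(resolution, resolution)


def probability_surface(
    classifier: TrainedClassifier, term: str, resolution: int = 101
) -> np.ndarray:
    """P(term) evaluated on the lattice; shape (res, res)."""
    from .core import TERM_INDEX
    g, pts = _lattice(resolution)
    p = classifier.predict_proba(pts)[:, TERM_INDEX[term]]
    return p.reshape(resolution, resolution)
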