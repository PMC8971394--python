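"""Model/Results facade over the emotion-mapping pipeline.

Two modelling objects in the statsmodels idiom:

* :class:`EmotionMap` — built from emotion-classification-task ratings;
  ``fit()`` trains one of the classifier families on a participant-level
  70-30 split (optionally selecting hyperparameters by 10-fold CV) and
  returns an :class:`EmotionMapResults` carrying the trained classifier,
  held-out accuracy and kappa, and prediction/plotting methods.
* :class:`GameAnalysis` — built from game trials plus per-trial emotion
  probabilities (from an EmotionMapResults, the IDW individual profiles,
  or any (n, 20) matrix); ``fit()`` runs the two-stage aggregation and
  returns a :class:`GameAnalysisResults` with rankings, deltas, paired
  tests, optional cluster frequencies, and a summary table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.iolib.table import SimpleTable

from . import classifiers as clf_mod
from . import clustering, games
from .core import TERMS, ClassificationDataset, apply_neutral_exclusion
from .classifiers import DEFAULT_GRIDS, accuracy, cohens_kappa


class EmotionMap:
    """Population-level 2D -> 20-class emotion map, ready to fit."""

    def __init__(self, data: ClassificationDataset, neutral_exclusion: bool = True,
                 exclusion_half_width: float = 50.0):
        if neutral_exclusion:
            self.data, self.excluded = apply_neutral_exclusion(
                data, exclusion_half_width
            )
        else:
            self.data, self.excluded = data, []

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "EmotionMap":
        return cls(ClassificationDataset(df), **kwargs)

    def fit(self, method: str = "nn", config=None, train_fraction: float = 0.70,
            seed: int | None = 0, select: bool = False, grid=None,
            folds: int = 10) -> "EmotionMapResults":
        """Train and evaluate one classifier family.

        With ``select=True`` the config is chosen by participant-level
        10-fold CV over ``grid`` (default grids include the canonical
        values: 27 hidden nodes / decay 0.035, k = 175, C = 0.01).
        """
        train_ds, test_ds = clf_mod.split_train_test(self.data, train_fraction, seed)
        cv_table = None
        if select:
            config, cv_table = clf_mod.cross_validate(
                method, train_ds, grid or DEFAULT_GRIDS[method], folds=folds,
                seed=seed,
            )
        classifier = clf_mod.train(method, train_ds, config)
        pred = classifier.predict_terms(test_ds.to_xy())
        truth = test_ds.df["term"].to_numpy()
        return EmotionMapResults(
            model=self, classifier=classifier, method=method,
            train=train_ds, test=test_ds, seed=seed,
            test_accuracy=accuracy(pred, truth),
            test_kappa=cohens_kappa(pred, truth),
            cv_table=cv_table,
        )

    def fit_clusters(self, k: int = 9, restarts: int = 25,
                     seed: int | None = 0) -> clustering.ClusterModel:
        """k-means partition of the classification points, modal-labeled."""
        model = clustering.fit_kmeans(self.data.to_xy(), k=k, restarts=restarts,
                                      seed=seed)
        return clustering.label_clusters(model, self.data)


class EmotionMapResults:
    """A fitted emotion map: trained classifier plus held-out diagnostics."""

    def __init__(self, model, classifier, method, train, test, seed,
                 test_accuracy, test_kappa, cv_table=None):
        self.model = model
        self.classifier = classifier
        self.method = method
        self.train = train
        self.test = test
        self.seed = seed
        self.test_accuracy = test_accuracy
        self.test_kappa = test_kappa
        self.cv_table = cv_table

    def predict(self, points: np.ndarray) -> pd.DataFrame:
        """Per-point probability of each of the 20 terms (+ argmax term)."""
        probs = self.classifier.predict_proba(points)
        out = pd.DataFrame(probs, columns=list(TERMS))
        out["argmax"] = np.array(TERMS)[np.argmax(probs, axis=1)]
        return out

    def model_view(self, resolution: int = 101) -> np.ndarray:
        return clf_mod.model_view_map(self.classifier, resolution)

    def probability_surface(self, term: str, resolution: int = 101) -> np.ndarray:
        return clf_mod.probability_surface(self.classifier, term, resolution)

    def summary(self) -> SimpleTable:
        null_acc = 1.0 / len(TERMS)
        rows = [
            ("classifier", self.method),
            ("config", str(self.classifier.config)),
            ("participants (retained)", str(self.model.data.n_participants)),
            ("participants excluded", str(len(self.model.excluded))),
            ("train / test participants",
             f"{self.train.n_participants} / {self.test.n_participants}"),
            ("test accuracy", f"{self.test_accuracy:.4f}"),
            ("null accuracy", f"{null_acc:.4f}"),
            ("test kappa", f"{self.test_kappa:.4f}"),
        ]
        return SimpleTable(rows, headers=["", ""], title="EmotionMap results")

    def plot_model_view(self, resolution: int = 101, ax=None):
        """Most-likely-term map over the grid (one color per term)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        view = self.model_view(resolution)
        im = ax.imshow(view, origin="lower", extent=(0, 500, 0, 500),
                       cmap="tab20", vmin=-0.5, vmax=19.5)
        ax.set_xlabel("valence (px)")
        ax.set_ylabel("arousal (px)")
        cbar = ax.figure.colorbar(im, ax=ax, ticks=range(20))
        cbar.ax.set_yticklabels(TERMS)
        return ax


class GameAnalysis:
    """Aggregation analysis of game trials given per-trial probabilities."""

    def __init__(self, trials: pd.DataFrame, probabilities: np.ndarray,
                 cluster_model: clustering.ClusterModel | None = None):
        probabilities = np.asarray(probabilities, dtype=float)
        if len(probabilities) != len(trials):
            raise ValueError("one probability vector per trial is required")
        self.trials = trials.reset_index(drop=True)
        self.probabilities = probabilities
        self.cluster_model = cluster_model
        game = self.trials["game"].unique()
        if len(game) != 1:
            raise ValueError("GameAnalysis expects a single game per table")
        self.game = str(game[0])

    def fit(self) -> "GameAnalysisResults":
        choices = games.binarize(self.trials)
        summary = games.aggregate_likelihoods(
            self.probabilities, self.trials["participant_id"].to_numpy(), choices
        )
        comp, coop = games.COMPETITIVE[self.game], games.COOPERATIVE[self.game]
        deltas = games.emotion_choice_delta(summary, comp, coop)
        rankings = {c: games.rank_emotions(summary, c) for c in summary.choices}
        unfairness = None
        if self.game == "UG":
            unfairness = games.likelihoods_by_unfairness(
                self.trials, self.probabilities, choices
            )
        cluster_freq = None
        if self.cluster_model is not None:
            assign = clustering.assign_clusters(
                self.cluster_model, self.trials[["valence", "arousal"]].to_numpy()
            )
            cluster_freq = clustering.cluster_choice_frequencies(
                assign, choices.to_numpy()
            )
        return GameAnalysisResults(
            analysis=self, choices=choices, likelihoods=summary, deltas=deltas,
            rankings=rankings, unfairness=unfairness, cluster_freq=cluster_freq,
        )


class GameAnalysisResults:
    def __init__(self, analysis, choices, likelihoods, deltas, rankings,
                 unfairness=None, cluster_freq=None):
        self.analysis = analysis
        self.game = analysis.game
        self.choices = choices
        self.likelihoods = likelihoods
        self.deltas = deltas
        self.rankings = rankings
        self.unfairness = unfairness
        self.cluster_freq = cluster_freq

    def paired_test(self, choice: str, term_a: str, term_b: str):
        """Paired t (with d_z) on per-participant likelihoods of two terms."""
        return games.paired_emotion_test(self.likelihoods, choice, term_a, term_b)

    def top_terms(self, choice: str, k: int = 3) -> list[str]:
        return self.rankings[choice]["term"].head(k).tolist()

    def summary(self) -> SimpleTable:
        comp = games.COMPETITIVE[self.game]
        coop = games.COOPERATIVE[self.game]
        rows = []
        for choice in (comp, coop):
            if choice not in self.rankings:
                continue
            top = self.rankings[choice].head(3)
            listing = ", ".join(
                f"{t} ({100 * v:.2f}%)"
                for t, v in zip(top["term"], top["mean_likelihood"])
            )
            n = int(self.likelihoods.n_participants[choice])
            rows.append((f"top emotions | {choice}", listing, str(n)))
        d = self.deltas.sort_values(ascending=False)
        rows.append((f"largest {comp}-{coop} delta",
                     f"{d.index[0]} ({100 * d.iloc[0]:+.2f} pts)", ""))
        return SimpleTable(
            rows, headers=["quantity", "value", "n participants"],
            title=f"GameAnalysis results ({self.game})",
        )

    def plot_deltas(self, ax=None):
        """Per-term competitive-minus-cooperative likelihood differences."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        d = self.deltas.sort_values()
        ax.barh(np.arange(len(d)), d.to_numpy())
        ax.set_yticks(np.arange(len(d)))
        ax.set_yticklabels(d.index)
        comp, coop = games.COMPETITIVE[self.game], games.COOPERATIVE[self.game]
        ax.set_xlabel(f"likelihood({comp}) - likelihood({coop})")
        return ax
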