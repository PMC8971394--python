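"""Label-free k-means partition of affect space.

Nine clusters over the classification-task points form a rough
three-by-three checkered emotion space (low/medium/high valence x
arousal).  Clusters are named by the modal emotion term among their
assigned labeled ratings; game ratings are assigned to their nearest
centroid and compared across choices with 1-df equal-frequency
chi-square tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .core import TERMS, ClassificationDataset, from_model_space, to_model_space

LEVELS = ("low", "med", "high")


@dataclass
class ClusterModel:
    """Fitted k-means partition of the affect grid.

    Centroids are stored in model space; ``centroids_px`` exposes them in
    pixels.  ``labels`` (cluster index -> modal term) and
    ``grid_position`` (cluster index -> (valence level, arousal level))
    are populated by :func:`label_clusters`.
    """

    k: int
    centroids: np.ndarray  # (k, 2) model space
    inertia: float
    seed: int | None = None
    labels: dict[int, str] = field(default_factory=dict)
    grid_position: dict[int, tuple[str, str]] = field(default_factory=dict)
    label_ties: dict[int, list] = field(default_factory=dict)

    @property
    def centroids_px(self) -> np.ndarray:
        return from_model_space(self.centroids)


def fit_kmeans(
    points: np.ndarray, k: int = 9, restarts: int = 25, seed: int | None = 0
) -> ClusterModel:
    """Lloyd's algorithm, best of ``restarts`` k-means++ initializations.

    ``points`` are pixel coordinates (typically the classification-task
    ratings); the fit runs in model space.  Deterministic given the seed.
    """
    X = to_model_space(np.asarray(points, dtype=float))
    if len(np.unique(X, axis=0)) < k:
        raise ValueError(f"need at least {k} distinct points")
    km = KMeans(n_clusters=k, init="k-means++", n_init=restarts,
                algorithm="lloyd", tol=1e-10, random_state=seed)
    km.fit(X)
    return ClusterModel(k=k, centroids=km.cluster_centers_.copy(),
                        inertia=float(km.inertia_), seed=seed)


def assign_clusters(model: ClusterModel, points: np.ndarray) -> np.ndarray:
    """Nearest-centroid index per point (Euclidean, model space).

    Equidistant points go to the lowest cluster index.
    """
    X = to_model_space(np.asarray(points, dtype=float))
    d2 = ((X[:, None, :] - model.centroids[None, :, :]) ** 2).sum(axis=-1)
    return np.argmin(d2, axis=1)


def _tertiles(values: np.ndarray) -> dict[int, str]:
    """Rank 9 centroid coordinates into low/med/high thirds."""
    order = np.argsort(values, kind="stable")
    out = {}
    third = len(values) // 3
    for rank, idx in enumerate(order):
        out[int(idx)] = LEVELS[min(rank // third, 2)]
    return out


def label_clusters(model: ClusterModel, dataset: ClassificationDataset) -> ClusterModel:
    """Name each cluster by its modal term and place it on the 3x3 grid.

    Modal ties break by canonical term order and are flagged in
    ``model.label_ties``.  Grid positions come from ranking centroid
    valence/arousal into tertiles (only meaningful for k = 9).
    """
    assign = assign_clusters(model, dataset.to_xy())
    terms = dataset.df["term"].to_numpy()
    for c in range(model.k):
        members = terms[assign == c]
        if members.size == 0:
            model.labels[c] = ""
            continue
        counts = pd.Series(members).value_counts()
        top = counts.max()
        tied = sorted(counts.index[counts == top], key=TERMS.index)
        model.labels[c] = tied[0]
        if len(tied) > 1:
            model.label_ties[c] = tied
    if model.k == 9:
        v_levels = _tertiles(model.centroids[:, 0])
        a_levels = _tertiles(model.centroids[:, 1])
        model.grid_position = {c: (v_levels[c], a_levels[c]) for c in range(9)}
    return model


def cluster_choice_frequencies(
    assignments: np.ndarray, choices: np.ndarray
) -> pd.DataFrame:
    """Cluster x choice contingency with within-choice base rates.

    Returns a tidy frame (cluster, choice, count, proportion) where the
    proportion is the share of all trials with that choice falling in
    that cluster (proportions within each choice sum to 1).
    """
    assignments = np.asarray(assignments)
    choices = np.asarray(choices)
    if assignments.shape != choices.shape:
        raise ValueError("length mismatch between assignments and choices")
    df = pd.DataFrame({"cluster": assignments, "choice": choices})
    counts = df.value_counts(["choice", "cluster"]).rename("count").reset_index()
    counts["proportion"] = counts.groupby("choice")["count"].transform(
        lambda s: s / s.sum()
    )
    return counts.sort_values(["choice", "cluster"]).reset_index(drop=True)


def chi_square_two_clusters(count_a: int, count_b: int) -> tuple[float, int, float]:
    """1-df goodness-of-fit of two cluster counts against equal frequency.

    chi2 = (a - n/2)^2 / (n/2) + (b - n/2)^2 / (n/2) with n = a + b.
    """
    if count_a + count_b <= 0:
        raise ValueError("both counts are zero")
    stat, p = stats.chisquare([count_a, count_b])
    return float(stat), 1, float(p)
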