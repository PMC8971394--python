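"""JSON (de)serialization of trained models.

Everything is stored as plain JSON so trained artifacts are diffable and
portable: the NN stores its weight matrices (predictions are replayed by
direct matrix arithmetic on load), the kNN stores its training points,
and the SVM stores its training points plus hyperparameters and refits
deterministically on load.  Cluster models store centroids and labels.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
from sklearn.svm import SVC

from .classifiers import (
    KNNClassifier, KNNConfig, NNClassifier, NNConfig, SVMClassifier,
    SVMConfig, TrainedClassifier,
)
from .clustering import ClusterModel


def model_to_dict(model: TrainedClassifier) -> dict:
    base = {"family": model.family, "metadata": model.metadata,
            "config": asdict(model.config)}
    if isinstance(model, NNClassifier):
        base["weights"] = {
            "coefs": [w.tolist() for w in model.coefs],
            "intercepts": [b.tolist() for b in model.intercepts],
            "classes": model._classes.tolist(),
        }
    elif isinstance(model, KNNClassifier):
        base["train"] = {"X_model": model.X_model.tolist(), "y": model.y.tolist()}
    elif isinstance(model, SVMClassifier):
        if model.X_model is None:
            raise ValueError("SVM model lacks its training set; cannot serialize")
        base["train"] = {
            "X_model": model.X_model.tolist(),
            "y": model.y.tolist(),
            "gamma": model.metadata["gamma"],
        }
    else:
        raise TypeError(f"cannot serialize {type(model).__name__}")
    return base


def model_from_dict(data: dict) -> TrainedClassifier:
    family = data["family"]
    if family == "nn":
        cfg = NNConfig(**data["config"])
        w = data["weights"]
        clf = NNClassifier.__new__(NNClassifier)
        TrainedClassifier.__init__(clf, cfg, data.get("metadata"))
        clf.coefs = [np.asarray(m, dtype=float) for m in w["coefs"]]
        clf.intercepts = [np.asarray(b, dtype=float) for b in w["intercepts"]]
        clf._classes = np.asarray(w["classes"], dtype=int)
        return clf
    if family == "knn":
        cfg = KNNConfig(**data["config"])
        t = data["train"]
        return KNNClassifier(cfg, np.asarray(t["X_model"]), np.asarray(t["y"]),
                             metadata=data.get("metadata"))
    if family == "svm":
        cfg = SVMConfig(**data["config"])
        t = data["train"]
        X = np.asarray(t["X_model"], dtype=float)
        y = np.asarray(t["y"], dtype=int)
        svc = SVC(C=cfg.cost, kernel="rbf", gamma=t["gamma"],
                  decision_function_shape="ovo")
        svc.fit(X, y)
        return SVMClassifier(cfg, svc, X_model=X, y=y, metadata=data.get("metadata"))
    raise ValueError(f"unknown model family {family!r}")


def save_model(model: TrainedClassifier, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model)))


def load_model(path: str | Path) -> TrainedClassifier:
    return model_from_dict(json.loads(Path(path).read_text()))


def save_cluster_model(model: ClusterModel, path: str | Path) -> None:
    data = {
        "k": model.k,
        "centroids": model.centroids.tolist(),
        "inertia": model.inertia,
        "seed": model.seed,
        "labels": {str(k): v for k, v in model.labels.items()},
        "grid_position": {str(k): list(v) for k, v in model.grid_position.items()},
    }
    Path(path).write_text(json.dumps(data))


def load_cluster_model(path: str | Path) -> ClusterModel:
    d = json.loads(Path(path).read_text())
    return ClusterModel(
        k=d["k"], centroids=np.asarray(d["centroids"], dtype=float),
        inertia=d["inertia"], seed=d["seed"],
        labels={int(k): v for k, v in d["labels"].items()},
        grid_position={int(k): tuple(v) for k, v in d["grid_position"].items()},
    )
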