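"""Individual-level emotion classification by inverse-distance weighting.

Each participant's own 20 term placements act as their personal emotion
lexicon; an unlabeled affect rating is scored against it with
P(term j) = (1 / d_j) / sum_m (1 / d_m), d_j the Euclidean pixel
distance to term j's placement.  This is the individual-level mirror of
the population classifiers: a participant who places "angry" low on
arousal gets credit for their idiosyncratic quiet anger.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import TERMS, ClassificationDataset, validate_points


@dataclass(frozen=True)
class ParticipantLexicon:
    """One participant's 20 term placements, rows in canonical term order."""

    participant_id: object
    coordinates: np.ndarray  # (20, 2) pixels

    def __post_init__(self):
        if self.coordinates.shape != (len(TERMS), 2):
            raise ValueError("lexicon must hold all 20 term coordinates")


def build_lexicons(dataset: ClassificationDataset) -> dict:
    """Per-participant lexicons from a (balanced) classification dataset."""
    out = {}
    for pid, grp in dataset.df.groupby("participant_id"):
        if set(grp["term"]) != set(TERMS):
            raise ValueError(f"participant {pid!r} lexicon is incomplete")
        coords = (
            grp.set_index("term").loc[list(TERMS), ["valence", "arousal"]]
            .to_numpy(dtype=float)
        )
        out[pid] = ParticipantLexicon(pid, coords)
    return out


def idw_weights(point, coordinates: np.ndarray) -> np.ndarray:
    """Inverse-distance weights of one point against reference coordinates.

    P(j) = (1 / d_j) / sum_m (1 / d_m) with d_j the Euclidean pixel
    distance to row j.  If the point coincides with one or more reference
    rows (zero distance), the limiting measure puts all mass equally on
    the zero-distance rows.  Works for any number of reference terms.
    """
    xy = validate_points(point)[0]
    d = np.linalg.norm(np.asarray(coordinates, dtype=float) - xy, axis=1)
    zero = d == 0.0
    if zero.any():
        return zero / zero.sum()
    inv = 1.0 / d
    return inv / inv.sum()


def idw_probabilities(point, lexicon: ParticipantLexicon) -> np.ndarray:
    """Inverse-distance-weighted 20-term probability vector for one point."""
    return idw_weights(point, lexicon.coordinates)


def individual_classify(trials: pd.DataFrame, lexicons: dict) -> np.ndarray:
    """(n_trials, 20) IDW probability matrix, each trial against its own
    participant's lexicon."""
    unknown = set(trials["participant_id"]) - set(lexicons)
    if unknown:
        raise KeyError(f"trials from participants with no lexicon: {sorted(unknown)[:5]}")
    pts = trials[["valence", "arousal"]].to_numpy(dtype=float)
    out = np.empty((len(trials), len(TERMS)))
    pids = trials["participant_id"].to_numpy()
    for i in range(len(trials)):
        out[i] = idw_probabilities(pts[i], lexicons[pids[i]])
    return out
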