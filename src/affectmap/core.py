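"""Core domain types and grid conventions for the affect-grid analyses.

The affect grid is a 500 x 500 pixel square.  The horizontal axis is
valence (pleasantness, increasing rightward) and the vertical axis is
arousal (activation, increasing upward); coordinates are stored
mathematically y-up.  Labeled data come from an emotion classification
task in which each participant places each of 20 canonical emotion terms
at one grid location; unlabeled data are affect ratings made during
economic games.

This module owns the canonical term lexicon, point validation, the
neutral-rating participant exclusion, model-space scaling, and CSV I/O
for both the classification and game tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
import yaml

GRID_MIN = 0.0
GRID_MAX = 500.0
GRID_CENTER = (250.0, 250.0)

#: The 20 canonical emotion terms, in canonical order.  This order is the
#: column order of every probability vector produced by the package.
TERMS: tuple[str, ...] = (
    "neutral", "surprised", "aroused", "peppy", "enthusiastic",
    "happy", "satisfied", "relaxed", "calm", "sleepy",
    "still", "quiet", "sluggish", "sad", "disappointed",
    "disgusted", "annoyed", "angry", "afraid", "nervous",
)

TERM_INDEX: dict[str, int] = {t: i for i, t in enumerate(TERMS)}

#: Games supported by the pipeline.
GAMES = ("UG", "PD", "PGG")


class AffectPoint(NamedTuple):
    """A (valence, arousal) location on the 500 x 500 grid, in pixels."""

    valence: float
    arousal: float


class PointValidationError(ValueError):
    """An affect-grid coordinate is non-finite or outside [0, 500]."""


class DataIntegrityError(ValueError):
    """A dataset violates a structural invariant (balance, duplicates...)."""


def validate_point(point) -> AffectPoint:
    """Validate a single affect-grid point; bounds are inclusive.

    Raises :class:`PointValidationError` naming the offending coordinate.
    """
    v, a = float(point[0]), float(point[1])
    for name, x in (("valence", v), ("arousal", a)):
        if not np.isfinite(x):
            raise PointValidationError(f"{name} coordinate is not finite: {x!r}")
        if not (GRID_MIN <= x <= GRID_MAX):
            raise PointValidationError(
                f"{name} coordinate {x} outside the [{GRID_MIN:g}, {GRID_MAX:g}] grid"
            )
    return AffectPoint(v, a)


def validate_points(xy: np.ndarray) -> np.ndarray:
    """Vectorized bounds check for an (n, 2) array of grid points."""
    xy = np.asarray(xy, dtype=float)
    if xy.ndim == 1:
        xy = xy[None, :]
    if xy.shape[-1] != 2:
        raise PointValidationError("expected points with two coordinates (valence, arousal)")
    if xy.size == 0:
        return xy
    if not np.all(np.isfinite(xy)):
        raise PointValidationError("non-finite coordinate in points array")
    if xy.min() < GRID_MIN or xy.max() > GRID_MAX:
        bad = xy[np.any((xy < GRID_MIN) | (xy > GRID_MAX), axis=1)][0]
        raise PointValidationError(f"point {tuple(bad)} outside the affect grid")
    return xy


def to_model_space(xy: np.ndarray) -> np.ndarray:
    """Affine map from pixel space [0, 500]^2 to model space [-1, 1]^2.

    x -> (x - 250) / 250 per axis.  All classifiers are fitted in model
    space so that scale-sensitive hyperparameters (NN weight decay, SVM
    cost) have a declared, reproducible meaning.
    """
    return (np.asarray(xy, dtype=float) - 250.0) / 250.0


def from_model_space(uv: np.ndarray) -> np.ndarray:
    """Inverse of :func:`to_model_space`."""
    return np.asarray(uv, dtype=float) * 250.0 + 250.0


@dataclass(frozen=True)
class GridConfig:
    """Run configuration: exclusion bounds, coordinate flip, RNG seed.

    ``neutral_half_width`` is half the side of the square around the grid
    center inside which a participant's "neutral" rating must fall (the
    pre-registered exclusion used a 100 x 100 px square, i.e. half-width
    50).  ``flip_screen_y`` converts externally collected screen
    coordinates (y-down) to the package's y-up arousal convention.
    """

    neutral_half_width: float = 50.0
    flip_screen_y: bool = False
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "GridConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls(**(data or {}))


class ClassificationDataset:
    """Emotion-classification-task ratings: one row per (participant, term).

    Wraps a DataFrame with columns ``participant_id, term, valence,
    arousal``.  The dataset is balanced by construction: every participant
    contributes exactly one rating for each of the 20 canonical terms.
    """

    COLUMNS = ("participant_id", "term", "valence", "arousal")

    def __init__(self, df: pd.DataFrame, require_balanced: bool = True):
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise DataIntegrityError(f"missing columns: {missing}")
        df = df.loc[:, list(self.COLUMNS)].reset_index(drop=True)
        unknown = set(df["term"]) - set(TERMS)
        if unknown:
            raise DataIntegrityError(f"unknown emotion terms: {sorted(unknown)}")
        dup = df.duplicated(subset=["participant_id", "term"])
        if dup.any():
            pair = df.loc[dup.idxmax(), ["participant_id", "term"]].tolist()
            raise DataIntegrityError(f"duplicate (participant, term) rating: {pair}")
        validate_points(df[["valence", "arousal"]].to_numpy())
        if require_balanced:
            counts = df.groupby("participant_id")["term"].count()
            if not (counts == len(TERMS)).all():
                bad = counts.index[counts != len(TERMS)][0]
                raise DataIntegrityError(
                    f"participant {bad!r} has {counts[bad]} ratings, expected {len(TERMS)}"
                )
        self.df = df

    @property
    def participants(self) -> list:
        return sorted(self.df["participant_id"].unique().tolist())

    @property
    def n_participants(self) -> int:
        return self.df["participant_id"].nunique()

    def __len__(self) -> int:
        return len(self.df)

    def subset(self, participants: Iterable) -> "ClassificationDataset":
        keep = set(participants)
        return ClassificationDataset(
            self.df[self.df["participant_id"].isin(keep)].copy(), require_balanced=False
        )

    def to_xy(self) -> np.ndarray:
        """(n, 2) pixel coordinates, row order of the underlying frame."""
        return self.df[["valence", "arousal"]].to_numpy(dtype=float)

    def labels(self) -> np.ndarray:
        """Integer class labels aligned with :data:`TERMS`."""
        return self.df["term"].map(TERM_INDEX).to_numpy()

    def __eq__(self, other) -> bool:
        if not isinstance(other, ClassificationDataset):
            return NotImplemented
        a = self.df.sort_values(["participant_id", "term"]).reset_index(drop=True)
        b = other.df.sort_values(["participant_id", "term"]).reset_index(drop=True)
        if len(a) != len(b):
            return False
        return all(bool((a[c].to_numpy() == b[c].to_numpy()).all())
                   for c in self.COLUMNS)


def apply_neutral_exclusion(
    dataset: ClassificationDataset, half_width: float = 50.0
) -> tuple[ClassificationDataset, list]:
    """Drop participants whose "neutral" rating is off-center.

    A participant is retained iff their neutral rating lies inside the
    axis-aligned square of side ``2 * half_width`` centered at (250, 250),
    bounds inclusive (valence and arousal in [250 - hw, 250 + hw]).  All
    rows of excluded participants are dropped; callers are responsible for
    dropping those participants' game trials downstream.

    Returns ``(retained_dataset, excluded_participant_ids)``.  Idempotent:
    re-applying to the retained dataset excludes nobody further.
    """
    df = dataset.df
    neutral = df[df["term"] == "neutral"].set_index("participant_id")
    missing = set(df["participant_id"].unique()) - set(neutral.index)
    if missing:
        raise DataIntegrityError(
            f"participants with no 'neutral' rating: {sorted(missing)[:5]}"
        )
    lo, hi = 250.0 - half_width, 250.0 + half_width
    ok = (
        neutral["valence"].between(lo, hi, inclusive="both")
        & neutral["arousal"].between(lo, hi, inclusive="both")
    )
    retained_ids = set(ok.index[ok])
    excluded = sorted(ok.index[~ok].tolist())
    retained = ClassificationDataset(
        df[df["participant_id"].isin(retained_ids)].copy(), require_balanced=False
    )
    return retained, excluded


# ---------------------------------------------------------------------------
# CSV I/O


class ParseError(ValueError):
    """A CSV row could not be parsed; the message carries the line number."""


def read_classification_csv(
    path: str | Path, flip_screen_y: bool = False, require_balanced: bool = True
) -> ClassificationDataset:
    """Read a classification table (participant_id,term,valence,arousal).

    ``flip_screen_y=True`` converts screen y-down coordinates into the
    package's y-up arousal convention (a = 500 - y).
    """
    df = pd.read_csv(path, dtype={"participant_id": str, "term": str},
                     float_precision="round_trip")
    missing = [c for c in ClassificationDataset.COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    for col in ("valence", "arousal"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            # +2: header line plus 1-based indexing
            line = int(vals.index[vals.isna()][0]) + 2
            raise ParseError(f"{path}: malformed {col} value at line {line}")
        df[col] = vals
    bad_term = ~df["term"].isin(TERMS)
    if bad_term.any():
        i = int(bad_term.idxmax())
        raise ParseError(
            f"{path}: unknown term {df.loc[i, 'term']!r} at line {i + 2}"
        )
    if flip_screen_y:
        df["arousal"] = GRID_MAX - df["arousal"]
    return ClassificationDataset(df, require_balanced=require_balanced)


def write_classification_csv(dataset: ClassificationDataset, path: str | Path) -> None:
    # %.17g keeps the float round-trip exact
    dataset.df.to_csv(path, index=False, float_format="%.17g")


GAME_COLUMNS = (
    "participant_id", "trial", "game", "role", "partner_action",
    "valence", "arousal", "response",
)


def read_game_csv(path: str | Path, flip_screen_y: bool = False) -> pd.DataFrame:
    """Read a game-trial table; schema in :data:`GAME_COLUMNS`.

    ``response`` is 'accept'/'reject' for UG rows and a dollar
    contribution for PD/PGG rows; it is kept as an object column.
    """
    df = pd.read_csv(path, dtype={"participant_id": str, "response": str},
                     float_precision="round_trip")
    missing = [c for c in GAME_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    bad_game = ~df["game"].isin(GAMES)
    if bad_game.any():
        i = int(bad_game.idxmax())
        raise ParseError(f"{path}: unknown game {df.loc[i, 'game']!r} at line {i + 2}")
    for col in ("valence", "arousal", "partner_action"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            line = int(vals.index[vals.isna()][0]) + 2
            raise ParseError(f"{path}: malformed {col} value at line {line}")
        df[col] = vals
    if flip_screen_y:
        df["arousal"] = GRID_MAX - df["arousal"]
    validate_points(df[["valence", "arousal"]].to_numpy())
    return df


def write_game_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format="%.17g")
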