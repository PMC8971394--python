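"""Game-trial semantics and the likelihood-aggregation analyses.

The pipeline: binarize each trial's response into the competitive vs
cooperative choice (reject -> punish in the UG; own contribution below
$0.50 -> defect in PD/PGG), then average the per-trial 20-term
probability vectors in two stages — within participant for each choice,
then unweighted across participants — so heavy raters do not dominate.
On top of that sit the per-term punish-minus-accept deltas, unfairness
gradients, rankings, and paired t tests with the d_z effect size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import TERMS

COMPETITIVE = {"UG": "punish", "PD": "defect", "PGG": "defect"}
COOPERATIVE = {"UG": "accept", "PD": "cooperate", "PGG": "cooperate"}


def binarize(trials: pd.DataFrame) -> pd.Series:
    """Binary choice label per trial.

    UG: reject -> ``punish``, accept -> ``accept``.  PD/PGG: own
    contribution in [$0, $0.49] -> ``defect``, [$0.50, $1] ->
    ``cooperate`` (responses live on the $0.10 lattice).
    """
    out = pd.Series(index=trials.index, dtype=object)
    ug = trials["game"] == "UG"
    if ug.any():
        resp = trials.loc[ug, "response"].astype(str)
        bad = ~resp.isin(("accept", "reject"))
        if bad.any():
            raise ValueError(f"UG response not accept/reject: {resp[bad].iloc[0]!r}")
        out[ug] = np.where(resp == "reject", "punish", "accept")
    if (~ug).any():
        contrib = pd.to_numeric(trials.loc[~ug, "response"])
        if contrib.min() < 0 or contrib.max() > 1:
            raise ValueError("PD/PGG contribution outside [0, 1]")
        out[~ug] = np.where(contrib < 0.5, "defect", "cooperate")
    return out


@dataclass
class EmotionLikelihoodSummary:
    """Two-stage mean emotion likelihoods per choice.

    ``means`` is a (choice x term) frame of across-participant means;
    ``ci_low``/``ci_high`` the normal-approximation 95% CI bounds;
    ``n_participants`` the stage-2 participant count per choice;
    ``participant_means`` the stage-1 frame (participant, choice, 20 term
    columns) kept for paired tests.
    """

    means: pd.DataFrame
    ci_low: pd.DataFrame
    ci_high: pd.DataFrame
    n_participants: pd.Series
    participant_means: pd.DataFrame

    @property
    def choices(self) -> list:
        return self.means.index.tolist()


def aggregate_likelihoods(
    probs: np.ndarray, participants, choices
) -> EmotionLikelihoodSummary:
    """Within-participant then across-participant likelihood averaging.

    Stage 1: per (participant, choice), the arithmetic mean vector over
    that participant's trials with that choice.  Stage 2: per choice, the
    unweighted mean over participants contributing at least one such
    trial, with CI = mean +/- 1.96 * SE across participants.  Both stages
    preserve normalization, so each choice's 20 means sum to 1.
    """
    probs = np.asarray(probs, dtype=float)
    frame = pd.DataFrame(probs, columns=list(TERMS))
    frame["participant_id"] = np.asarray(participants)
    frame["choice"] = np.asarray(choices)
    if len(frame) == 0:
        raise ValueError("no trials to aggregate")
    stage1 = (
        frame.groupby(["participant_id", "choice"], sort=True)[list(TERMS)]
        .mean()
        .reset_index()
    )
    g = stage1.groupby("choice")[list(TERMS)]
    means = g.mean()
    n = g.size()
    se = g.std(ddof=1).div(np.sqrt(n), axis=0).fillna(0.0)
    return EmotionLikelihoodSummary(
        means=means,
        ci_low=means - 1.96 * se,
        ci_high=means + 1.96 * se,
        n_participants=n,
        participant_means=stage1,
    )


def emotion_choice_delta(
    summary: EmotionLikelihoodSummary, competitive: str, cooperative: str
) -> pd.Series:
    """Per-term likelihood(competitive) - likelihood(cooperative).

    Positive values mark emotions more associated with punishing /
    defecting; the 20 deltas sum to 0 because each side sums to 1.
    """
    for c in (competitive, cooperative):
        if c not in summary.means.index:
            raise ValueError(f"choice {c!r} absent from summary")
    return summary.means.loc[competitive] - summary.means.loc[cooperative]


def likelihoods_by_unfairness(
    trials: pd.DataFrame, probs: np.ndarray, choices=None
) -> pd.DataFrame:
    """Two-stage mean vectors per (choice, unfairness level) for UG trials.

    The unfairness level is the amount kept by the Proposer
    (``partner_action``).  Levels or choices with no trials are simply
    absent from the output.  Returns a frame indexed by (choice, level)
    whose 20 term columns each sum to 1 per row.
    """
    if choices is None:
        choices = binarize(trials)
    frame = pd.DataFrame(np.asarray(probs, dtype=float), columns=list(TERMS))
    frame["participant_id"] = trials["participant_id"].to_numpy()
    frame["choice"] = np.asarray(choices)
    frame["level"] = np.round(trials["partner_action"].to_numpy(dtype=float), 2)
    stage1 = (
        frame.groupby(["participant_id", "choice", "level"], sort=True)[list(TERMS)]
        .mean()
        .reset_index()
    )
    return stage1.groupby(["choice", "level"])[list(TERMS)].mean()


def rank_emotions(summary: EmotionLikelihoodSummary, choice: str) -> pd.DataFrame:
    """Terms ordered by descending mean likelihood for one choice.

    Exact ties keep canonical term order and are flagged in a ``tied``
    column.
    """
    if choice not in summary.means.index:
        raise ValueError(f"choice {choice!r} absent from summary")
    s = summary.means.loc[choice]
    order = sorted(TERMS, key=lambda t: (-s[t], TERMS.index(t)))
    out = pd.DataFrame({
        "term": order,
        "mean_likelihood": [s[t] for t in order],
    })
    out["rank"] = np.arange(1, len(order) + 1)
    out["tied"] = out["mean_likelihood"].duplicated(keep=False)
    return out


def paired_t_cohens_d(x, y) -> tuple[float, int, float, float]:
    """Classical paired t test with the d_z effect size.

    Returns (t, df, p, d) with d = mean(diff) / sd(diff), so t = d * sqrt(n)
    exactly.  Zero-variance differences with nonzero mean give infinite t
    (p = 0); all-zero differences give t = 0, d = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must be aligned")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    diff = x - y
    m = diff.mean()
    sd = diff.std(ddof=1)
    df = n - 1
    if sd == 0.0:
        if m == 0.0:
            return 0.0, df, 1.0, 0.0
        sign = float(np.sign(m))
        return sign * np.inf, df, 0.0, sign * np.inf
    t = m / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), df, float(p), float(m / sd)


def paired_emotion_test(
    summary: EmotionLikelihoodSummary, choice: str, term_a: str, term_b: str
) -> tuple[float, int, float, float]:
    """Paired t on per-participant likelihoods of two terms for one choice."""
    s1 = summary.participant_means
    rows = s1[s1["choice"] == choice]
    return paired_t_cohens_d(rows[term_a].to_numpy(), rows[term_b].to_numpy())


def continuous_choice_association(
    trials: pd.DataFrame, probs: np.ndarray
) -> pd.DataFrame:
    """Rank terms by association between likelihood and non-contribution.

    Approximation of the continuous-choice analysis: per participant, the
    covariance across trials between each term's likelihood and
    (1 - own contribution); participants with constant contributions are
    excluded from the across-participant mean.  Returns a frame sorted by
    descending mean association (terms whose likelihood rises as
    contributions fall come first).
    """
    contrib = pd.to_numeric(trials["response"]).to_numpy(dtype=float)
    frame = pd.DataFrame(np.asarray(probs, dtype=float), columns=list(TERMS))
    frame["participant_id"] = trials["participant_id"].to_numpy()
    frame["anti"] = 1.0 - contrib
    per_part = []
    for pid, grp in frame.groupby("participant_id"):
        if grp["anti"].nunique() < 2:
            continue  # constant contribution: association undefined
        a = grp["anti"] - grp["anti"].mean()
        cov = grp[list(TERMS)].sub(grp[list(TERMS)].mean()).mul(a, axis=0).mean()
        per_part.append(cov)
    if not per_part:
        raise ValueError("no participant with varying contributions")
    assoc = pd.concat(per_part, axis=1).T.mean()
    out = assoc.sort_values(ascending=False).rename("mean_association").reset_index()
    out.columns = ["term", "mean_association"]
    out["rank"] = np.arange(1, len(out) + 1)
    return out
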