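"""Synthetic classification-task and game-trial data.

The generator emulates the statistical structure the analyses assume:

* each of the 20 emotion terms is a 1- or 2-component Gaussian mixture
  over the 500 x 500 grid (2 components encode population heterogeneity,
  e.g. the "quiet anger" sub-cluster of *angry*), truncated to the grid
  by rejection sampling;
* game trials carry a partner action (offer kept, or contribution), an
  affect rating whose mean valence worsens linearly with how badly the
  partner behaved, and a choice driven by a logistic model on valence —
  the unfairness -> negative valence -> punishment chain.

Everything is deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    GRID_MAX, GRID_MIN, TERMS, ClassificationDataset, to_model_space,
)

__all__ = [
    "TermGenerator", "GameScenario", "default_lexicon",
    "well_separated_lexicon", "generate_classification", "generate_game",
    "payoff", "bayes_accuracy", "mixture_mean", "lexicon_density",
]


@dataclass(frozen=True)
class TermGenerator:
    """Truncated Gaussian mixture for one emotion term.

    ``components`` is a sequence of (weight, mean_valence, mean_arousal,
    sd_valence, sd_arousal) in pixels; weights sum to 1.
    """

    term: str
    components: tuple[tuple[float, float, float, float, float], ...]

    def __post_init__(self):
        w = np.array([c[0] for c in self.components])
        if not (1 <= len(self.components) <= 2):
            raise ValueError("1-2 components per term")
        if np.any(w <= 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("component weights must be positive and sum to 1")
        if any(c[3] <= 0 or c[4] <= 0 for c in self.components):
            raise ValueError("component sds must be positive")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n in-bounds points (rejection sampling, no edge clipping)."""
        weights = np.array([c[0] for c in self.components])
        out = np.empty((n, 2))
        todo = np.arange(n)
        comp = rng.choice(len(self.components), size=n, p=weights)
        while todo.size:
            params = np.array(
                [self.components[c][1:] for c in comp[todo]]
            )  # (m, 4): mv, ma, sv, sa
            draw = params[:, :2] + rng.standard_normal((todo.size, 2)) * params[:, 2:]
            ok = np.all((draw >= GRID_MIN) & (draw <= GRID_MAX), axis=1)
            out[todo[ok]] = draw[ok]
            todo = todo[~ok]
        return out


def _axis_truncation_mass(mean: float, sd: float) -> float:
    return stats.norm.cdf(GRID_MAX, mean, sd) - stats.norm.cdf(GRID_MIN, mean, sd)


def mixture_mean(gen: TermGenerator) -> tuple[float, float]:
    """Analytic mean of the grid-truncated mixture (per-axis truncnorm)."""
    means = np.zeros(2)
    # Rejection sampling truncates to the square; because the kernel is a
    # product of independent normals, the truncated density factorizes and
    # each axis mean is a 1-D truncated-normal mean.
    total_w = 0.0
    for w, mv, ma, sv, sa in gen.components:
        # component weight after truncation renormalization across components
        mass = _axis_truncation_mass(mv, sv) * _axis_truncation_mass(ma, sa)
        tw = w * mass
        tm_v = stats.truncnorm.mean((GRID_MIN - mv) / sv, (GRID_MAX - mv) / sv, mv, sv)
        tm_a = stats.truncnorm.mean((GRID_MIN - ma) / sa, (GRID_MAX - ma) / sa, ma, sa)
        means += tw * np.array([tm_v, tm_a])
        total_w += tw
    return tuple(means / total_w)


def default_lexicon() -> dict[str, TermGenerator]:
    """Default per-term generators placing each term in its circumplex octant.

    Means/sds are declared fixture constants (pixels), not estimates of any
    real cohort.  Notable structure: *angry* has a dominant high-arousal
    negative-valence component plus a minor neutrally-arousing "quiet
    anger" component; *disappointed* is a single negative-valence
    component that is very wide along arousal; *neutral* is tight at the
    grid center.
    """
    spec: dict[str, tuple] = {
        "neutral":      ((1.0, 250, 250, 16, 16),),
        "surprised":    ((1.0, 280, 415, 45, 35),),
        "aroused":      ((1.0, 315, 430, 45, 32),),
        "peppy":        ((1.0, 375, 395, 40, 35),),
        "enthusiastic": ((1.0, 400, 365, 40, 35),),
        "happy":        ((1.0, 420, 325, 40, 40),),
        "satisfied":    ((1.0, 420, 265, 40, 35),),
        "relaxed":      ((1.0, 400, 180, 40, 40),),
        "calm":         ((1.0, 375, 160, 40, 40),),
        "sleepy":       ((1.0, 280, 90, 45, 35),),
        "still":        ((1.0, 295, 135, 45, 40),),
        "quiet":        ((1.0, 260, 145, 45, 40),),
        "sluggish":     ((1.0, 200, 110, 45, 40),),
        "sad":          ((1.0, 95, 150, 40, 40),),
        "disappointed": ((1.0, 115, 245, 38, 75),),
        "disgusted":    ((1.0, 85, 320, 40, 42),),
        "annoyed":      ((1.0, 130, 345, 40, 40),),
        "angry":        ((0.75, 80, 420, 35, 35), (0.25, 90, 250, 35, 35)),
        "afraid":       ((1.0, 120, 400, 40, 40),),
        "nervous":      ((1.0, 165, 385, 45, 40),),
    }
    return {t: TermGenerator(t, spec[t]) for t in TERMS}


def well_separated_lexicon(sd: float = 12.0) -> dict[str, TermGenerator]:
    """Single-component, tightly clustered generators on a 5 x 4 lattice.

    A near-separable layout (pairwise mean separation >= ~95 px against a
    small sd) for which the Bayes accuracy of the generating mixture is
    close to 1 — used for classifier parameter-recovery checks.
    """
    vals = [60.0, 155.0, 250.0, 345.0, 440.0]
    arss = [70.0, 190.0, 310.0, 430.0]
    lex = {}
    for i, t in enumerate(TERMS):
        mv, ma = vals[i % 5], arss[i // 5]
        lex[t] = TermGenerator(t, ((1.0, mv, ma, sd, sd),))
    return lex


def generate_classification(
    lexicon: Mapping[str, TermGenerator], n_participants: int, seed: int | None = 0
) -> ClassificationDataset:
    """One draw per participant per term from that term's truncated mixture."""
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    if set(lexicon) != set(TERMS):
        raise ValueError("lexicon must cover exactly the 20 canonical terms")
    rng = np.random.default_rng(seed)
    frames = []
    pids = [f"P{i:05d}" for i in range(n_participants)]
    for term in TERMS:
        pts = lexicon[term].sample(n_participants, rng)
        frames.append(pd.DataFrame({
            "participant_id": pids,
            "term": term,
            "valence": pts[:, 0],
            "arousal": pts[:, 1],
        }))
    df = pd.concat(frames, ignore_index=True)
    df = df.sort_values(["participant_id", "term"], kind="stable").reset_index(drop=True)
    return ClassificationDataset(df)


# ---------------------------------------------------------------------------
# Games


def _even_schedule(levels: np.ndarray, reps: int) -> np.ndarray:
    return np.repeat(levels, reps)


@dataclass(frozen=True)
class GameScenario:
    """Design + generative parameters for one economic-game simulation.

    ``schedule`` holds the per-round partner actions (UG: dollars kept by
    the Proposer; PD: partner contribution; PGG: collective contribution
    of the three partners).  The affect model maps a badness score
    s in [0, 1] (0 = best partner behaviour, 1 = worst) linearly onto mean
    valence/arousal with isotropic Gaussian pixel noise.  The choice model
    is logistic on model-space valence v in [-1, 1]: for the UG,
    P(reject) = logistic(choice_intercept + choice_slope * v); for PD/PGG
    the participant's own contribution is the deterministic monotone map
    round(10 * logistic(contrib_intercept + contrib_slope * v)) / 10.
    """

    game: str
    n_participants: int
    schedule: tuple[float, ...]
    valence_best: float = 350.0
    valence_worst: float = 80.0
    arousal_best: float = 250.0
    arousal_worst: float = 330.0
    noise_sd: float = 55.0
    choice_intercept: float = -0.8
    choice_slope: float = -5.0
    contrib_intercept: float = 0.0
    contrib_slope: float = 3.0
    #: Optional planted-emotion mode: map from choice label to a term whose
    #: generator supplies the trial affect (recorded for recovery tests).
    planted: Mapping[str, str] | None = None

    @classmethod
    def ultimatum(cls, n_participants: int = 100, **kw) -> "GameScenario":
        # 20 one-shot rounds: 10 kept-amount levels $0.50..$0.95 x 2 each.
        levels = np.round(np.arange(0.50, 0.951, 0.05), 2)
        return cls("UG", n_participants, tuple(_even_schedule(levels, 2)), **kw)

    @classmethod
    def prisoners_dilemma(cls, n_participants: int = 100, **kw) -> "GameScenario":
        # 22 rounds: partner contributions $0..$1 in $0.10 steps x 2 each.
        levels = np.round(np.arange(0.0, 1.001, 0.1), 1)
        return cls("PD", n_participants, tuple(_even_schedule(levels, 2)), **kw)

    @classmethod
    def public_goods(cls, n_participants: int = 100, **kw) -> "GameScenario":
        # 62 rounds: collective contributions $0..$3 in $0.10 steps x 2 each.
        levels = np.round(np.arange(0.0, 3.001, 0.1), 1)
        return cls("PGG", n_participants, tuple(_even_schedule(levels, 2)), **kw)

    def badness(self, partner_action: np.ndarray) -> np.ndarray:
        """Normalized partner badness s in [0, 1]."""
        a = np.asarray(partner_action, dtype=float)
        if self.game == "UG":
            return (a - 0.50) / 0.45
        if self.game == "PD":
            return 1.0 - a
        if self.game == "PGG":
            return 1.0 - a / 3.0
        raise ValueError(f"unknown game {self.game!r}")


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def generate_game(
    scenario: GameScenario,
    lexicon: Mapping[str, TermGenerator] | None = None,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Simulate the game-trial table for one scenario.

    Returns a DataFrame with the game CSV schema (plus a ``planted_term``
    column in planted-emotion mode).  Per trial: partner action from the
    even schedule (order shuffled per participant), affect from the linear
    valence/arousal model truncated to the grid by resampling, and the
    response from the logistic choice model.

    In planted mode the causal order is reversed: the choice is drawn
    first from the logistic model evaluated at the *noise-free* valence
    for that partner action, then the affect is drawn from the planted
    term's generator for that choice.
    """
    if scenario.game not in ("UG", "PD", "PGG"):
        raise ValueError(f"unknown game {scenario.game!r}")
    if scenario.planted is not None and lexicon is None:
        raise ValueError("planted-emotion mode requires a lexicon")
    rng = np.random.default_rng(seed)
    sched = np.asarray(scenario.schedule, dtype=float)
    n_tr = sched.size
    rows = []
    for p in range(scenario.n_participants):
        pid = f"G{p:05d}"
        actions = rng.permutation(sched)
        s = scenario.badness(actions)
        mean_v = scenario.valence_best + (scenario.valence_worst - scenario.valence_best) * s
        mean_a = scenario.arousal_best + (scenario.arousal_worst - scenario.arousal_best) * s

        if scenario.planted is None:
            xy = _truncated_normal_points(mean_v, mean_a, scenario.noise_sd, rng)
            v_model = to_model_space(xy)[:, 0]
            response, planted_terms = _responses(scenario, v_model, rng), None
        else:
            v_model_det = (mean_v - 250.0) / 250.0
            response = _responses(scenario, v_model_det, rng)
            choice = _binary_choice(scenario.game, response)
            planted_terms = np.array([scenario.planted[c] for c in choice])
            xy = np.empty((n_tr, 2))
            for term in np.unique(planted_terms):
                mask = planted_terms == term
                xy[mask] = lexicon[term].sample(int(mask.sum()), rng)

        frame = pd.DataFrame({
            "participant_id": pid,
            "trial": np.arange(1, n_tr + 1),
            "game": scenario.game,
            "role": "responder",
            "partner_action": actions,
            "valence": xy[:, 0],
            "arousal": xy[:, 1],
            "response": response,
        })
        if planted_terms is not None:
            frame["planted_term"] = planted_terms
        rows.append(frame)
    return pd.concat(rows, ignore_index=True)


def _truncated_normal_points(mean_v, mean_a, sd, rng) -> np.ndarray:
    n = len(mean_v)
    out = np.empty((n, 2))
    todo = np.arange(n)
    while todo.size:
        draw = np.column_stack([mean_v[todo], mean_a[todo]])
        draw = draw + rng.standard_normal((todo.size, 2)) * sd
        ok = np.all((draw >= GRID_MIN) & (draw <= GRID_MAX), axis=1)
        out[todo[ok]] = draw[ok]
        todo = todo[~ok]
    return out


def _responses(scenario: GameScenario, v_model: np.ndarray, rng) -> np.ndarray:
    if scenario.game == "UG":
        p_reject = _logistic(scenario.choice_intercept + scenario.choice_slope * v_model)
        reject = rng.random(v_model.size) < p_reject
        return np.where(reject, "reject", "accept")
    latent = _logistic(scenario.contrib_intercept + scenario.contrib_slope * v_model)
    return np.round(np.round(latent * 10.0) / 10.0, 1).astype(object)


def _binary_choice(game: str, response: np.ndarray) -> np.ndarray:
    if game == "UG":
        return np.where(response == "reject", "punish", "accept")
    contrib = np.asarray(response, dtype=float)
    return np.where(contrib < 0.5, "defect", "cooperate")


def payoff(game: str, own: float, others: float | Sequence[float]) -> float:
    """Dollar payoff of one round, endowment $1.

    PD: (1 - own) + 1.5 * (own + partner) / 2.  PGG: (1 - own) +
    2 * (own + sum of 3 partners) / 4.  Unilateral defection strictly
    increases own payoff (marginal return per contributed dollar < 1).
    """
    own = float(own)
    if not (0.0 <= own <= 1.0):
        raise ValueError("own contribution outside [0, 1]")
    if game == "PD":
        partner = float(np.atleast_1d(others)[0])
        if not (0.0 <= partner <= 1.0):
            raise ValueError("partner contribution outside [0, 1]")
        return (1.0 - own) + 1.5 * (own + partner) / 2.0
    if game == "PGG":
        arr = np.atleast_1d(np.asarray(others, dtype=float))
        if arr.size != 3:
            raise ValueError("PGG expects the 3 partners' contributions")
        if arr.min() < 0.0 or arr.max() > 1.0:
            raise ValueError("partner contribution outside [0, 1]")
        return (1.0 - own) + 2.0 * (own + arr.sum()) / 4.0
    raise ValueError(f"payoff undefined for game {game!r}")


# ---------------------------------------------------------------------------
# Numeric Bayes accuracy of a lexicon


def lexicon_density(
    lexicon: Mapping[str, TermGenerator], resolution: int = 251
) -> tuple[np.ndarray, np.ndarray]:
    """Per-term truncated-mixture densities on a lattice.

    Returns ``(grid, dens)`` where grid is the shared 1-D axis lattice and
    dens has shape (20, resolution, resolution) indexed [term, a, v].
    """
    g = np.linspace(GRID_MIN, GRID_MAX, resolution)
    vv, aa = np.meshgrid(g, g)
    dens = np.zeros((len(TERMS), resolution, resolution))
    for ti, term in enumerate(TERMS):
        for w, mv, ma, sv, sa in lexicon[term].components:
            z = _axis_truncation_mass(mv, sv) * _axis_truncation_mass(ma, sa)
            dens[ti] += (
                w / z
                * stats.norm.pdf(vv, mv, sv)
                * stats.norm.pdf(aa, ma, sa)
            )
    return g, dens


def bayes_accuracy(lexicon: Mapping[str, TermGenerator], resolution: int = 251) -> float:
    """Bayes-optimal accuracy of the balanced 20-class generating mixture.

    Numeric lattice integration: accuracy = (1/20) * sum_j of the mass of
    class j's density on the region where j maximizes the density stack.
    """
    g, dens = lexicon_density(lexicon, resolution)
    winner = np.argmax(dens, axis=0)
    acc = 0.0
    for ti in range(len(TERMS)):
        mass_total = np.trapezoid(np.trapezoid(dens[ti], g, axis=1), g)
        correct = np.where(winner == ti, dens[ti], 0.0)
        acc += np.trapezoid(np.trapezoid(correct, g, axis=1), g) / mass_total
    return acc / len(TERMS)
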