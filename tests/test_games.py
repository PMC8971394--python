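"""Binarization, two-stage aggregation, deltas, rankings, paired tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from affectmap.core import TERMS
from affectmap.games import (
    aggregate_likelihoods, binarize, continuous_choice_association,
    emotion_choice_delta, likelihoods_by_unfairness, paired_t_cohens_d,
    rank_emotions,
)


def _vec(**kw):
    v = np.full(20, (1.0 - sum(kw.values())) / (20 - len(kw)))
    for t, p in kw.items():
        v[TERMS.index(t)] = p
    return v


class TestBinarize:
    def test_ug_mapping(self):
        trials = pd.DataFrame({"game": ["UG", "UG"],
                               "response": ["reject", "accept"]})
        assert binarize(trials).tolist() == ["punish", "accept"]

    @pytest.mark.parametrize("contrib, label", [
        (0.0, "defect"), (0.4, "defect"), (0.49, "defect"),
        (0.5, "cooperate"), (1.0, "cooperate"),
    ])
    def test_contribution_bins(self, contrib, label):
        trials = pd.DataFrame({"game": ["PD"], "response": [contrib]})
        assert binarize(trials).iloc[0] == label

    def test_bad_ug_response(self):
        trials = pd.DataFrame({"game": ["UG"], "response": ["maybe"]})
        with pytest.raises(ValueError):
            binarize(trials)


class TestAggregate:
    def test_single_participant_idempotent(self):
        v = _vec(angry=0.4)
        probs = np.tile(v, (5, 1))
        s = aggregate_likelihoods(probs, ["p"] * 5, ["punish"] * 5)
        assert np.allclose(s.means.loc["punish"].to_numpy(), v)

    def test_two_stage_ignores_trial_counts(self):
        u, v = _vec(angry=0.5), _vec(happy=0.5)
        # participant a: 8 punish trials of u; b: 2 punish trials of v
        probs = np.vstack([np.tile(u, (8, 1)), np.tile(v, (2, 1))])
        s = aggregate_likelihoods(probs, ["a"] * 8 + ["b"] * 2, ["punish"] * 10)
        assert np.allclose(s.means.loc["punish"].to_numpy(), (u + v) / 2)

    def test_three_participant_hand_arithmetic(self):
        # spreadsheet oracle: explicit stage-1 then stage-2 means
        rows = {
            "a": [_vec(sad=0.6), _vec(sad=0.2)],   # stage-1 mean: sad=0.4
            "b": [_vec(sad=0.3)],                  # sad=0.3
            "c": [_vec(sad=0.5), _vec(sad=0.7)],   # sad=0.6
        }
        probs, pids = [], []
        for pid, vecs in rows.items():
            probs.extend(vecs)
            pids.extend([pid] * len(vecs))
        s = aggregate_likelihoods(np.array(probs), pids, ["punish"] * 5)
        expect_sad = (0.4 + 0.3 + 0.6) / 3
        assert s.means.loc["punish", "sad"] == pytest.approx(expect_sad, abs=1e-12)
        assert s.n_participants["punish"] == 3
        lo = s.ci_low.loc["punish", "sad"]
        hi = s.ci_high.loc["punish", "sad"]
        assert lo < expect_sad < hi

    def test_means_sum_to_one(self):
        rng = np.random.default_rng(0)
        probs = rng.dirichlet(np.ones(20), 60)
        pids = rng.choice(list("abcde"), 60)
        choices = rng.choice(["punish", "accept"], 60)
        s = aggregate_likelihoods(probs, pids, choices)
        for c in s.choices:
            assert s.means.loc[c].sum() == pytest.approx(1.0, abs=1e-9)


class TestDelta:
    def _summary(self, pu, ac):
        probs = np.vstack([np.tile(pu, (3, 1)), np.tile(ac, (3, 1))])
        return aggregate_likelihoods(
            probs, ["a", "b", "c"] * 2, ["punish"] * 3 + ["accept"] * 3
        )

    def test_equal_vectors_zero_delta(self):
        v = _vec(sad=0.3)
        d = emotion_choice_delta(self._summary(v, v), "punish", "accept")
        assert np.allclose(d.to_numpy(), 0.0)

    def test_deltas_sum_to_zero_and_sign(self):
        s = self._summary(_vec(disappointed=0.5), _vec(satisfied=0.5))
        d = emotion_choice_delta(s, "punish", "accept")
        assert d.sum() == pytest.approx(0.0, abs=1e-12)
        assert d["disappointed"] > 0 > d["satisfied"]

    def test_missing_choice(self):
        v = _vec(sad=0.3)
        s = aggregate_likelihoods(np.tile(v, (3, 1)), list("abc"), ["punish"] * 3)
        with pytest.raises(ValueError):
            emotion_choice_delta(s, "punish", "accept")


class TestUnfairnessGradient:
    def test_rows_sum_to_one_and_levels_present(self):
        rng = np.random.default_rng(1)
        n = 120
        trials = pd.DataFrame({
            "participant_id": rng.choice(list("abcdef"), n),
            "game": "UG",
            "partner_action": rng.choice([0.5, 0.7, 0.95], n),
            "response": rng.choice(["accept", "reject"], n),
        })
        probs = rng.dirichlet(np.ones(20), n)
        out = likelihoods_by_unfairness(trials, probs)
        assert np.allclose(out.sum(axis=1), 1.0, atol=1e-9)
        assert set(out.index.get_level_values("level")) == {0.5, 0.7, 0.95}

    def test_empty_level_absent(self):
        trials = pd.DataFrame({
            "participant_id": ["a", "a"], "game": "UG",
            "partner_action": [0.5, 0.5], "response": ["accept", "accept"],
        })
        probs = np.tile(_vec(neutral=0.5), (2, 1))
        out = likelihoods_by_unfairness(trials, probs)
        assert list(out.index.get_level_values("level").unique()) == [0.5]
        assert "punish" not in out.index.get_level_values("choice")


class TestRanking:
    def test_strict_max_first_and_order_invariance(self):
        rng = np.random.default_rng(2)
        probs = rng.dirichlet(np.ones(20), 40)
        pids = rng.choice(list("abcd"), 40)
        choices = ["punish"] * 40
        s1 = aggregate_likelihoods(probs, pids, choices)
        perm = rng.permutation(40)
        s2 = aggregate_likelihoods(probs[perm], np.array(pids)[perm],
                                   np.array(choices)[perm])
        r1, r2 = rank_emotions(s1, "punish"), rank_emotions(s2, "punish")
        assert r1["term"].tolist() == r2["term"].tolist()
        top = s1.means.loc["punish"].idxmax()
        assert r1["term"].iloc[0] == top


class TestPairedT:
    def test_hand_arithmetic(self):
        x, y = np.array([2.0, 3.0, 4.0]), np.array([1.0, 1.0, 1.0])
        t, df, p, d = paired_t_cohens_d(x, y)
        assert t == pytest.approx(2 * np.sqrt(3))
        assert df == 2
        assert d == pytest.approx(2.0)

    def test_identical_gives_zero(self):
        x = np.array([1.0, 2.0, 3.0])
        t, df, p, d = paired_t_cohens_d(x, x)
        assert t == 0.0 and d == 0.0 and p == 1.0

    def test_constant_nonzero_diff_infinite_t(self):
        x, y = np.array([2.0, 2.0, 2.0]), np.array([1.0, 1.0, 1.0])
        t, df, p, d = paired_t_cohens_d(x, y)
        assert np.isinf(t) and t > 0 and p == 0.0

    @given(st.lists(st.floats(-5, 5), min_size=3, max_size=12),
           st.integers(0, 10 ** 6))
    @settings(deadline=None, max_examples=50)
    def test_t_equals_d_root_n(self, xs, seed):
        rng = np.random.default_rng(seed)
        x = np.array(xs)
        y = x + rng.normal(0, 1, x.size)
        t, df, p, d = paired_t_cohens_d(x, y)
        if np.isfinite(t):
            assert t == pytest.approx(d * np.sqrt(x.size), rel=1e-9)


class TestContinuousAssociation:
    def _trials(self, contribs, pids):
        return pd.DataFrame({
            "participant_id": pids, "game": "PD", "response": contribs,
        })

    def test_planted_disappointment_ranked_top(self):
        rng = np.random.default_rng(3)
        n = 400
        pids = np.repeat([f"p{i}" for i in range(20)], 20)
        contrib = rng.choice(np.round(np.arange(0, 1.01, 0.1), 1), n)
        base = rng.dirichlet(np.ones(20), n) * 0.4
        probs = base.copy()
        # disappointment likelihood rises as contribution falls
        probs[:, TERMS.index("disappointed")] += 0.6 * (1 - contrib)
        probs[:, TERMS.index("happy")] += 0.6 * contrib
        probs /= probs.sum(axis=1, keepdims=True)
        out = continuous_choice_association(self._trials(contrib, pids), probs)
        assert out["term"].iloc[0] == "disappointed"
        assert out.set_index("term").loc["happy", "rank"] == 20

    def test_null_association_near_zero(self):
        rng = np.random.default_rng(4)
        n = 600
        pids = np.repeat([f"p{i}" for i in range(30)], 20)
        contrib = rng.choice(np.round(np.arange(0, 1.01, 0.1), 1), n)
        probs = rng.dirichlet(np.ones(20), n)
        out = continuous_choice_association(self._trials(contrib, pids), probs)
        assert np.abs(out["mean_association"]).max() < 0.01

    def test_sign_flips_under_reflection(self):
        rng = np.random.default_rng(5)
        n = 100
        pids = np.repeat([f"p{i}" for i in range(5)], 20)
        contrib = rng.choice(np.round(np.arange(0, 1.01, 0.1), 1), n)
        probs = rng.dirichlet(np.ones(20), n)
        a = continuous_choice_association(self._trials(contrib, pids), probs)
        b = continuous_choice_association(self._trials(1 - contrib, pids), probs)
        a = a.set_index("term")["mean_association"]
        b = b.set_index("term")["mean_association"]
        assert np.allclose(a, -b[a.index], atol=1e-12)

    def test_constant_contribution_participants_excluded(self):
        probs = np.tile(_vec(sad=0.3), (4, 1))
        trials = self._trials([0.5, 0.5, 0.2, 0.8], ["a", "a", "b", "b"])
        out = continuous_choice_association(trials, probs)
        assert np.allclose(out["mean_association"], 0.0)  # only b counts
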