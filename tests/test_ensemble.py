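"""Bootstrap diversification, aggregation rules and member selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mwlcnn.ensemble import (
    ModelScore,
    bootstrap_train_sets,
    combine_posteriors,
    fit_stacking,
    majority_vote,
    rank_weights,
    select_members,
    weighted_average_predict,
)


class TestBootstrap:
    def test_subset_sizes(self):
        subsets = bootstrap_train_sets(np.arange(100), fraction=0.8, K=5, seed=0)
        assert len(subsets) == 5
        for s in subsets:
            assert len(s) == 80
            assert len(np.unique(s)) == 80  # without replacement

    def test_fraction_one_is_permutation(self):
        subsets = bootstrap_train_sets(np.arange(30), fraction=1.0, K=3, seed=1)
        for s in subsets:
            assert sorted(s) == list(range(30))

    def test_determinism_and_member_diversity(self):
        a = bootstrap_train_sets(np.arange(50), K=4, seed=7)
        b = bootstrap_train_sets(np.arange(50), K=4, seed=7)
        for x, y in zip(a, b):
            assert np.array_equal(x, y)
        assert not np.array_equal(np.sort(a[0]), np.sort(a[1])) or not np.array_equal(a[0], a[1])

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_train_sets(np.arange(10), fraction=1.5, K=2, seed=0)


class TestRankWeights:
    def test_distinct_accuracies_closed_form(self):
        w = rank_weights([0.9, 0.8, 0.7, 0.6, 0.5])
        np.testing.assert_allclose(w, np.array([5, 4, 3, 2, 1]) / 15.0, atol=1e-12)

    def test_single_member(self):
        np.testing.assert_allclose(rank_weights([0.42]), [1.0])

    def test_ties_average_ranks_and_sum_to_one(self):
        w = rank_weights([0.8, 0.8, 0.6])
        # ranks (2.5, 2.5, 1) -> weights /6
        np.testing.assert_allclose(w, [2.5 / 6, 2.5 / 6, 1 / 6], atol=1e-12)

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=12))
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_weights_always_sum_to_one(self, accs):
        w = rank_weights(accs)
        assert abs(w.sum() - 1.0) < 1e-12
        assert (w >= 0).all()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rank_weights([])


class TestWeightedAverage:
    def test_hand_example(self):
        post = np.array([[[0.6, 0.4]], [[0.1, 0.9]]])  # (K=2, n=1, c=2)
        labels = weighted_average_predict(post, np.array([0.7, 0.3]))
        combined = combine_posteriors(post, np.array([0.7, 0.3]))
        np.testing.assert_allclose(combined, [[0.45, 0.55]], atol=1e-12)
        assert labels.tolist() == [1]

    def test_identical_members_match_single_member(self):
        rng = np.random.default_rng(0)
        p = rng.dirichlet(np.ones(3), size=20)
        post = np.stack([p, p, p])
        labels = weighted_average_predict(post, np.array([0.5, 0.3, 0.2]))
        assert np.array_equal(labels, p.argmax(axis=1))

    def test_uniform_weights_equal_plain_average(self):
        rng = np.random.default_rng(1)
        post = rng.dirichlet(np.ones(4), size=(5, 30))
        combined = combine_posteriors(post, np.full(5, 0.2))
        np.testing.assert_allclose(combined, post.mean(axis=0), atol=1e-12)

    def test_weights_not_summing_to_one_rejected(self):
        post = np.random.default_rng(2).dirichlet(np.ones(2), size=(3, 4))
        with pytest.raises(ValueError, match="sum to 1"):
            weighted_average_predict(post, np.array([0.3, 0.3, 0.3]))

    def test_member_weight_mismatch_rejected(self):
        post = np.random.default_rng(3).dirichlet(np.ones(2), size=(3, 4))
        with pytest.raises(ValueError):
            weighted_average_predict(post, np.array([0.5, 0.5]))


class TestMajorityVote:
    def test_simple_majority(self):
        votes = np.array([[1], [1], [2]])
        assert majority_vote(votes).tolist() == [1]

    def test_tie_broken_by_best_member(self):
        votes = np.array([[1], [2]])
        assert majority_vote(votes, accuracies=[0.6, 0.9]).tolist() == [2]
        assert majority_vote(votes, accuracies=[0.9, 0.6]).tolist() == [1]

    def test_unanimous(self):
        votes = np.full((5, 7), 3)
        assert majority_vote(votes).tolist() == [3] * 7

    def test_agrees_with_weighted_average_when_members_agree(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            n, c, K = 6, 3, 4
            hard = rng.integers(0, c, n)
            post = np.zeros((K, n, c))
            post[:, np.arange(n), hard] = 0.7
            post += rng.dirichlet(np.ones(c), size=(K, n)) * 0.3  # keep argmax
            w = rank_weights(rng.random(K))
            assert np.array_equal(
                majority_vote(post.argmax(axis=2)), weighted_average_predict(post, w)
            )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            majority_vote(np.empty((0, 3), dtype=int))


class _OracleMember:
    """Deterministic member: predicts a fixed function of the features,
    optionally corrupted on a fraction of inputs."""

    def __init__(self, n_classes, flip=0.0, seed=0):
        self.n_classes, self.flip, self.seed = n_classes, flip, seed

    def fit(self, features, labels):
        return self

    def predict_proba(self, features):
        y = (features[:, 0].astype(int)) % self.n_classes
        rng = np.random.default_rng([self.seed, len(features)])
        bad = rng.random(len(y)) < self.flip
        y = np.where(bad, (y + 1) % self.n_classes, y)
        out = np.full((len(y), self.n_classes), 0.01)
        out[np.arange(len(y)), y] = 1.0
        return out / out.sum(axis=1, keepdims=True)


class TestStacking:
    def _data(self, n=100, c=3):
        rng = np.random.default_rng(5)
        X = np.column_stack([rng.integers(0, c, n), rng.standard_normal(n)]).astype(float)
        y = X[:, 0].astype(int)
        return X, y

    def test_meta_table_shape_n_by_k(self):
        X, y = self._data(n=100)
        members = [_OracleMember(3, flip=f, seed=i) for i, f in enumerate((0, 0.1, 0.2))]
        ens = fit_stacking(members, X, y, folds=5, seed=0)
        assert ens.meta_table.shape == (100, 3)

    def test_perfect_members_give_perfect_stack(self):
        X, y = self._data(n=80)
        members = [_OracleMember(3) for _ in range(4)]
        ens = fit_stacking(members, X, y, folds=5, seed=0)
        Xt, yt = self._data(n=40)
        assert (ens.predict(Xt) == yt).mean() == 1.0

    def test_leave_one_out_table(self):
        X, y = self._data(n=12)
        members = [_OracleMember(3)]
        ens = fit_stacking(members, X, y, folds=12, seed=0)
        assert ens.meta_table.shape == (12, 1)

    def test_too_many_folds_rejected(self):
        X, y = self._data(n=4)
        with pytest.raises(ValueError):
            fit_stacking([_OracleMember(3)], X, y, folds=10, seed=0)


def _grid_scores():
    rng = np.random.default_rng(6)
    scores = []
    for arch in ("CNN1", "CNN2", "CNN3", "CNN4", "CNN5"):
        for opt in ("nm", "adagrad", "adadelta", "adam"):
            scores.append(ModelScore(None, float(rng.random()), arch, opt))
    return scores


class TestSelectMembers:
    def test_best_per_family(self):
        scores = _grid_scores()
        picked = select_members(scores, "best-per-family")
        assert len(picked) == 5
        assert sorted({s.arch_id for s in picked}) == ["CNN1", "CNN2", "CNN3", "CNN4", "CNN5"]
        for s in picked:
            family = [t for t in scores if t.arch_id == s.arch_id]
            assert s.accuracy == max(t.accuracy for t in family)

    def test_best_and_worst_per_family(self):
        picked = select_members(_grid_scores(), "best-and-worst-per-family")
        assert len(picked) == 10

    def test_top_half(self):
        scores = _grid_scores()
        picked = select_members(scores, "top-half")
        assert len(picked) == 10
        threshold = sorted((s.accuracy for s in scores), reverse=True)[10]
        assert all(s.accuracy >= threshold for s in picked)

    def test_all(self):
        assert len(select_members(_grid_scores(), "all")) == 20

    def test_unknown_strategy_rejected(self):
        with pytest.raises(ValueError, match="strategy"):
            select_members(_grid_scores(), "bagging")


def test_ensemble_beats_mean_member_usually():
    """With independent member noise the aggregate should rarely lose to the
    average member (directional check over 20 seeded repetitions)."""
    wins = 0
    for rep in range(20):
        rng = np.random.default_rng([rep, 99])
        n, c, K = 300, 4, 10
        y = rng.integers(0, c, n)
        post = np.zeros((K, n, c))
        member_acc = []
        for j in range(K):
            noise = rng.gumbel(size=(n, c))
            logits = 1.5 * np.eye(c)[y] + noise
            post[j] = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)
            member_acc.append((post[j].argmax(axis=1) == y).mean())
        w = rank_weights(member_acc)
        ens_acc = (weighted_average_predict(post, w) == y).mean()
        wins += ens_acc >= np.mean(member_acc)
    assert wins >= 18
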