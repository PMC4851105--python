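"""Grouped-bootstrap forests, OOB scores, importance and q search."""

import numpy as np
import pytest
from sklearn.tree import DecisionTreeClassifier

from swingemg.forest import (
    GroupedRandomForestClassifier,
    GroupedRandomForestRegressor,
    default_q_grid,
    group_bootstrap,
    permutation_importance,
    q_grid_search,
)

SUBJECTS = [f"g{i}" for i in range(15)]


def _toy(n_subjects=15, shots=5, p=10, seed=0, informative=True):
    rng = np.random.default_rng(seed)
    groups = np.repeat([f"g{i}" for i in range(n_subjects)], shots)
    sex = np.repeat([1] * 10 + [0] * (n_subjects - 10), shots)
    X = rng.normal(size=(n_subjects * shots, p))
    latent = X[:, 0] + 0.5 * X[:, 1]
    if informative:
        y = (latent > 0).astype(int)
    else:
        y = rng.integers(0, 2, len(latent))
    target = latent + 0.1 * rng.normal(size=len(latent))
    return X, y, target, groups, sex


class TestGroupBootstrap:
    def test_no_subject_both_in_bag_and_oob(self):
        rng = np.random.default_rng(0)
        for _ in range(500):
            counts, oob = group_bootstrap(SUBJECTS, rng)
            assert not set(counts) & oob
            assert sum(counts.values()) == len(SUBJECTS)

    def test_stratified_preserves_sex_ratio(self):
        rng = np.random.default_rng(1)
        sex = {s: int(i < 10) for i, s in enumerate(SUBJECTS)}
        for _ in range(200):
            counts, _ = group_bootstrap(SUBJECTS, rng, sex)
            men = sum(m for s, m in counts.items() if sex[s] == 1)
            assert men == 10 and sum(counts.values()) == 15

    def test_unique_fraction_matches_theory(self):
        """E[unique subjects]/n = 1 - (1 - 1/n)^n for the plain bootstrap."""
        rng = np.random.default_rng(2)
        n = len(SUBJECTS)
        fracs = [len(group_bootstrap(SUBJECTS, rng)[0]) / n
                 for _ in range(4000)]
        expected = 1.0 - (1.0 - 1.0 / n) ** n
        se = np.std(fracs) / np.sqrt(len(fracs))
        assert abs(np.mean(fracs) - expected) < 5 * se + 1e-3

    def test_missing_sex_entry_rejected(self):
        rng = np.random.default_rng(3)
        with pytest.raises(KeyError):
            group_bootstrap(["a", "b", "c"], rng, {"a": 1, "b": 1})


class TestClassifierOob:
    def test_leaf_frequency_hand_example(self):
        """Oracle: a depth-limited tree with a known impure leaf must
        yield score = f1 - f0 computed from the leaf's class counts."""
        X = np.array([[0.0], [0.0], [0.0], [0.0], [10.0], [10.0]])
        y = np.array([0, 0, 0, 1, 1, 1])
        tree = DecisionTreeClassifier(max_depth=1, random_state=0).fit(X, y)
        clf = GroupedRandomForestClassifier(n_trees=1)
        clf.classes_ = np.array([0, 1])
        scores = clf._leaf_freq_diff(tree, X)
        # left leaf holds 3 zeros + 1 one -> 1/4 - 3/4 = -0.5
        np.testing.assert_allclose(scores[:4], -0.5)
        # right leaf is pure ones -> 1.0
        np.testing.assert_allclose(scores[4:], 1.0)

    def test_scores_bounded(self):
        X, y, _, groups, sex = _toy()
        clf = GroupedRandomForestClassifier(n_trees=100, random_state=0)
        clf.fit(X, y, groups=groups, sex=sex)
        assert (np.abs(clf.oob_score_) <= 1.0).all()
        assert (clf.oob_count_ > 0).all()

    def test_oob_purity(self):
        X, y, _, groups, sex = _toy()
        clf = GroupedRandomForestClassifier(n_trees=50, random_state=0)
        clf.fit(X, y, groups=groups, sex=sex)
        masks = clf._oob_tree_mask()
        for t, oob in enumerate(clf.oob_subjects_):
            in_bag = set(np.unique(clf.groups_[~masks[t]]))
            assert not in_bag & oob

    def test_informative_scores_separate_classes(self):
        X, y, _, groups, sex = _toy(seed=4)
        clf = GroupedRandomForestClassifier(n_trees=300, random_state=0)
        clf.fit(X, y, groups=groups, sex=sex)
        assert clf.oob_score_[y == 1].mean() > clf.oob_score_[y == 0].mean()

    def test_single_class_rejected(self):
        X, _, _, groups, sex = _toy()
        with pytest.raises(ValueError, match="two classes"):
            GroupedRandomForestClassifier(n_trees=5).fit(
                X, np.zeros(len(X)), groups=groups, sex=sex)

    def test_requires_groups(self):
        X, y, _, _, _ = _toy()
        with pytest.raises(ValueError, match="groups"):
            GroupedRandomForestClassifier(n_trees=5).fit(X, y)

    def test_too_few_trees_leaves_shots_uncovered(self):
        X, y, _, groups, sex = _toy()
        with pytest.raises(ValueError, match="never OOB"):
            # one tree leaves most subjects in-bag only
            GroupedRandomForestClassifier(n_trees=1, random_state=5).fit(
                X, y, groups=groups, sex=sex)


class TestRegressorOob:
    def test_oob_is_mean_of_oob_tree_predictions(self):
        X, _, target, groups, _ = _toy(seed=6)
        reg = GroupedRandomForestRegressor(
            n_trees=50, stratify_sex=False, random_state=0)
        reg.fit(X, target, groups=groups)
        masks = reg._oob_tree_mask()
        # recompute by brute force for a handful of shots
        for i in (0, 17, 42):
            preds = [tree.predict(X[i:i + 1])[0]
                     for t, tree in enumerate(reg.estimators_) if masks[t, i]]
            assert reg.oob_score_[i] == pytest.approx(np.mean(preds))
            assert reg.oob_count_[i] == len(preds)

    def test_learns_linear_signal(self):
        X, _, target, groups, _ = _toy(seed=7)
        reg = GroupedRandomForestRegressor(
            n_trees=300, stratify_sex=False, random_state=0)
        reg.fit(X, target, groups=groups)
        assert np.corrcoef(reg.oob_score_, target)[0, 1] > 0.5

    def test_scoreset_alignment(self, study_arrays):
        X = np.column_stack([study_arrays["sex"],
                             np.random.default_rng(0).normal(size=75)])
        reg = GroupedRandomForestRegressor(
            n_trees=100, stratify_sex=False, random_state=0)
        reg.fit(X, study_arrays["speed"], groups=study_arrays["groups"])
        ss = reg.oob_score_set(shot_id=study_arrays["shot_ids"],
                               sex=study_arrays["sex"])
        assert ss.task == "regress"
        np.testing.assert_array_equal(ss.shot_id, study_arrays["shot_ids"])


class TestImportanceAndGrid:
    def test_informative_feature_ranks_first(self):
        X, y, _, groups, sex = _toy(seed=8, p=5)
        clf = GroupedRandomForestClassifier(n_trees=200, random_state=0)
        clf.fit(X, y, groups=groups, sex=sex)
        imp = permutation_importance(clf, n_repeats=3, random_state=0)
        assert imp.argmax() in (0, 1)  # the two generative columns

    def test_constant_feature_zero_importance(self):
        X, y, _, groups, sex = _toy(seed=9, p=5)
        X[:, 3] = 7.0
        clf = GroupedRandomForestClassifier(n_trees=100, random_state=0)
        clf.fit(X, y, groups=groups, sex=sex)
        imp = permutation_importance(clf, n_repeats=2, random_state=0)
        assert imp[3] == 0.0

    def test_default_q_grid(self):
        assert default_q_grid(49) == [7, 14, 17]
        assert default_q_grid(1) == [1]

    def test_grid_search_returns_argmin(self):
        X, y, target, groups, sex = _toy(seed=10)
        q, crit, forest = q_grid_search(
            X, y, groups, sex=sex, task="detect", grid=[2, 5],
            n_trees=60, random_state=0)
        assert q in (2, 5) and np.isfinite(crit)
        from swingemg.metrics import cllr

        assert crit == pytest.approx(cllr(forest.oob_score_, y))
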