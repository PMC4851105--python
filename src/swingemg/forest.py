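"""Random forest with subject-grouped bootstrap and OOB score extraction.

Golf data are repeated measures: each player contributes several swings.
The bootstrap therefore resamples *subjects* (with replacement, optionally
stratified by sex so every bag preserves the sex ratio); all shots of a
drawn subject enter the bag with the subject's multiplicity, and subjects
never drawn are that tree's out-of-bag (OOB) set — converting the usual
leave-one-out character of OOB validation into leave-one-subject-out.

Per-shot OOB scores feed decision-level fusion: for detection the score is
the difference between the OOB-averaged leaf class frequencies of the
effective and ineffective classes (a value in [-1, 1]); for regression it
is the mean of the OOB tree predictions.  Individual trees are unpruned
CART trees (Gini / variance reduction) with ``q`` features tried per node.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from swingemg.metrics import cllr as _cllr


@dataclass
class ForestConfig:
    """Forest hyper-parameters.  ``n_trees`` defaults to the desk scale
    (500); pass 5000 to reproduce the full-size ensembles."""

    n_trees: int = 500
    q: int | None = None  # features tried per node; None = ceil(sqrt(p))
    task: str = "detect"
    min_leaf: int = 1
    stratify_sex: bool = True
    seed: int = 0


@dataclass
class ScoreSet:
    """Per-shot OOB outputs of a learner, aligned with its dataset."""

    shot_id: np.ndarray
    subject_id: np.ndarray
    sex: np.ndarray
    score: np.ndarray       # detection: posterior difference in [-1, 1];
    # regression: predicted target
    oob_count: np.ndarray   # number of trees for which the shot was OOB
    y: np.ndarray           # labels (detect) or targets (regress)
    task: str = "detect"


def group_bootstrap(
    subjects: Sequence[str],
    rng: np.random.Generator,
    sex_of_subject: dict[str, int] | None = None,
) -> tuple[dict[str, int], set[str]]:
    """Draw one subject-level bootstrap sample.

    Subjects are sampled with replacement (stratified within sex when
    ``sex_of_subject`` is given, drawing each stratum's own size so the
    sex ratio of the bag matches the dataset).  Returns the multiplicity
    of each drawn subject and the set of never-drawn (OOB) subjects.
    """
    subjects = list(dict.fromkeys(subjects))
    counts: dict[str, int] = {}
    if sex_of_subject is None:
        strata = [subjects]
    else:
        strata = [
            [s for s in subjects if sex_of_subject[s] == sex_value]
            for sex_value in sorted({sex_of_subject[s] for s in subjects})
        ]
        if any(len(st) == 0 for st in strata):
            raise ValueError("empty sex stratum with stratification enabled")
    for stratum in strata:
        draws = rng.integers(0, len(stratum), size=len(stratum))
        for d in draws:
            counts[stratum[d]] = counts.get(stratum[d], 0) + 1
    oob = {s for s in subjects if s not in counts}
    return counts, oob


class _GroupedForestBase(BaseEstimator):
    """Shared fitting machinery for the detection and regression forests."""

    _is_classifier = True

    def __init__(
        self,
        n_trees: int = 500,
        q: int | None = None,
        min_leaf: int = 1,
        stratify_sex: bool = True,
        random_state: int | None = 0,
    ):
        self.n_trees = n_trees
        self.q = q
        self.min_leaf = min_leaf
        self.stratify_sex = stratify_sex
        self.random_state = random_state

    # -- helpers ---------------------------------------------------------
    def _validate(self, X, y, groups, sex):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        groups = np.asarray(groups)
        if X.ndim != 2 or len(X) != len(y) or len(groups) != len(y):
            raise ValueError("X, y and groups must be aligned")
        if sex is not None:
            sex = np.asarray(sex).astype(int)
            if len(sex) != len(y):
                raise ValueError("sex must align with y")
        return X, y, groups, sex

    def fit(self, X, y, groups=None, sex=None):
        """Fit ``n_trees`` unpruned trees on subject-grouped bootstraps.

        Parameters
        ----------
        X : array (n_shots, p)
        y : labels (classifier) or targets (regressor)
        groups : subject id per shot (required)
        sex : per-shot sex flags; used for sex-stratified subject sampling
            when ``stratify_sex`` (classification only)
        """
        if groups is None:
            raise ValueError("groups (subject ids) are required")
        X, y, groups, sex = self._validate(X, y, groups, sex)
        rng = np.random.default_rng(self.random_state)
        subjects = list(dict.fromkeys(groups))
        sex_of_subject = None
        if self._is_classifier and self.stratify_sex and sex is not None:
            sex_of_subject = {g: int(sex[groups == g][0]) for g in subjects}
        shot_idx_of = {g: np.flatnonzero(groups == g) for g in subjects}

        q = self.q if self.q is not None else int(np.ceil(np.sqrt(X.shape[1])))
        q = max(1, min(q, X.shape[1]))
        if self._is_classifier:
            self.classes_ = np.unique(y)
            if len(self.classes_) < 2:
                raise ValueError("need two classes to fit a detection forest")
        self.estimators_ = []
        self.oob_subjects_ = []  # per tree: frozenset of OOB subjects
        tree_seeds = rng.integers(0, 2**31 - 1, size=self.n_trees)
        for b in range(self.n_trees):
            counts, oob = group_bootstrap(subjects, rng, sex_of_subject)
            if self._is_classifier:
                # resample degenerate single-class bags
                for _ in range(100):
                    bag_labels = {int(y[shot_idx_of[g]][0]) for g in counts}
                    bag = np.concatenate(
                        [np.repeat(shot_idx_of[g], m) for g, m in counts.items()]
                    )
                    if len(np.unique(y[bag])) >= 2:
                        break
                    counts, oob = group_bootstrap(subjects, rng, sex_of_subject)
                else:  # pragma: no cover
                    raise ValueError("could not draw a two-class bag")
            else:
                bag = np.concatenate(
                    [np.repeat(shot_idx_of[g], m) for g, m in counts.items()]
                )
            tree = self._make_tree(q, tree_seeds[b])
            tree.fit(X[bag], y[bag])
            self.estimators_.append(tree)
            self.oob_subjects_.append(frozenset(oob))
        self.groups_ = groups
        self.n_features_in_ = X.shape[1]
        self._fit_X, self._fit_y = X, y
        self.oob_score_, self.oob_count_ = self._compute_oob(X)
        return self

    def _oob_tree_mask(self) -> np.ndarray:
        """Boolean (n_trees, n_shots): shot OOB for tree."""
        masks = np.zeros((len(self.estimators_), len(self.groups_)), dtype=bool)
        for t, oob in enumerate(self.oob_subjects_):
            if oob:
                masks[t] = np.isin(self.groups_, list(oob))
        return masks

    def oob_score_set(self, shot_id=None, sex=None) -> ScoreSet:
        """Package the fitted OOB scores as a ScoreSet."""
        n = len(self.groups_)
        return ScoreSet(
            shot_id=np.asarray(shot_id if shot_id is not None else np.arange(n)),
            subject_id=np.asarray(self.groups_),
            sex=np.asarray(sex if sex is not None else np.zeros(n, dtype=int)),
            score=self.oob_score_,
            oob_count=self.oob_count_,
            y=self._fit_y,
            task="detect" if self._is_classifier else "regress",
        )


class GroupedRandomForestClassifier(_GroupedForestBase, ClassifierMixin):
    """Detection forest; OOB score = leaf-frequency posterior difference."""

    _is_classifier = True

    def _make_tree(self, q, seed):
        return DecisionTreeClassifier(
            max_features=q,
            min_samples_leaf=self.min_leaf,
            random_state=int(seed),
        )

    def _leaf_freq_diff(self, tree, X_rows: np.ndarray) -> np.ndarray:
        """Per row: f(class 1) - f(class 0) in the leaf the row falls in."""
        leaves = tree.apply(X_rows)
        value = tree.tree_.value[leaves][:, 0, :]  # normalized frequencies
        freq = value / value.sum(axis=1, keepdims=True)
        i1 = int(np.flatnonzero(self.classes_ == self.classes_.max())[0])
        i0 = 1 - i1
        return freq[:, i1] - freq[:, i0]

    def _compute_oob(self, X) -> tuple[np.ndarray, np.ndarray]:
        masks = self._oob_tree_mask()
        total = np.zeros(len(X))
        count = masks.sum(axis=0)
        for t, tree in enumerate(self.estimators_):
            rows = np.flatnonzero(masks[t])
            if rows.size:
                total[rows] += self._leaf_freq_diff(tree, X[rows])
        if (count == 0).any():
            bad = np.flatnonzero(count == 0)
            raise ValueError(
                f"{bad.size} shot(s) never OOB; increase the number of trees"
            )
        return total / count, count

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        votes = np.zeros((len(X), len(self.classes_)))
        for tree in self.estimators_:
            pred = tree.predict(X)
            for i, c in enumerate(self.classes_):
                votes[:, i] += pred == c
        return self.classes_[votes.argmax(axis=1)]


class GroupedRandomForestRegressor(_GroupedForestBase, RegressorMixin):
    """Regression forest; OOB score = mean of OOB tree predictions."""

    _is_classifier = False

    def _make_tree(self, q, seed):
        return DecisionTreeRegressor(
            max_features=q,
            min_samples_leaf=self.min_leaf,
            random_state=int(seed),
        )

    def _compute_oob(self, X) -> tuple[np.ndarray, np.ndarray]:
        masks = self._oob_tree_mask()
        total = np.zeros(len(X))
        count = masks.sum(axis=0)
        for t, tree in enumerate(self.estimators_):
            rows = np.flatnonzero(masks[t])
            if rows.size:
                total[rows] += tree.predict(X[rows])
        if (count == 0).any():
            bad = np.flatnonzero(count == 0)
            raise ValueError(
                f"{bad.size} shot(s) never OOB; increase the number of trees"
            )
        return total / count, count

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return np.mean([tree.predict(X) for tree in self.estimators_], axis=0)


def _oob_performance(forest, X) -> float:
    """OOB accuracy (classifier) or OOB RMSE (regressor) of a fitted forest
    on a (possibly permuted) copy of its training matrix."""
    score, _ = forest._compute_oob(X)
    if forest._is_classifier:
        pred = np.where(score > 0, forest.classes_.max(), forest.classes_.min())
        return float(np.mean(pred == forest._fit_y))
    return float(np.sqrt(np.mean((score - forest._fit_y) ** 2)))


def permutation_importance(
    forest, n_repeats: int = 5, random_state: int | None = 0
) -> np.ndarray:
    """OOB permutation importance per feature.

    Classification: mean decrease in OOB accuracy after permuting the
    feature.  Regression: mean increase in OOB RMSE (reported as a
    decrease in performance, so larger = more important for both tasks).
    """
    rng = np.random.default_rng(random_state)
    X = forest._fit_X
    base = _oob_performance(forest, X)
    importances = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        if np.all(X[:, j] == X[0, j]):
            continue  # constant feature: permutation changes nothing
        deltas = []
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            perm = _oob_performance(forest, Xp)
            if forest._is_classifier:
                deltas.append(base - perm)
            else:
                deltas.append(perm - base)
        importances[j] = float(np.mean(deltas))
    return importances


def default_q_grid(p: int) -> list[int]:
    """q candidates for individual feature sets."""
    root = np.sqrt(p)
    grid = {int(np.ceil(root)), int(np.ceil(2 * root)), int(np.ceil(p / 3))}
    return sorted({max(1, min(q, p)) for q in grid})


def q_grid_search(
    X,
    y,
    groups,
    sex=None,
    task: str = "detect",
    grid: Sequence[int] | None = None,
    n_trees: int = 500,
    random_state: int = 0,
):
    """Fit one forest per candidate q and keep the best.

    Selection criterion: minimum Cllr of the OOB scores (detection) or
    minimum OOB RMSE (regression).  Returns (best_q, best_criterion,
    best_forest).
    """
    X = np.asarray(X, dtype=float)
    if grid is None:
        grid = default_q_grid(X.shape[1])
    if not grid:
        raise ValueError("empty q grid")
    best = None
    for q in grid:
        if task == "detect":
            forest = GroupedRandomForestClassifier(
                n_trees=n_trees, q=q, random_state=random_state
            ).fit(X, y, groups=groups, sex=sex)
            crit = _cllr(forest.oob_score_, y)
        else:
            forest = GroupedRandomForestRegressor(
                n_trees=n_trees, q=q, stratify_sex=False, random_state=random_state
            ).fit(X, y, groups=groups)
            crit = float(np.sqrt(np.mean((forest.oob_score_ - y) ** 2)))
        if best is None or crit < best[1]:
            best = (q, crit, forest)
    return best
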