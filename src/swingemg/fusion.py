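"""Decision-level fusion with angle-modulated differential evolution.

The 22 per-feature-set OOB scores become meta-features for a second
grouped random forest; sex is always prepended and can never be removed.
Meta-feature subsets are encoded by the angle-modulation trick: a
4-parameter trigonometric generating function

    g(x) = sin(2 pi (x - a) * b * cos(2 pi c (x - a))) + d

is sampled on the grid x_k = 0.1 k (k = 1..22) and thresholded at zero to
yield a binary selection mask, so differential evolution over (a, b, c, d)
searches the 22-dimensional Hamming space through a 4-dimensional
continuous one.  Fitness of a mask is the best criterion (Cllr for
detection, RMSE for regression) over the meta-forest's q sweep.
"""

from __future__ import annotations


import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from swingemg.forest import (
    GroupedRandomForestClassifier,
    GroupedRandomForestRegressor,
    ScoreSet,
)
from swingemg.metrics import cllr, det_eer, regression_metrics, roc_auc

N_META = 22


def build_meta_table(
    scoresets: dict[int, ScoreSet], sex: np.ndarray, y: np.ndarray,
    groups: np.ndarray, shot_id: np.ndarray | None = None,
) -> pd.DataFrame:
    """Aligned meta-feature table: sex + one OOB-score column per set.

    All score sets must cover the same shots in the same order.
    """
    ids = sorted(scoresets)
    ref = np.asarray(scoresets[ids[0]].shot_id)
    data = {"sex": np.asarray(sex, dtype=float)}
    for i in ids:
        ss = scoresets[i]
        if not np.array_equal(np.asarray(ss.shot_id), ref):
            diff = set(map(str, ss.shot_id)) ^ set(map(str, ref))
            raise ValueError(f"score set {i} misaligned; differing shots: {sorted(diff)}")
        data[f"m{i}"] = np.asarray(ss.score, dtype=float)
    df = pd.DataFrame(data, index=pd.Index(
        shot_id if shot_id is not None else ref, name="shot_id"))
    df.attrs["y"] = np.asarray(y)
    df.attrs["groups"] = np.asarray(groups)
    return df


def amde_mask(params: np.ndarray, n: int = N_META) -> np.ndarray:
    """Binary selection mask from the angle-modulated generating function.

    ``g_k = 1`` iff ``g(x_k) > 0`` with ``x_k = 0.1 k``, k = 1..n.
    """
    a, b, c, d = (float(v) for v in params)
    x = 0.1 * np.arange(1, n + 1)
    g = np.sin(2.0 * np.pi * (x - a) * b * np.cos(2.0 * np.pi * c * (x - a))) + d
    return (g > 0.0).astype(int)


def _meta_criterion(score: np.ndarray, y: np.ndarray, task: str) -> float:
    if task == "detect":
        return cllr(score, y)
    return float(np.sqrt(np.mean((score - y) ** 2)))


def fuse(
    meta: pd.DataFrame,
    mask: np.ndarray,
    task: str = "detect",
    n_trees: int = 500,
    q_grid: list[int] | None = None,
    random_state: int = 0,
) -> tuple[ScoreSet, int, float]:
    """Fit the meta-forest on sex + the masked meta-features.

    Every ``q`` in 2..(n_selected + 1) is tried (or the supplied
    ``q_grid``) and the best criterion retained: Cllr for detection, RMSE
    for regression.  Returns (ScoreSet, best_q, best_criterion).
    """
    mask = np.asarray(mask, dtype=int)
    meta_cols = [c for c in meta.columns if c != "sex"]
    if mask.sum() < 1:
        raise ValueError("mask selects no meta-feature")
    selected = [meta_cols[j] for j in np.flatnonzero(mask[: len(meta_cols)])]
    cols = ["sex"] + selected  # sex survives every mask
    X = meta[cols].to_numpy(dtype=float)
    y = meta.attrs["y"]
    groups = meta.attrs["groups"]
    sex = meta["sex"].to_numpy()
    p = X.shape[1]
    if q_grid is None:
        q_grid = list(range(2, len(selected) + 2)) or [1]
    q_grid = sorted({max(1, min(q, p)) for q in q_grid})
    best = None
    for q in q_grid:
        if task == "detect":
            forest = GroupedRandomForestClassifier(
                n_trees=n_trees, q=q, random_state=random_state
            ).fit(X, y, groups=groups, sex=sex)
        else:
            forest = GroupedRandomForestRegressor(
                n_trees=n_trees, q=q, stratify_sex=False, random_state=random_state
            ).fit(X, y, groups=groups)
        crit = _meta_criterion(forest.oob_score_, y, task)
        if best is None or crit < best[2]:
            best = (forest, q, crit)
    forest, q, crit = best
    ss = ScoreSet(
        shot_id=np.asarray(meta.index),
        subject_id=np.asarray(groups),
        sex=np.asarray(sex, dtype=int),
        score=forest.oob_score_,
        oob_count=forest.oob_count_,
        y=np.asarray(y),
        task=task,
    )
    return ss, q, crit


class AmdeFusion(BaseEstimator):
    """Meta-feature selection by angle-modulated differential evolution.

    DE/rand/1/bin over the four generating-function parameters; fitness
    of a candidate is the fused criterion (Cllr or RMSE) of its mask.
    The forest seed is fixed during a run so fitness is deterministic and
    the elitist best-so-far trajectory is monotone non-increasing.

    Parameters largely follow standard DE practice: population ``np_pop``,
    scale ``f_scale``, crossover ``cr``, ``generations`` with early stop
    after ``patience`` stagnant generations.
    """

    def __init__(
        self,
        task: str = "detect",
        np_pop: int = 10,
        f_scale: float = 0.5,
        cr: float = 0.9,
        generations: int = 10,
        patience: int = 10,
        n_trees: int = 150,
        q_grid: list[int] | None = None,
        random_state: int = 0,
    ):
        self.task = task
        self.np_pop = np_pop
        self.f_scale = f_scale
        self.cr = cr
        self.generations = generations
        self.patience = patience
        self.n_trees = n_trees
        self.q_grid = q_grid
        self.random_state = random_state

    def _random_params(self, rng) -> np.ndarray:
        """Draw parameters whose mask selects at least one meta-feature."""
        for _ in range(1000):
            params = rng.uniform(-1.0, 1.0, size=4)
            if amde_mask(params, self._n_meta).sum() > 0:
                return params
        raise RuntimeError("could not draw a non-empty mask")  # pragma: no cover

    def fit(self, meta: pd.DataFrame):
        """Run the evolution; exposes ``best_mask_``, ``best_q_``,
        ``best_criterion_``, ``best_scores_`` and ``trajectory_``."""
        rng = np.random.default_rng(self.random_state)
        self._n_meta = len([c for c in meta.columns if c != "sex"])
        forest_seed = int(rng.integers(0, 2**31 - 1))
        cache: dict[tuple, tuple] = {}

        def fitness(params: np.ndarray):
            mask = amde_mask(params, self._n_meta)
            key = tuple(mask)
            if key not in cache:
                ss, q, crit = fuse(
                    meta, mask, self.task, self.n_trees,
                    self.q_grid, forest_seed,
                )
                cache[key] = (crit, q, ss)
            return cache[key]

        pop = np.array([self._random_params(rng) for _ in range(self.np_pop)])
        fits = [fitness(ind) for ind in pop]
        best_i = int(np.argmin([f[0] for f in fits]))
        best = (pop[best_i].copy(), *fits[best_i])
        self.trajectory_ = [best[1]]
        stagnant = 0
        for _ in range(self.generations):
            for i in range(self.np_pop):
                r1, r2, r3 = rng.choice(
                    [j for j in range(self.np_pop) if j != i], size=3, replace=False
                )
                v = pop[r1] + self.f_scale * (pop[r2] - pop[r3])
                jrand = rng.integers(0, 4)
                trial = pop[i].copy()
                cross = rng.uniform(size=4) < self.cr
                cross[jrand] = True
                trial[cross] = v[cross]
                if amde_mask(trial, self._n_meta).sum() == 0:
                    trial = self._random_params(rng)  # resample all-zero masks
                f_trial = fitness(trial)
                if f_trial[0] <= fits[i][0]:
                    pop[i], fits[i] = trial, f_trial
            gen_best = int(np.argmin([f[0] for f in fits]))
            if fits[gen_best][0] < best[1]:
                best = (pop[gen_best].copy(), *fits[gen_best])
                stagnant = 0
            else:
                stagnant += 1
            self.trajectory_.append(best[1])
            if stagnant >= self.patience:
                break
        self.best_params_ = best[0]
        self.best_criterion_ = best[1]
        self.best_q_ = best[2]
        self.best_scores_ = best[3]
        self.best_mask_ = amde_mask(best[0], self._n_meta)
        return self


def optimize(
    meta: pd.DataFrame, task: str = "detect", random_state: int = 0, **kwargs
) -> AmdeFusion:
    """Convenience wrapper: run AMDE meta-feature selection on a table."""
    return AmdeFusion(task=task, random_state=random_state, **kwargs).fit(meta)


def repeat_fusion(
    meta: pd.DataFrame,
    mask: np.ndarray,
    task: str = "detect",
    n_repeats: int = 100,
    n_trees: int = 500,
    q: int | None = None,
    random_state: int = 0,
) -> dict[str, tuple[float, float]]:
    """Repeat fusion with a fixed mask over different forest seeds.

    Returns per metric the mean and half-width of the normal-approximation
    95% confidence interval (``+- 1.96 sd / sqrt(n)``); a single repeat
    reports a zero half-width.
    """
    rng = np.random.default_rng(random_state)
    q_grid = [q] if q is not None else None
    runs: dict[str, list[float]] = {}
    for _ in range(n_repeats):
        seed = int(rng.integers(0, 2**31 - 1))
        ss, _, crit = fuse(meta, mask, task, n_trees, q_grid, seed)
        if task == "detect":
            _, eer = det_eer(ss.score, ss.y)
            _, auc = roc_auc(ss.score, ss.y)
            vals = {"cllr": crit, "eer": eer, "auc": auc}
        else:
            m = regression_metrics(ss.score, ss.y)
            vals = {"rmse": m["rmse"], "mape": m["mape"], "corr": m["corr"]}
        for k, v in vals.items():
            runs.setdefault(k, []).append(v)
    out = {}
    for k, v in runs.items():
        v = np.asarray(v)
        half = 0.0 if len(v) < 2 else float(1.96 * v.std(ddof=1) / np.sqrt(len(v)))
        out[k] = (float(v.mean()), half)
    return out
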