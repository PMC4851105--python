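"""Meta-table construction, angle-modulated masks, fusion and repeats."""

import numpy as np
import pytest

from swingemg.forest import ScoreSet
from swingemg.fusion import (
    AmdeFusion,
    amde_mask,
    build_meta_table,
    fuse,
    repeat_fusion,
)


def _scoreset(score, y, groups, sex, shot_id, task="detect"):
    return ScoreSet(
        shot_id=np.asarray(shot_id), subject_id=np.asarray(groups),
        sex=np.asarray(sex), score=np.asarray(score, float),
        oob_count=np.full(len(score), 10), y=np.asarray(y), task=task,
    )


def _toy_meta(seed=0, n_sets=22, n_subjects=10, shots=4, informative=(1, 2),
              task="detect"):
    """Meta table where only the sets in ``informative`` carry the label."""
    rng = np.random.default_rng(seed)
    n = n_subjects * shots
    groups = np.repeat([f"g{i}" for i in range(n_subjects)], shots)
    sex = np.repeat(rng.integers(0, 2, n_subjects), shots)
    shot_id = np.array([f"s{i}" for i in range(n)])
    if task == "detect":
        y = rng.integers(0, 2, n)
        signal = 2.0 * (y - 0.5)
    else:
        y = rng.normal(size=n) * 5.0 + 50.0
        signal = (y - y.mean()) / y.std()
    sets = {}
    for i in range(1, n_sets + 1):
        noise = rng.normal(size=n)
        score = signal + 0.3 * noise if i in informative else noise
        sets[i] = _scoreset(score, y, groups, sex, shot_id, task)
    return build_meta_table(sets, sex, y, groups, shot_id)


class TestMetaTable:
    def test_shape_and_columns(self):
        meta = _toy_meta()
        assert meta.shape == (40, 23)
        assert meta.columns[0] == "sex"
        assert list(meta.columns[1:]) == [f"m{i}" for i in range(1, 23)]

    def test_misaligned_scores_rejected(self):
        rng = np.random.default_rng(0)
        y = np.array([0, 1, 0, 1])
        a = _scoreset([0.0] * 4, y, ["g"] * 4, [1] * 4, ["s1", "s2", "s3", "s4"])
        b = _scoreset([0.0] * 4, y, ["g"] * 4, [1] * 4, ["s1", "s2", "s3", "sX"])
        with pytest.raises(ValueError, match="misaligned"):
            build_meta_table({1: a, 2: b}, [1] * 4, y, ["g"] * 4)


class TestAmdeMask:
    def test_closed_form_constant_positive(self):
        """b = 0 collapses the sine to 0, so the mask is sign(d)."""
        assert amde_mask(np.array([0.0, 0.0, 0.0, 1.0])).tolist() == [1] * 22
        assert amde_mask(np.array([0.0, 0.0, 0.0, -1.0])).tolist() == [0] * 22

    def test_closed_form_pure_sine(self):
        """a = 0.05, b = 1, c = d = 0: g(x_k) = sin(2 pi (0.1 k - 0.05)),
        positive exactly for k mod 10 in 1..5.  (The phase shift keeps
        every grid point away from the sine's zeros, where the strict
        g > 0 threshold would be at the mercy of rounding.)"""
        got = amde_mask(np.array([0.05, 1.0, 0.0, 0.0]))
        want = [1 if (k % 10) in (1, 2, 3, 4, 5) else 0 for k in range(1, 23)]
        assert got.tolist() == want

    def test_shift_invariance(self):
        """Shifting a by a full period of the outer argument with c = 0
        and integer b leaves the mask unchanged."""
        p1 = np.array([0.3, 2.0, 0.0, 0.1])
        p2 = p1.copy()
        p2[0] += 0.5  # with b=2, a shift of 0.5 advances the phase by 2 pi
        np.testing.assert_array_equal(amde_mask(p1), amde_mask(p2))

    def test_threshold_is_strict(self):
        # g identically zero (b=0, d=0) selects nothing
        assert amde_mask(np.zeros(4)).sum() == 0


class TestFuse:
    def test_sex_survives_every_mask(self):
        meta = _toy_meta(seed=1)
        mask = np.zeros(22, int)
        mask[0] = 1
        ss, q, crit = fuse(meta, mask, "detect", n_trees=60, random_state=0)
        assert len(ss.score) == len(meta)
        assert np.isfinite(crit) and q >= 1

    def test_empty_mask_rejected(self):
        meta = _toy_meta(seed=2)
        with pytest.raises(ValueError, match="mask"):
            fuse(meta, np.zeros(22, int), "detect")

    def test_informative_mask_beats_noise_mask(self):
        meta = _toy_meta(seed=3)
        good = np.zeros(22, int)
        good[[0, 1]] = 1  # sets 1 and 2 are the planted carriers
        bad = np.zeros(22, int)
        bad[[10, 11]] = 1
        _, _, crit_good = fuse(meta, good, "detect", n_trees=150,
                               q_grid=[2], random_state=0)
        _, _, crit_bad = fuse(meta, bad, "detect", n_trees=150,
                              q_grid=[2], random_state=0)
        assert crit_good < crit_bad

    def test_regression_criterion_is_rmse(self):
        meta = _toy_meta(seed=4, task="regress")
        mask = np.ones(22, int)
        ss, _, crit = fuse(meta, mask, "regress", n_trees=60,
                           q_grid=[3], random_state=0)
        want = float(np.sqrt(np.mean((ss.score - ss.y) ** 2)))
        assert crit == pytest.approx(want)


class TestAmdeFusion:
    def test_trajectory_monotone_and_best_exposed(self):
        meta = _toy_meta(seed=5)
        opt = AmdeFusion(task="detect", np_pop=6, generations=4,
                         n_trees=60, q_grid=[2], random_state=0).fit(meta)
        traj = np.asarray(opt.trajectory_)
        assert (np.diff(traj) <= 1e-12).all()  # elitist: never worsens
        assert opt.best_criterion_ == traj[-1]
        assert opt.best_mask_.sum() >= 1
        assert opt.best_scores_.score.shape == (len(meta),)

    def test_deterministic_for_fixed_seed(self):
        meta = _toy_meta(seed=6)
        kw = dict(task="detect", np_pop=5, generations=3, n_trees=40,
                  q_grid=[2], random_state=7)
        m1 = AmdeFusion(**kw).fit(meta).best_mask_
        m2 = AmdeFusion(**kw).fit(meta).best_mask_
        np.testing.assert_array_equal(m1, m2)


class TestRepeatFusion:
    def test_reports_mean_and_halfwidth(self):
        meta = _toy_meta(seed=8)
        out = repeat_fusion(meta, np.ones(22, int), "detect", n_repeats=4,
                            n_trees=60, q=3, random_state=0)
        assert set(out) == {"cllr", "eer", "auc"}
        for mean, half in out.values():
            assert np.isfinite(mean) and half >= 0.0

    def test_single_repeat_zero_halfwidth(self):
        meta = _toy_meta(seed=9)
        out = repeat_fusion(meta, np.ones(22, int), "detect", n_repeats=1,
                            n_trees=60, q=3, random_state=0)
        assert out["cllr"][1] == 0.0
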