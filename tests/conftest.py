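"""Shared fixtures.

Heavy artifacts (simulated study, segments, feature tables, base-learner
score sets) are session-scoped so the whole suite pays for them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from swingemg.features import build_feature_tables, feature_matrix
from swingemg.forest import GroupedRandomForestClassifier, GroupedRandomForestRegressor
from swingemg.fusion import build_meta_table
from swingemg.io import effectiveness_labels
from swingemg.segmentation import extract_segment
from swingemg.simulate import default_study_config, noiseless_config, simulate

STUDY_SEED = 0


@pytest.fixture(scope="session")
def study():
    """Default 15-subject / 75-shot synthetic study with ground truth."""
    return simulate(default_study_config(seed=STUDY_SEED))


@pytest.fixture(scope="session")
def dataset(study):
    return study[0]


@pytest.fixture(scope="session")
def truth(study):
    return study[1]


@pytest.fixture(scope="session")
def noiseless_study():
    """Same study without baseline noise, pre-swing bumps or onset jitter."""
    return simulate(noiseless_config(seed=STUDY_SEED))


@pytest.fixture(scope="session")
def segments(dataset):
    return {rec.shot_id: extract_segment(rec) for rec in dataset}


@pytest.fixture(scope="session")
def feature_tables(dataset, segments):
    return build_feature_tables(dataset, segments)


@pytest.fixture(scope="session")
def study_arrays(dataset):
    """Aligned label/target/sex/group/shot arrays for the default study."""
    return {
        "labels": effectiveness_labels(dataset, "speed"),
        "speed": np.array([r.speed for r in dataset]),
        "sex": np.array([r.sex for r in dataset]),
        "groups": np.array(dataset.subject_ids),
        "shot_ids": np.array(dataset.shot_ids),
    }


@pytest.fixture(scope="session")
def base_scores(feature_tables, study_arrays):
    """Per-set OOB score sets at the desk ensemble size (B = 500)."""
    det, reg = {}, {}
    for i, table in feature_tables.items():
        X, _ = feature_matrix(table)
        q = int(np.ceil(np.sqrt(X.shape[1])))
        clf = GroupedRandomForestClassifier(
            n_trees=500, q=q, random_state=100 + i
        ).fit(X, study_arrays["labels"], groups=study_arrays["groups"],
              sex=study_arrays["sex"])
        det[i] = clf.oob_score_set(
            shot_id=study_arrays["shot_ids"], sex=study_arrays["sex"])
        rgr = GroupedRandomForestRegressor(
            n_trees=500, q=q, stratify_sex=False, random_state=200 + i
        ).fit(X, study_arrays["speed"], groups=study_arrays["groups"])
        reg[i] = rgr.oob_score_set(
            shot_id=study_arrays["shot_ids"], sex=study_arrays["sex"])
    return det, reg


@pytest.fixture(scope="session")
def meta_tables(base_scores, study_arrays):
    det, reg = base_scores
    a = study_arrays
    meta_det = build_meta_table(det, a["sex"], a["labels"], a["groups"],
                                a["shot_ids"])
    meta_reg = build_meta_table(reg, a["sex"], a["speed"], a["groups"],
                                a["shot_ids"])
    return meta_det, meta_reg
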