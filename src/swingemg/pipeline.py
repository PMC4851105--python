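"""End-to-end driver: simulate/ingest -> preprocess -> profile -> segment
-> features -> per-set forests -> fusion -> evaluation.

A single global seed is expanded into independent per-stage seeds with
``numpy.random.SeedSequence`` so stages stay individually reproducible.
Artifacts are written under one run directory together with a JSON
manifest (config snapshot, seeds, per-stage timing).
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from swingemg.features import build_feature_tables, feature_matrix
from swingemg.forest import q_grid_search
from swingemg.fusion import AmdeFusion, build_meta_table, repeat_fusion
from swingemg.io import ShotDataset, effectiveness_labels
from swingemg.metrics import detection_report, naive_baseline, regression_metrics
from swingemg.onset import activation_profile, profile_map
from swingemg.segmentation import extract_segment
from swingemg.simulate import SimConfig, default_study_config, simulate


def stage_seeds(seed: int, n: int = 8) -> list[int]:
    """Expand one global seed into independent per-stage seeds (< 2^31)."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


def load_config(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    known = {"data", "filter", "onset", "segment", "features", "forest",
             "fusion", "eval", "seed", "target", "task"}
    unknown = set(cfg) - known
    if unknown:
        raise ValueError(f"unknown config section(s): {sorted(unknown)}")
    return cfg


def run_all(
    out_dir: str | Path,
    seed: int = 0,
    target: str = "speed",
    n_trees: int = 500,
    sim_config: SimConfig | None = None,
    dataset: ShotDataset | None = None,
    optimize_fusion: bool = True,
    n_repeats: int = 0,
) -> dict:
    """Run the full chain on a dataset (simulated by default).

    Returns the report dict that is also written to ``report.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(seed)
    manifest: dict = {"seed": seed, "stage_seeds": seeds, "target": target,
                      "timing": {}}
    t0 = time.time()

    if dataset is None:
        cfg = sim_config or default_study_config(seed=seeds[0])
        dataset, truth = simulate(cfg)
        manifest["sim_config"] = {
            k: v for k, v in asdict(cfg).items() if not isinstance(v, np.ndarray)
        }
    manifest["n_shots"] = len(dataset)
    manifest["timing"]["data"] = time.time() - t0

    # activation profiles
    t0 = time.time()
    profiles = [activation_profile(rec)[1] for rec in dataset]
    profile_map(profiles).to_csv(out / "profiles.csv", index=False)
    manifest["timing"]["profiles"] = time.time() - t0

    # segmentation + features
    t0 = time.time()
    segments = {rec.shot_id: extract_segment(rec) for rec in dataset}
    tables = build_feature_tables(dataset, segments)
    manifest["timing"]["features"] = time.time() - t0

    # per-set base learners
    t0 = time.time()
    labels = effectiveness_labels(dataset, target)
    targets = np.array([getattr(r, target) for r in dataset], dtype=float)
    sex = np.array([r.sex for r in dataset])
    groups = np.array(dataset.subject_ids)
    shot_ids = np.array(dataset.shot_ids)
    det_scores, reg_scores = {}, {}
    for i, table in tables.items():
        X, _ = feature_matrix(table)
        _, _, forest = q_grid_search(
            X, labels, groups, sex=sex, task="detect",
            grid=[int(np.ceil(np.sqrt(X.shape[1])))],
            n_trees=n_trees, random_state=seeds[1] + i,
        )
        det_scores[i] = forest.oob_score_set(shot_id=shot_ids, sex=sex)
        _, _, forest = q_grid_search(
            X, targets, groups, task="regress",
            grid=[int(np.ceil(np.sqrt(X.shape[1])))],
            n_trees=n_trees, random_state=seeds[2] + i,
        )
        reg_scores[i] = forest.oob_score_set(shot_id=shot_ids, sex=sex)
    manifest["timing"]["base_learners"] = time.time() - t0

    # fusion
    t0 = time.time()
    report: dict = {"target": target, "n_shots": len(dataset)}
    for task, scores, y in (
        ("detect", det_scores, labels),
        ("regress", reg_scores, targets),
    ):
        meta = build_meta_table(scores, sex, y, groups, shot_ids)
        if optimize_fusion:
            opt = AmdeFusion(task=task, n_trees=max(100, n_trees // 4),
                             random_state=seeds[3]).fit(meta)
            mask, ss = opt.best_mask_, opt.best_scores_
            report[f"{task}_mask"] = mask.tolist()
            report[f"{task}_q"] = int(opt.best_q_)
        else:
            from swingemg.fusion import fuse

            mask = np.ones(len(scores), dtype=int)
            ss, q, _ = fuse(meta, mask, task, n_trees, None, seeds[3])
            report[f"{task}_q"] = int(q)
        if task == "detect":
            rep = detection_report(ss.score, ss.y)
            report["detection"] = {"cllr": rep.cllr, "eer": rep.eer, "auc": rep.auc}
        else:
            report["regression"] = regression_metrics(ss.score, ss.y)
            report["regression_baseline"] = naive_baseline(sex, targets)
        if n_repeats > 1:
            report[f"{task}_repeats"] = {
                k: list(v)
                for k, v in repeat_fusion(
                    meta, mask, task, n_repeats, n_trees,
                    random_state=seeds[4],
                ).items()
            }
    manifest["timing"]["fusion"] = time.time() - t0

    (out / "report.json").write_text(json.dumps(report, indent=2))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return report
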