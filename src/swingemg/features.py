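"""The 22 registered EMG feature sets.

Every feature vector starts with sex (0 woman, 1 man).  The sets fall in
four families:

* channel statistics and correlations (sets 1-6): swing duration plus a
  12-statistic summary of each body-side channel's filtered samples over
  the swing window, and Pearson-vs-Spearman correlation contrasts for the
  28 channel pairs;
* properties of the first peak P1 (sets 7-9) and of the second peak P2
  (sets 10-12): the five peak properties per channel, and pairwise peak
  synchrony (signed or absolute relative-position differences);
* properties of both peaks (sets 13-22): property contrasts between P1
  and P2, and the P1/P2 synchrony values combined pairwise by the basic
  arithmetic operations.

The 12 summary statistics of a sample are: minimum, maximum, mean,
median, lower quartile, upper quartile, standard deviation, inter-quartile
range, lower range (median - Qlo), upper range (Qup - median), skewness
and kurtosis (standardized 3rd/4th central moments; kurtosis is not
excess).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats as sps

from swingemg.io import N_CHANNELS, ShotDataset
from swingemg.segmentation import SwingSegment

#: denominator guard for the ratio-style sets
_DIV_EPS = 1e-9

STAT_NAMES = (
    "min", "max", "mean", "median", "q_lower", "q_upper",
    "std", "iqr", "range_lower", "range_upper", "skewness", "kurtosis",
)

#: 1-based channel numbers per body side (right = 1,2,5,6; left = 3,4,7,8)
RIGHT_SIDE = (1, 2, 5, 6)
LEFT_SIDE = (3, 4, 7, 8)

PEAK_PROPS = ("rel_position", "height", "width", "area", "fit_error")

_PAIRS = list(combinations(range(1, N_CHANNELS + 1), 2))


def stat_vector(sample: np.ndarray) -> dict[str, float]:
    """The 12 named summary statistics of a sample (>= 4 values).

    Standard deviation uses the n-1 denominator; quartiles use linear
    interpolation.  For a constant sample the sd-normalized moments
    (skewness, kurtosis) are defined as 0.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 values for the statistic vector")
    q_lo, med, q_up = np.percentile(x, [25.0, 50.0, 75.0])
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        skew, kurt = 0.0, 0.0
    else:
        skew = float(sps.skew(x, bias=True))
        kurt = float(sps.kurtosis(x, bias=True, fisher=False))
    return {
        "min": float(x.min()),
        "max": float(x.max()),
        "mean": float(x.mean()),
        "median": float(med),
        "q_lower": float(q_lo),
        "q_upper": float(q_up),
        "std": sd,
        "iqr": float(q_up - q_lo),
        "range_lower": float(med - q_lo),
        "range_upper": float(q_up - med),
        "skewness": skew,
        "kurtosis": kurt,
    }


def _window_samples(seg: SwingSegment, channel: int) -> np.ndarray:
    if seg.filtered is None:
        raise ValueError("segment carries no filtered signal matrix")
    return seg.filtered[channel - 1, seg.window_slice()]


def _guarded_div(num: float, den: float) -> float:
    if abs(den) < _DIV_EPS:
        return 0.0
    return num / den


def chan_stats(seg: SwingSegment, side: str) -> dict[str, float]:
    """Swing duration plus the 12 statistics of each side channel's
    filtered swing-window samples (1 + 4 x 12 = 49 features)."""
    channels = {"right": RIGHT_SIDE, "left": LEFT_SIDE}[side]
    out = {"duration": seg.duration}
    for ch in channels:
        stats = stat_vector(_window_samples(seg, ch))
        out.update({f"ch{ch}_{k}": v for k, v in stats.items()})
    return out


def corr_features(seg: SwingSegment, mode: str, with_stats: bool) -> dict[str, float]:
    """Pearson-vs-Spearman contrast per channel pair (28 values), plus
    optionally the 12 statistics of the 28 values (40 total)."""
    window = {ch: _window_samples(seg, ch) for ch in range(1, N_CHANNELS + 1)}
    out: dict[str, float] = {}
    for i, j in _PAIRS:
        xi, xj = window[i], window[j]
        if xi.std() == 0 or xj.std() == 0:
            raise ValueError(f"zero-variance channel in pair ({i},{j})")
        pearson = float(np.corrcoef(xi, xj)[0, 1])
        spearman = float(sps.spearmanr(xi, xj).statistic)
        if mode == "delta":
            out[f"corr_d_{i}_{j}"] = pearson - spearman
        else:
            out[f"corr_r_{i}_{j}"] = _guarded_div(pearson, spearman)
    if with_stats:
        out.update({f"stat_{k}": v
                    for k, v in stat_vector(np.array(list(out.values()))).items()})
    return out


def _peak_pair(seg: SwingSegment, ch: int):
    try:
        return seg.peaks[ch]
    except KeyError:
        raise ValueError(f"channel {ch} has no peak pair") from None


def peak_property_features(seg: SwingSegment, which: str) -> dict[str, float]:
    """The 5 peak properties per channel (5 x 8 = 40 features).

    ``which`` selects P1, P2, their difference (P1 - P2) or their
    guarded ratio (P1 / P2).
    """
    out: dict[str, float] = {}
    for ch in range(1, N_CHANNELS + 1):
        p1, p2 = _peak_pair(seg, ch)
        for prop in PEAK_PROPS:
            v1, v2 = getattr(p1, prop), getattr(p2, prop)
            if which == "P1":
                out[f"p1_{prop}_ch{ch}"] = v1
            elif which == "P2":
                out[f"p2_{prop}_ch{ch}"] = v2
            elif which == "delta":
                out[f"pk_d_{prop}_ch{ch}"] = v1 - v2
            else:
                out[f"pk_r_{prop}_ch{ch}"] = _guarded_div(v1, v2)
    return out


def _sync_values(seg: SwingSegment, rank: str, absolute: bool) -> dict[str, float]:
    """Pairwise relative-position differences (lower-index minus higher)."""
    k = 0 if rank == "P1" else 1
    pos = {ch: _peak_pair(seg, ch)[k].rel_position for ch in range(1, N_CHANNELS + 1)}
    vals = {}
    for i, j in _PAIRS:
        d = pos[i] - pos[j]
        vals[f"{i}_{j}"] = abs(d) if absolute else d
    return vals


def sync_features(seg: SwingSegment, rank: str, absolute: bool) -> dict[str, float]:
    """Peak-position concurrency per pair for one peak rank, plus the 12
    statistics of the 28 values (28 + 12 = 40)."""
    tag = "a" if absolute else "s"
    vals = _sync_values(seg, rank, absolute)
    out = {f"sync{tag}_{rank}_{key}": v for key, v in vals.items()}
    out.update({f"stat_{k}": v
                for k, v in stat_vector(np.array(list(vals.values()))).items()})
    return out


_COMBINE: dict[str, Callable[[float, float], float]] = {
    "delta": lambda a, b: a - b,
    "sum": lambda a, b: a + b,
    "prod": lambda a, b: a * b,
    "div": _guarded_div,
}


def sync_combo_features(seg: SwingSegment, op: str, absolute: bool) -> dict[str, float]:
    """P1 and P2 concurrency values combined pairwise by an arithmetic
    operation, plus the 12 statistics of the 28 results (40 total)."""
    v1 = _sync_values(seg, "P1", absolute)
    v2 = _sync_values(seg, "P2", absolute)
    fn = _COMBINE[op]
    tag = "a" if absolute else "s"
    vals = {key: fn(v1[key], v2[key]) for key in v1}
    out = {f"combo{tag}_{op}_{key}": v for key, v in vals.items()}
    out.update({f"stat_{k}": v
                for k, v in stat_vector(np.array(list(vals.values()))).items()})
    return out


@dataclass(frozen=True)
class FeatureSetSpec:
    """One registered feature set: id, name, size (excluding sex), builder."""

    id: int
    name: str
    size: int
    builder: Callable[[SwingSegment], dict[str, float]]


FEATURE_SET_REGISTRY: dict[int, FeatureSetSpec] = {
    spec.id: spec
    for spec in [
        FeatureSetSpec(1, "RightChanStats", 49, lambda s: chan_stats(s, "right")),
        FeatureSetSpec(2, "LeftChanStats", 49, lambda s: chan_stats(s, "left")),
        FeatureSetSpec(3, "CorrDelta", 28, lambda s: corr_features(s, "delta", False)),
        FeatureSetSpec(4, "CorrRatio", 28, lambda s: corr_features(s, "ratio", False)),
        FeatureSetSpec(5, "StatsCorrDelta", 40, lambda s: corr_features(s, "delta", True)),
        FeatureSetSpec(6, "StatsCorrRatio", 40, lambda s: corr_features(s, "ratio", True)),
        FeatureSetSpec(7, "PeakP1", 40, lambda s: peak_property_features(s, "P1")),
        FeatureSetSpec(8, "PeakP1Sync", 40, lambda s: sync_features(s, "P1", False)),
        FeatureSetSpec(9, "PeakP1AbsSync", 40, lambda s: sync_features(s, "P1", True)),
        FeatureSetSpec(10, "PeakP2", 40, lambda s: peak_property_features(s, "P2")),
        FeatureSetSpec(11, "PeakP2Sync", 40, lambda s: sync_features(s, "P2", False)),
        FeatureSetSpec(12, "PeakP2AbsSync", 40, lambda s: sync_features(s, "P2", True)),
        FeatureSetSpec(13, "PeakDelta", 40, lambda s: peak_property_features(s, "delta")),
        FeatureSetSpec(14, "PeakRatio", 40, lambda s: peak_property_features(s, "ratio")),
        FeatureSetSpec(15, "PeakSyncDelta", 40, lambda s: sync_combo_features(s, "delta", False)),
        FeatureSetSpec(16, "PeakSyncSum", 40, lambda s: sync_combo_features(s, "sum", False)),
        FeatureSetSpec(17, "PeakSyncProd", 40, lambda s: sync_combo_features(s, "prod", False)),
        FeatureSetSpec(18, "PeakSyncDiv", 40, lambda s: sync_combo_features(s, "div", False)),
        FeatureSetSpec(19, "PeakAbsSyncDelta", 40, lambda s: sync_combo_features(s, "delta", True)),
        FeatureSetSpec(20, "PeakAbsSyncSum", 40, lambda s: sync_combo_features(s, "sum", True)),
        FeatureSetSpec(21, "PeakAbsSyncProd", 40, lambda s: sync_combo_features(s, "prod", True)),
        FeatureSetSpec(22, "PeakAbsSyncDiv", 40, lambda s: sync_combo_features(s, "div", True)),
    ]
}


def build_feature_table(
    ds: ShotDataset,
    segments: dict[str, SwingSegment],
    set_id: int,
    with_targets: bool = True,
) -> pd.DataFrame:
    """One feature table for a registered set: rows = shots, sex first,
    then the named features, then target columns.

    Shots whose builder fails are dropped (their shot_ids are recorded in
    ``df.attrs['dropped']``).
    """
    spec = FEATURE_SET_REGISTRY[set_id]
    rows, index, dropped = [], [], []
    meta = []
    for rec in ds:
        seg = segments[rec.shot_id]
        try:
            feats = spec.builder(seg)
        except ValueError as exc:
            dropped.append((rec.shot_id, str(exc)))
            continue
        if len(feats) != spec.size:
            raise RuntimeError(
                f"{spec.name}: built {len(feats)} features, expected {spec.size}"
            )
        rows.append({"sex": float(rec.sex), **feats})
        index.append(rec.shot_id)
        meta.append((rec.subject_id, rec.speed, rec.distance))
    df = pd.DataFrame(rows, index=pd.Index(index, name="shot_id"))
    df.attrs["dropped"] = dropped
    df.attrs["set_name"] = spec.name
    df.attrs["subject_id"] = [m[0] for m in meta]
    if with_targets:
        df["speed"] = [m[1] for m in meta]
        df["distance"] = [m[2] for m in meta]
    return df


def build_feature_tables(
    ds: ShotDataset, segments: dict[str, SwingSegment]
) -> dict[int, pd.DataFrame]:
    """All 22 registered feature tables."""
    return {i: build_feature_table(ds, segments, i) for i in FEATURE_SET_REGISTRY}


def feature_matrix(df: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Predictor matrix (sex + features, targets stripped) and its names."""
    cols = [c for c in df.columns if c not in ("speed", "distance")]
    return df[cols].to_numpy(dtype=float), cols
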