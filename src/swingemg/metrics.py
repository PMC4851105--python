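"""Goodness-of-detection and regression metrics.

Detection scores are calibrated with the pool-adjacent-violators (PAV)
algorithm — equivalent to the ROC convex hull — into monotone
log-likelihood ratios; the cost of the log-likelihood ratio (Cllr, bits)
is then the average of the two proper scoring terms.  A useful,
well-calibrated detector has Cllr < 1, EER < 50% and AUC > 0.5; Cllr = 1
is the uninformative reference.  The equal error rate is read off the ROC
convex hull with linear interpolation, and AUC is the normalized
Mann-Whitney statistic with ties counted half.

Regression is summarized by RMSE, MAPE (%) and Pearson correlation, with
a naive reference predictor that outputs the sex-specific average.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

#: LLR magnitude cap (nats) so separable score sets report finite values
LLR_CAP = 15.0


def _check_two_classes(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("need both classes (labels 0 and 1) present")
    return labels


def pav_posteriors(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Isotonic (PAV) posterior of class 1 given the score, per shot.

    Classic stack-based pool-adjacent-violators on the label means after
    sorting by score; tied scores are merged first so equal scores get
    equal posteriors.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_two_classes(labels)
    order = np.argsort(scores, kind="stable")
    s_sorted, y_sorted = scores[order], labels[order]
    # merge tied scores into blocks
    blocks: list[list[float]] = []  # [sum_y, weight]
    uniq, start = [], 0
    while start < len(s_sorted):
        end = start
        while end + 1 < len(s_sorted) and s_sorted[end + 1] == s_sorted[start]:
            end += 1
        blocks.append([float(y_sorted[start : end + 1].sum()), float(end - start + 1)])
        uniq.append((start, end))
        start = end + 1
    # PAV: merge adjacent blocks while means decrease
    stack: list[list[float]] = []
    spans: list[list[int]] = []
    for (b, (lo, hi)) in zip(blocks, uniq):
        stack.append(list(b))
        spans.append([lo, hi])
        while len(stack) > 1 and (
            stack[-2][0] / stack[-2][1] >= stack[-1][0] / stack[-1][1]
        ):
            s2, s1 = stack.pop(), stack.pop()
            stack.append([s1[0] + s2[0], s1[1] + s2[1]])
            sp2, sp1 = spans.pop(), spans.pop()
            spans.append([sp1[0], sp2[1]])
    fitted = np.empty(len(s_sorted))
    for (b, (lo, hi)) in zip(stack, spans):
        fitted[lo : hi + 1] = b[0] / b[1]
    out = np.empty(len(scores))
    out[order] = fitted
    return out


def rocch_llr(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Calibrated log-likelihood ratios via the ROC convex hull (PAV).

    The mapping is monotone (order-preserving) in the score; LLRs are
    capped at +-15 nats so perfectly separated sets stay finite.
    """
    labels = _check_two_classes(labels)
    p = pav_posteriors(scores, labels)
    prior = labels.mean()
    prior_logit = np.log(prior / (1.0 - prior))
    with np.errstate(divide="ignore"):
        post_logit = np.log(p) - np.log1p(-p)
    llr = post_logit - prior_logit
    return np.clip(llr, -LLR_CAP, LLR_CAP)


def cllr(scores: np.ndarray, labels: np.ndarray) -> float:
    """Minimum cost of the log-likelihood ratio (bits), on PAV-calibrated
    LLRs: 0 for perfect separation, 1 for an uninformative detector."""
    labels = _check_two_classes(labels)
    llr = rocch_llr(scores, labels)
    tar, non = llr[labels == 1], llr[labels == 0]
    c_tar = np.mean(np.log2(1.0 + np.exp(-tar)))
    c_non = np.mean(np.log2(1.0 + np.exp(non)))
    return float(0.5 * (c_tar + c_non))


def _rocch_points(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """ROC convex hull operating points as (pfa, pmiss) rows.

    Built from the PAV blocks: each distinct calibrated posterior value is
    one hull vertex, swept from the strictest to the laxest threshold.
    """
    labels = _check_two_classes(labels)
    p = pav_posteriors(scores, labels)
    n_tar = labels.sum()
    n_non = len(labels) - n_tar
    pts = [(0.0, 1.0)]
    for level in sorted(np.unique(p))[::-1]:
        sel = p >= level
        tp = int((labels[sel] == 1).sum())
        fp = int((labels[sel] == 0).sum())
        pts.append((fp / n_non, 1.0 - tp / n_tar))
    pts.append((1.0, 0.0))
    return np.array(pts)


def det_eer(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, float]:
    """DET operating points on the convex hull and the equal error rate.

    EER (in %) is where the miss rate equals the false-alarm rate,
    linearly interpolated between adjacent hull points.
    """
    pts = _rocch_points(scores, labels)
    diff = pts[:, 1] - pts[:, 0]  # pmiss - pfa, decreasing along the sweep
    for k in range(1, len(pts)):
        if diff[k] <= 0.0:
            if diff[k] == diff[k - 1]:
                eer = pts[k, 0]
            else:
                w = diff[k - 1] / (diff[k - 1] - diff[k])
                eer = pts[k - 1, 0] + w * (pts[k, 0] - pts[k - 1, 0])
            # interpolate pmiss too; at the crossing both rates are equal
            return pts, float(eer * 100.0)
    return pts, 50.0


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, float]:
    """ROC points and AUC (Mann-Whitney with ties counted half)."""
    labels = _check_two_classes(labels)
    scores = np.asarray(scores, dtype=float)
    ranks = sps.rankdata(scores)
    n1 = labels.sum()
    n0 = len(labels) - n1
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    auc = float(u / (n1 * n0))
    pts = _rocch_points(scores, labels)
    roc = np.column_stack([pts[:, 0], 1.0 - pts[:, 1]])  # (fpr, tpr)
    return roc, auc


@dataclass
class DetectionReport:
    """Cllr (bits), EER (%), AUC and the DET/ROC operating points."""

    cllr: float
    eer: float
    auc: float
    det_curve: np.ndarray = field(repr=False, default=None)
    roc_curve: np.ndarray = field(repr=False, default=None)


def detection_report(scores: np.ndarray, labels: np.ndarray) -> DetectionReport:
    det, eer = det_eer(scores, labels)
    roc, auc = roc_auc(scores, labels)
    return DetectionReport(
        cllr=cllr(scores, labels), eer=eer, auc=auc, det_curve=det, roc_curve=roc
    )


def regression_metrics(pred: np.ndarray, actual: np.ndarray) -> dict[str, float]:
    """RMSE (target units), MAPE (%) and Pearson correlation."""
    pred = np.asarray(pred, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if pred.size < 2 or pred.size != actual.size:
        raise ValueError("need n >= 2 paired values")
    if (actual == 0).any():
        raise ValueError("MAPE undefined for zero actual values")
    rmse = float(np.sqrt(np.mean((pred - actual) ** 2)))
    mape = float(100.0 * np.mean(np.abs(pred - actual) / np.abs(actual)))
    if np.std(pred) == 0 or np.std(actual) == 0:
        corr = float("nan")  # degenerate: correlation undefined
    else:
        corr = float(np.corrcoef(pred, actual)[0, 1])
    return {"rmse": rmse, "mape": mape, "corr": corr}


@dataclass
class RegressionReport:
    """Model metrics next to the naive sex-average reference."""

    rmse: float
    mape: float
    corr: float
    baseline: dict[str, float] | None = None


def naive_baseline(sex: np.ndarray, actual: np.ndarray) -> dict[str, float]:
    """Metrics of the naive predictor that outputs the full-sample
    sex-specific average for every shot."""
    sex = np.asarray(sex).astype(int)
    actual = np.asarray(actual, dtype=float)
    pred = np.empty_like(actual)
    for s in np.unique(sex):
        pred[sex == s] = actual[sex == s].mean()
    return regression_metrics(pred, actual)


def regression_report(
    pred: np.ndarray, actual: np.ndarray, sex: np.ndarray | None = None
) -> RegressionReport:
    m = regression_metrics(pred, actual)
    baseline = naive_baseline(sex, actual) if sex is not None else None
    return RegressionReport(m["rmse"], m["mape"], m["corr"], baseline)
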