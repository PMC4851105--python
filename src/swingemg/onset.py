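"""Multiscale Gaussian onset detection and activation-sequence profiling.

The rectified signal of each channel is smoothed by four sliding Gaussian
filters of increasing width (256, 512, 1024, 2048 samples).  A per-channel
threshold is the scaled mean of the rectified signal around the coarsest
envelope's maximum.  The activation onset is located from the threshold
crossings of the three coarser envelopes and the steepest rise of the
finest one.  Onset-time differences of channels 1-7 relative to channel 8
(left trapezius) form the muscle-activation profile of a shot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import convolve1d

from swingemg.io import N_CHANNELS, REFERENCE_CHANNEL, EmgRecording
from swingemg.preprocessing import rectify

DEFAULT_WIDTHS = (256, 512, 1024, 2048)


@dataclass(frozen=True)
class GaussianBank:
    """Bank of unit-area Gaussian kernels; sigma = width / 6 so each
    window spans +-3 sigma."""

    widths: tuple[int, ...] = DEFAULT_WIDTHS

    def __post_init__(self) -> None:
        w = self.widths
        if any(b <= a for a, b in zip(w, w[1:])):
            raise ValueError("widths must be strictly increasing")

    def kernels(self) -> list[np.ndarray]:
        out = []
        for width in self.widths:
            sigma = width / 6.0
            half = width // 2
            x = np.arange(-half, half + 1)
            k = np.exp(-0.5 * (x / sigma) ** 2)
            out.append(k / k.sum())
        return out


def multiscale_filter(
    rectified: np.ndarray, bank: GaussianBank | None = None
) -> list[np.ndarray]:
    """Smooth a rectified channel with each kernel of the bank.

    Returns the four same-length series v1..v4 (finest to coarsest);
    convolution is centered (zero lag) with reflective edge padding.
    """
    if bank is None:
        bank = GaussianBank()
    rectified = np.asarray(rectified, dtype=float)
    if rectified.shape[-1] <= max(bank.widths):
        raise ValueError(
            f"signal length {rectified.shape[-1]} must exceed the largest "
            f"filter width {max(bank.widths)}"
        )
    return [convolve1d(rectified, k, mode="reflect") for k in bank.kernels()]


def channel_threshold(
    rectified: np.ndarray,
    v4: np.ndarray,
    alpha: float = 1.2,
    delta: int = 500,
) -> float:
    """Activation threshold: ``alpha`` times the mean rectified amplitude
    over ``[t* - delta, t* + 2 delta]`` where t* is the coarsest
    envelope's maximum.  The window is clipped to the record bounds and
    the mean taken over the samples actually present."""
    rectified = np.asarray(rectified, dtype=float)
    t_star = int(np.argmax(v4))
    lo = max(0, t_star - delta)
    hi = min(len(rectified), t_star + 2 * delta + 1)
    return float(alpha * rectified[lo:hi].mean())


def _last_crossing_before_max(v: np.ndarray, threshold: float) -> int | None:
    """Last upward crossing of ``threshold`` at or before the global max."""
    m = int(np.argmax(v))
    if v[m] < threshold:
        return None
    upward = np.flatnonzero((v[1 : m + 1] >= threshold) & (v[:m] < threshold)) + 1
    if upward.size == 0:
        # above threshold from the very start
        return 0 if v[0] >= threshold else None
    return int(upward[-1])


def detect_onset(
    rectified: np.ndarray,
    vs: list[np.ndarray],
    threshold: float,
    search_width: int = 256,
) -> int:
    """Locate the start of swing-related activation in one channel.

    The last upward threshold crossings preceding the global maximum of
    the three coarser envelopes (v2-v4) anchor a search window
    ``[min(c) - W, max(c)]``; the onset is the steepest rise (argmax of
    the first difference) of the finest envelope v1 inside it.  Envelopes
    that never cross the threshold are skipped; if none cross, the
    channel has no detectable activation.
    """
    v1 = vs[0]
    crossings = [
        c
        for v in vs[1:]
        if (c := _last_crossing_before_max(np.asarray(v), threshold)) is not None
    ]
    if not crossings:
        raise ValueError("no activation: no envelope crosses the threshold")
    lo = max(1, min(crossings) - search_width)
    hi = min(len(v1) - 1, max(crossings))
    if hi < lo:
        hi = lo
    dv1 = np.diff(v1)
    # dv1[t] is the rise from t to t+1; search window [lo, hi] on t
    return int(lo + np.argmax(dv1[lo : hi + 1]))


@dataclass
class OnsetResult:
    """Per-shot onset detection output."""

    ts: np.ndarray          # (8,) onset sample indices
    thresholds: np.ndarray  # (8,) channel thresholds
    lam: float              # max |ts8 - tsi| over i=1..7, samples
    flagged: bool = False


@dataclass
class ActivationProfile:
    """Onset-time differences x_i = ts8 - tsi (ms), channels 1..7."""

    x: np.ndarray
    subject_id: str = ""
    shot_id: str = ""


def activation_profile(
    rec: EmgRecording,
    bank: GaussianBank | None = None,
    alpha: float = 1.2,
    delta: int = 500,
    lambda_min: float | None = None,
    lambda_max: float | None = None,
) -> tuple[OnsetResult, ActivationProfile]:
    """Detect all eight channel onsets and build the activation profile.

    Positive profile components mean the channel activated before the
    reference (channel 8, left trapezius).  ``flagged`` is set when the
    maximum reference-vs-other onset gap lies outside [lambda_min,
    lambda_max] (samples); pass None to skip flagging.
    """
    ts = np.empty(N_CHANNELS)
    thresholds = np.empty(N_CHANNELS)
    for ch in range(N_CHANNELS):
        rect = rectify(rec.signal[ch])
        vs = multiscale_filter(rect, bank)
        try:
            thresholds[ch] = channel_threshold(rect, vs[3], alpha, delta)
            ts[ch] = detect_onset(rect, vs, thresholds[ch])
        except ValueError as exc:
            raise ValueError(f"shot {rec.shot_id!r}, channel {ch + 1}: {exc}") from exc
    lam = float(np.max(np.abs(ts[REFERENCE_CHANNEL] - np.delete(ts, REFERENCE_CHANNEL))))
    flagged = False
    if lambda_min is not None and lam < lambda_min:
        flagged = True
    if lambda_max is not None and lam > lambda_max:
        flagged = True
    x_ms = (ts[REFERENCE_CHANNEL] - ts[:REFERENCE_CHANNEL]) * 1000.0 / rec.fs
    return (
        OnsetResult(ts=ts, thresholds=thresholds, lam=lam, flagged=flagged),
        ActivationProfile(x=x_ms, subject_id=rec.subject_id, shot_id=rec.shot_id),
    )


def profile_map(profiles: list[ActivationProfile]) -> pd.DataFrame:
    """Per-shot profile matrix ordered by subject, for plotting/export.

    Columns: subject_id, shot_id, x1..x7.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    rows = [
        {"subject_id": p.subject_id, "shot_id": p.shot_id,
         **{f"x{i + 1}": p.x[i] for i in range(len(p.x))}}
        for p in profiles
    ]
    df = pd.DataFrame(rows)
    return df.sort_values(["subject_id", "shot_id"], kind="stable").reset_index(drop=True)


def lambda_bounds(lams: np.ndarray, lo_pct: float = 2.5, hi_pct: float = 97.5):
    """Dataset-level flagging bounds: percentiles of the observed gaps."""
    lams = np.asarray(lams, dtype=float)
    return float(np.percentile(lams, lo_pct)), float(np.percentile(lams, hi_pct))
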