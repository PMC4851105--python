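"""Two-peak swing-segment extraction from the filtered envelopes.

Per channel, peaks of the filtered signal are found by Gaussian smoothing
and derivative zero-crossings, refined by a local log-Gaussian parabola
fit; the two highest are labeled P1/P2 in order of appearance.  Pooled
peak positions are pruned by the Tukey box-plot rule (1.5 IQR fences) and
the swing window [t1, t2] is spanned by the marginal peaks: t1 is the
earliest retained P1 minus half its width, t2 the latest retained P2 plus
half its width.  Peak positions are finally re-expressed relative to the
swing duration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from swingemg.io import N_CHANNELS, EmgRecording
from swingemg.preprocessing import FilterSpec, preprocess_recording

#: Gaussian peak area factor: integral of a Gaussian = 1.0646 * height * FWHM
GAUSS_AREA_FACTOR = 1.0646
_FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class PeakDescriptor:
    """One refined peak of a channel's filtered envelope."""

    position: float      # seconds, sub-sample
    height: float
    width: float         # FWHM, seconds
    area: float          # height * width * 1.0646
    fit_error: float     # RMS residual of the local Gaussian fit, % of height
    channel: int         # 1-8
    rank: str = ""       # "P1" or "P2" once assigned
    rel_position: float = np.nan  # fraction of swing duration


@dataclass
class SwingSegment:
    """Extracted swing window with per-channel P1/P2 descriptors."""

    t1: float
    t2: float
    peaks: dict[int, tuple[PeakDescriptor, PeakDescriptor]]  # channel -> (P1, P2)
    excluded_p1: list[int] = field(default_factory=list)
    excluded_p2: list[int] = field(default_factory=list)
    iterations: int = 1
    shot_id: str = ""
    filtered: np.ndarray | None = None  # 8 x T filtered matrix
    fs: float = 1000.0

    @property
    def duration(self) -> float:
        return self.t2 - self.t1

    def window_slice(self) -> slice:
        lo = int(round(self.t1 * self.fs))
        hi = int(round(self.t2 * self.fs))
        return slice(max(0, lo), hi)


def find_peaks(
    filtered: np.ndarray, fs: float, peak_density: float = 2.0
) -> list[PeakDescriptor]:
    """Detect and refine all peaks of a filtered channel.

    The signal is smoothed with a moving Gaussian of window
    ``w = max(3, round(T / (50 * peak_density)))``; candidates are
    downward zero-crossings of the smoothed first difference whose
    smoothed height exceeds 5% of the global maximum.  Each candidate is
    refined by a least-squares parabola fit to the log of the samples
    above half its height, yielding a sub-sample position, height and
    FWHM width.
    """
    y = np.asarray(filtered, dtype=float)
    n = y.size
    w = max(3, int(round(n / (50.0 * peak_density))))
    if n <= w:
        raise ValueError("signal shorter than the smoothing window")
    sm = gaussian_filter1d(y, sigma=w / 6.0, mode="reflect")
    d = np.diff(sm)
    # candidate peak at i where the slope turns from positive to <= 0
    idx = np.flatnonzero((d[:-1] > 0) & (d[1:] <= 0)) + 1
    floor = 0.05 * sm.max()
    idx = idx[sm[idx] > floor]
    if idx.size == 0:
        raise ValueError("no peaks detected")
    peaks = []
    for i in idx:
        peaks.append(_refine_peak(sm, int(i), fs))
    return peaks


def _refine_peak(sm: np.ndarray, i: int, fs: float) -> PeakDescriptor:
    """Gaussian refinement by a parabola fit to log(y) around sample i."""
    half = sm[i] / 2.0
    lo = i
    while lo > 0 and sm[lo - 1] > half:
        lo -= 1
    hi = i
    while hi < len(sm) - 1 and sm[hi + 1] > half:
        hi += 1
    if hi - lo < 2:
        lo, hi = max(0, i - 1), min(len(sm) - 1, i + 1)
    xs = np.arange(lo, hi + 1, dtype=float)
    ys = sm[lo : hi + 1]
    pos_mask = ys > 0
    if pos_mask.sum() < 3:
        # degenerate: fall back to the raw sample peak, 1-sample width
        h = float(sm[i])
        width = 1.0 / fs
        return PeakDescriptor(
            position=i / fs, height=h, width=width,
            area=GAUSS_AREA_FACTOR * h * width, fit_error=100.0,
            channel=0,
        )
    xs, ys = xs[pos_mask], ys[pos_mask]
    coef = np.polyfit(xs - i, np.log(ys), 2)
    a, b, c = coef
    if a >= 0:  # not a concave log-parabola; keep the raw candidate
        h = float(sm[i])
        width = max(hi - lo, 1) / fs
        return PeakDescriptor(
            position=i / fs, height=h, width=width,
            area=GAUSS_AREA_FACTOR * h * width, fit_error=100.0,
            channel=0,
        )
    vertex = -b / (2 * a)
    height = float(np.exp(c - b * b / (4 * a)))
    sigma = np.sqrt(-1.0 / (2.0 * a))
    width = _FWHM_PER_SIGMA * sigma / fs
    fit = np.exp(np.polyval(coef, xs - i))
    fit_error = float(np.sqrt(np.mean((fit - ys) ** 2)) / height * 100.0)
    return PeakDescriptor(
        position=(i + vertex) / fs,
        height=height,
        width=width,
        area=GAUSS_AREA_FACTOR * height * width,
        fit_error=fit_error,
        channel=0,
    )


def two_highest(
    peaks: list[PeakDescriptor],
) -> tuple[PeakDescriptor, PeakDescriptor] | None:
    """The two highest peaks, re-labeled P1/P2 by order of appearance.

    Returns None when the channel has fewer than two peaks (degenerate,
    candidate for exclusion).
    """
    if len(peaks) < 2:
        return None
    top = sorted(peaks, key=lambda p: p.height, reverse=True)[:2]
    first, second = sorted(top, key=lambda p: p.position)
    first.rank, second.rank = "P1", "P2"
    return first, second


def tukey_fences(pool: np.ndarray) -> tuple[float, float]:
    """1.5-IQR box-plot fences with linearly interpolated quartiles."""
    q1, q3 = np.percentile(pool, [25.0, 75.0])
    iqr = q3 - q1
    return float(q1 - 1.5 * iqr), float(q3 + 1.5 * iqr)


def prune_outliers(
    p1_pos: dict[int, float], p2_pos: dict[int, float]
) -> tuple[list[int], list[int]]:
    """Drop channels whose P1 (resp. P2) lies outside the Tukey fences of
    the pooled peak positions.  Returns the retained channel lists."""
    pool = np.array(list(p1_pos.values()) + list(p2_pos.values()))
    lo, hi = tukey_fences(pool)
    idx1 = [ch for ch, p in p1_pos.items() if lo <= p <= hi]
    idx2 = [ch for ch, p in p2_pos.items() if lo <= p <= hi]
    if not idx1 or not idx2:
        raise ValueError("segmentation failed: all channels pruned")
    return idx1, idx2


def swing_window(
    peaks: dict[int, tuple[PeakDescriptor, PeakDescriptor]],
    idx1: list[int],
    idx2: list[int],
    record_end: float,
) -> tuple[float, float]:
    """Swing start/end from the marginal peaks: the earliest retained P1
    minus half its width and the latest retained P2 plus half its width,
    clipped to the record."""
    k1 = min(idx1, key=lambda ch: peaks[ch][0].position)
    k2 = max(idx2, key=lambda ch: peaks[ch][1].position)
    p1, p2 = peaks[k1][0], peaks[k2][1]
    t1 = max(0.0, p1.position - p1.width / 2.0)
    t2 = min(record_end, p2.position + p2.width / 2.0)
    if t1 >= t2:
        raise ValueError(f"degenerate swing window [{t1}, {t2}]")
    return t1, t2


def extract_segment(
    rec: EmgRecording,
    spec: FilterSpec | None = None,
    peak_density: float = 2.0,
    max_iterations: int = 5,
    filtered: np.ndarray | None = None,
) -> SwingSegment:
    """Full segmentation of one shot: find peaks per channel, iterate
    outlier pruning until stable, compute the window and relative peak
    positions.

    ``filtered`` may be supplied to reuse an existing preprocessed matrix.
    """
    if filtered is None:
        filtered = preprocess_recording(rec, spec)
    peaks: dict[int, tuple[PeakDescriptor, PeakDescriptor]] = {}
    for ch in range(N_CHANNELS):
        found = find_peaks(filtered[ch], rec.fs, peak_density)
        pair = two_highest(found)
        if pair is None:
            continue  # degenerate channel: excluded from the pools
        for p in pair:
            p.channel = ch + 1
        peaks[ch + 1] = pair
    if not peaks:
        raise ValueError(f"shot {rec.shot_id!r}: no channel yielded two peaks")

    active1 = sorted(peaks)
    active2 = sorted(peaks)
    iterations = 0
    for iterations in range(1, max_iterations + 1):
        idx1, idx2 = prune_outliers(
            {ch: peaks[ch][0].position for ch in active1},
            {ch: peaks[ch][1].position for ch in active2},
        )
        if idx1 == active1 and idx2 == active2:
            break
        active1, active2 = idx1, idx2
    else:
        raise ValueError(f"shot {rec.shot_id!r}: pruning did not converge")

    t1, t2 = swing_window(peaks, active1, active2, rec.duration)
    duration = t2 - t1
    for pair in peaks.values():
        for p in pair:
            p.rel_position = (p.position - t1) / duration
    all_channels = sorted(peaks)
    return SwingSegment(
        t1=t1,
        t2=t2,
        peaks=peaks,
        excluded_p1=[ch for ch in all_channels if ch not in active1],
        excluded_p2=[ch for ch in all_channels if ch not in active2],
        iterations=iterations,
        shot_id=rec.shot_id,
        filtered=filtered,
        fs=rec.fs,
    )
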