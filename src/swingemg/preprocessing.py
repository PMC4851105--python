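"""Rectification, peak normalization and zero-phase Butterworth filtering.

The feature-extraction chain is: full-wave rectify each channel, normalize
to the channel's peak activation level, then band filter with second-order
Butterworth high- and low-pass filters applied forward and backward
(zero phase, effective order 4), demeaning between the two passes.
Defaults are a 20 Hz high-pass and a 400 Hz low-pass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt

from swingemg.io import EmgRecording


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth band specification (Hz); ``order`` is per pass."""

    hp_cutoff: float = 20.0
    lp_cutoff: float = 400.0
    order: int = 2
    zero_phase: bool = True

    def validate(self, fs: float) -> None:
        if not 0 < self.hp_cutoff < self.lp_cutoff < fs / 2:
            raise ValueError(
                f"cutoffs must satisfy 0 < hp < lp < fs/2, got "
                f"hp={self.hp_cutoff}, lp={self.lp_cutoff}, fs={fs}"
            )


def rectify(signal: np.ndarray) -> np.ndarray:
    """Full-wave rectification (elementwise absolute value)."""
    signal = np.asarray(signal, dtype=float)
    if not np.isfinite(signal).all():
        raise ValueError("signal contains non-finite samples")
    return np.abs(signal)


def normalize_peak(signal: np.ndarray) -> np.ndarray:
    """Normalize a nonnegative signal to its peak activation level."""
    signal = np.asarray(signal, dtype=float)
    peak = signal.max()
    if peak <= 0:
        raise ValueError("silent channel: cannot normalize an all-zero signal")
    return signal / peak


def butterworth_envelope(
    signal: np.ndarray, fs: float, spec: FilterSpec | None = None
) -> np.ndarray:
    """Zero-phase band filtering: high-pass, demean, low-pass.

    Each pass is a second-order Butterworth filter run forward and
    backward, which doubles the effective order and cancels phase lag.
    The high-passed result is demeaned per channel before low-pass
    filtering.  The output of band-passing a nonnegative signal may dip
    slightly negative; downstream peak logic operates on it as-is.
    """
    if spec is None:
        spec = FilterSpec()
    spec.validate(fs)
    signal = np.asarray(signal, dtype=float)
    if signal.shape[-1] <= 6 * spec.order:
        raise ValueError("signal too short for stable forward-backward filtering")
    b_hp, a_hp = butter(spec.order, spec.hp_cutoff, btype="highpass", fs=fs)
    b_lp, a_lp = butter(spec.order, spec.lp_cutoff, btype="lowpass", fs=fs)
    if spec.zero_phase:
        y = filtfilt(b_hp, a_hp, signal, axis=-1)
        y = y - y.mean(axis=-1, keepdims=True)
        y = filtfilt(b_lp, a_lp, y, axis=-1)
    else:
        from scipy.signal import lfilter

        y = lfilter(b_hp, a_hp, signal, axis=-1)
        y = y - y.mean(axis=-1, keepdims=True)
        y = lfilter(b_lp, a_lp, y, axis=-1)
    return y


def preprocess_recording(
    rec: EmgRecording, spec: FilterSpec | None = None
) -> np.ndarray:
    """Rectify, peak-normalize and band filter all channels of a shot.

    Returns the 8 x T filtered matrix used by segmentation and feature
    extraction.
    """
    out = np.empty_like(rec.signal)
    for ch in range(rec.signal.shape[0]):
        out[ch] = normalize_peak(rectify(rec.signal[ch]))
    return butterworth_envelope(out, rec.fs, spec)
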