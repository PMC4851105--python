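"""Synthetic eight-channel surface-EMG generator with exact ground truth.

Each simulated shot is a pre-swing baseline, a swing of 1.5-2.2 s, and a
post-swing tail.  Per channel the signal is a zero-mean EMG carrier (white
Gaussian noise band-limited to the 20-400 Hz analysis band) amplitude-
modulated by a sum of Gaussian burst envelopes, so full-wave rectification
is meaningful and band filtering does not distort the planted structure.

The burst layout emulates the muscle orchestration seen in golf swings:

* *early* channels (2 right EDC, 3 left FCR, 5 right rhomboideus,
  6 right trapezius, 7 left rhomboideus) carry a dominant backswing burst
  whose onset follows a subject-specific ordering (the avalanche motif
  5 -> 6 -> 7 among the trunk muscles), plus a smaller burst at impact;
* *late* channels (1 right FCR, 4 left EDC, 8 left trapezius) activate
  just before impact with a downswing burst followed by the dominant
  impact burst, nearly synchronized with each other.

Channel 8 (left trapezius) is therefore late, as required of the timing
reference.  The ground truth records, per shot and channel, the true onset
(the time the swing-related envelope first exceeds 5% of its peak), the two
planted burst centers (P1/P2), the true swing window, and the pre-noise
generative target values.

Target attributes are a linear model of shot characteristics: swing
duration, the per-shot deviation of the within-channel burst amplitude
ratio (peak normalization erases absolute amplitude, so the ratio is the
identifiable quantity), and the synchrony of the late-channel impact
bursts, plus subject and residual noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import butter, filtfilt

from swingemg.io import N_CHANNELS, EmgRecording, ShotDataset

#: 0-based indices of channels whose dominant burst is the backswing.
EARLY_CHANNELS = (1, 2, 4, 5, 6)
#: 0-based indices of channels that activate late (downswing/impact).
LATE_CHANNELS = (0, 3, 7)

_ENVELOPE_ONSET_FRACTION = 0.05
# A Gaussian envelope first exceeds 5% of its peak sqrt(2 ln 20) sigma
# before its center.
_ONSET_SIGMAS = float(np.sqrt(2.0 * np.log(20.0)))


@dataclass
class SimConfig:
    """Generator configuration; defaults are the study conditions."""

    n_subjects: int = 15
    n_men: int = 10
    shots_per_subject: int = 5
    fs: float = 1000.0
    swing_duration_range: tuple[float, float] = (1.5, 2.2)
    #: seconds of baseline before the swing and after it
    pre_swing: float = 1.0
    post_swing: float = 1.0
    #: fraction of the swing at which the impact burst is centered
    impact_fraction: float = 0.85
    #: early-channel backswing onset delays are drawn per subject from this
    #: range (s after swing start); the avalanche chain 5->6->7 is imposed
    onset_delay_range: tuple[float, float] = (0.02, 0.40)
    #: late channels start their downswing burst this long before impact (s)
    downswing_lead: float = 0.25
    onset_jitter_sd: float = 10.0  # ms, shot-to-shot onset jitter
    #: Gaussian burst envelope widths (sigma, s)
    burst1_width: float = 0.065
    burst2_width: float = 0.050
    #: dominant / secondary burst amplitudes (before lognormal variation)
    amp_dominant: float = 1.0
    amp_secondary: float = 0.45
    amp_lognorm_sd: float = 0.15
    baseline_noise_sd: float = 0.03
    pre_swing_activity_amp: float = 0.12
    pre_swing_activity_prob: float = 0.3
    #: coupling coefficients from shot characteristics to the targets,
    #: order (duration, amplitude-ratio deviation, impact-lag spread)
    effect_speed: tuple[float, float, float] = (-6.0, 12.0, -25.0)
    effect_distance: tuple[float, float, float] = (-12.0, 30.0, -60.0)
    #: global multiplier on both coefficient vectors (0 = null model)
    effect_scale: float = 1.0
    #: residual target noise (speed, distance)
    noise_sd_target: tuple[float, float] = (0.8, 2.0)
    #: subject-level random intercept SDs (speed, distance)
    subject_sd_target: tuple[float, float] = (2.0, 4.0)
    #: sex-specific intercepts: base + sex_gap * sex
    speed_base: float = 78.0
    speed_sex_gap: float = 9.0
    distance_base: float = 150.0
    distance_sex_gap: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shots_per_subject < 2:
            raise ValueError("shots_per_subject must be >= 2")
        if self.n_subjects < 1 or not 0 <= self.n_men <= self.n_subjects:
            raise ValueError("invalid subject counts")
        lo, hi = self.swing_duration_range
        if not 0 < lo <= hi:
            raise ValueError("swing_duration_range must be positive")
        if self.burst1_width <= 0 or self.burst2_width <= 0:
            raise ValueError("burst widths must be positive")
        if self.onset_jitter_sd < 0 or self.baseline_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")


@dataclass
class ShotTruth:
    """Exact per-shot ground truth (sample units unless noted)."""

    shot_id: str
    onsets: np.ndarray          # (8,) true onset sample per channel
    p1_pos: np.ndarray          # (8,) first planted burst center, samples
    p2_pos: np.ndarray          # (8,) second planted burst center, samples
    window: tuple[float, float]  # true swing window (samples)
    swing_start: float          # samples
    swing_duration: float       # seconds
    gen_speed: float            # pre-noise generative target
    gen_distance: float
    #: latent shot characteristics driving the targets
    characteristics: np.ndarray  # (3,) duration, amp-ratio dev, lag spread


@dataclass
class GroundTruth:
    """Ground truth for a simulated dataset, aligned with its shots."""

    shots: list[ShotTruth] = field(default_factory=list)
    config: SimConfig | None = None

    def __len__(self) -> int:
        return len(self.shots)

    def __getitem__(self, i: int) -> ShotTruth:
        return self.shots[i]

    def by_shot_id(self) -> dict[str, ShotTruth]:
        return {s.shot_id: s for s in self.shots}


def default_study_config(seed: int = 0) -> SimConfig:
    """The study conditions: 15 subjects (10 men, 5 women), 5 shots each,
    1000 Hz sampling, swing durations uniform in [1.5, 2.2] s."""
    return SimConfig(seed=seed)


def _band_limited_noise(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Unit-variance white Gaussian noise band-limited to 20-400 Hz."""
    white = rng.standard_normal(n)
    b, a = butter(4, [20.0, 400.0], btype="bandpass", fs=fs)
    x = filtfilt(b, a, white)
    return x / x.std()


def _gaussian_envelope(t: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / sigma) ** 2)


def simulate(cfg: SimConfig) -> tuple[ShotDataset, GroundTruth]:
    """Simulate a dataset and its exact ground truth.

    Deterministic for a fixed ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.fs
    dur_lo, dur_hi = cfg.swing_duration_range

    # per-subject structure, fixed across that subject's shots
    subjects = []
    for s in range(cfg.n_subjects):
        sex = 1 if s < cfg.n_men else 0
        delays = np.zeros(N_CHANNELS)
        lo, hi = cfg.onset_delay_range
        # avalanche chain among trunk early channels 5 -> 6 -> 7 (0-based
        # 4, 5, 6); forearm early channels 2, 3 fall anywhere in range
        chain = np.sort(rng.uniform(lo, hi, size=3))
        delays[4], delays[5], delays[6] = chain
        delays[1] = rng.uniform(lo, hi)
        delays[2] = rng.uniform(lo, hi)
        # late channels: lag of the downswing burst relative to its nominal
        # start, nearly synchronized (|lag| small), channel 8 not earliest
        late_lags = rng.normal(0.0, 0.02, size=3)
        subjects.append(
            {
                "subject_id": f"G{s + 1}",
                "sex": sex,
                "delays": delays,
                "late_lags": late_lags,
                "u_speed": rng.normal(0.0, cfg.subject_sd_target[0]),
                "u_distance": rng.normal(0.0, cfg.subject_sd_target[1]),
            }
        )

    mean_duration = 0.5 * (dur_lo + dur_hi)
    recs: list[EmgRecording] = []
    truths: list[ShotTruth] = []
    for subj in subjects:
        for k in range(cfg.shots_per_subject):
            shot_id = f"{subj['subject_id']}_s{k + 1}"
            duration = rng.uniform(dur_lo, dur_hi)
            n = int(round((cfg.pre_swing + duration + cfg.post_swing) * fs))
            t = np.arange(n) / fs
            swing_start = cfg.pre_swing
            impact = swing_start + cfg.impact_fraction * duration

            jitter = rng.normal(0.0, cfg.onset_jitter_sd / 1000.0, N_CHANNELS)
            amps1 = np.empty(N_CHANNELS)
            amps2 = np.empty(N_CHANNELS)
            centers1 = np.empty(N_CHANNELS)
            centers2 = np.empty(N_CHANNELS)
            for ch in range(N_CHANNELS):
                log_a = rng.normal(0.0, cfg.amp_lognorm_sd, size=2)
                if ch in EARLY_CHANNELS:
                    # dominant backswing burst, secondary impact burst
                    onset_time = swing_start + subj["delays"][ch] + jitter[ch]
                    centers1[ch] = onset_time + _ONSET_SIGMAS * cfg.burst1_width
                    centers2[ch] = impact + rng.normal(0.0, 0.01)
                    amps1[ch] = cfg.amp_dominant * np.exp(log_a[0])
                    amps2[ch] = cfg.amp_secondary * np.exp(log_a[1])
                else:
                    # downswing burst then dominant impact burst
                    lag = subj["late_lags"][LATE_CHANNELS.index(ch)]
                    onset_time = (
                        impact - cfg.downswing_lead
                        - _ONSET_SIGMAS * cfg.burst1_width + lag + jitter[ch]
                    )
                    centers1[ch] = onset_time + _ONSET_SIGMAS * cfg.burst1_width
                    centers2[ch] = impact + lag + jitter[ch]
                    amps1[ch] = cfg.amp_secondary * 1.5 * np.exp(log_a[0])
                    amps2[ch] = cfg.amp_dominant * np.exp(log_a[1])

            # shot characteristics driving the targets
            amp_ratio_dev = float(np.mean(np.log(amps2 / amps1))
                                  - np.log(cfg.amp_secondary / cfg.amp_dominant)
                                  * len(EARLY_CHANNELS) / N_CHANNELS
                                  - np.log(cfg.amp_dominant / (cfg.amp_secondary * 1.5))
                                  * len(LATE_CHANNELS) / N_CHANNELS)
            late_pos = centers2[list(LATE_CHANNELS)]
            lag_spread = float(np.std(late_pos - impact))
            chars = np.array([duration - mean_duration, amp_ratio_dev, lag_spread])

            cs = np.asarray(cfg.effect_speed) * cfg.effect_scale
            cd = np.asarray(cfg.effect_distance) * cfg.effect_scale
            gen_speed = (
                cfg.speed_base + cfg.speed_sex_gap * subj["sex"]
                + subj["u_speed"] + float(cs @ chars)
            )
            gen_distance = (
                cfg.distance_base + cfg.distance_sex_gap * subj["sex"]
                + subj["u_distance"] + float(cd @ chars)
            )
            speed = gen_speed + rng.normal(0.0, cfg.noise_sd_target[0])
            distance = gen_distance + rng.normal(0.0, cfg.noise_sd_target[1])

            signal = np.empty((N_CHANNELS, n))
            onsets = np.empty(N_CHANNELS)
            for ch in range(N_CHANNELS):
                env = (
                    amps1[ch] * _gaussian_envelope(t, centers1[ch], cfg.burst1_width)
                    + amps2[ch] * _gaussian_envelope(t, centers2[ch], cfg.burst2_width)
                )
                total_env = env + cfg.baseline_noise_sd
                if rng.uniform() < cfg.pre_swing_activity_prob:
                    bump_c = rng.uniform(0.15, max(0.2, swing_start - 0.3))
                    total_env = total_env + cfg.pre_swing_activity_amp * \
                        _gaussian_envelope(t, bump_c, 0.08)
                carrier = _band_limited_noise(rng, n, fs)
                signal[ch] = total_env * carrier
                # true onset: swing-related envelope first exceeds 5% of peak
                above = env >= _ENVELOPE_ONSET_FRACTION * env.max()
                onsets[ch] = float(np.argmax(above))

            starts = centers1 - _ONSET_SIGMAS * cfg.burst1_width
            ends = centers2 + _ONSET_SIGMAS * cfg.burst2_width
            recs.append(
                EmgRecording(
                    shot_id=shot_id,
                    subject_id=subj["subject_id"],
                    sex=subj["sex"],
                    signal=signal,
                    fs=fs,
                    speed=float(speed),
                    distance=float(distance),
                )
            )
            truths.append(
                ShotTruth(
                    shot_id=shot_id,
                    onsets=onsets,
                    p1_pos=centers1 * fs,
                    p2_pos=centers2 * fs,
                    window=(float(starts.min() * fs), float(ends.max() * fs)),
                    swing_start=swing_start * fs,
                    swing_duration=duration,
                    gen_speed=float(gen_speed),
                    gen_distance=float(gen_distance),
                    characteristics=chars,
                )
            )
    return ShotDataset(recs), GroundTruth(shots=truths, config=cfg)


def noiseless_config(seed: int = 0) -> SimConfig:
    """Study config without baseline noise, pre-swing activity or onset
    jitter: the clean-burst condition used to validate onset recovery."""
    return replace(
        default_study_config(seed),
        baseline_noise_sd=0.0,
        pre_swing_activity_prob=0.0,
        onset_jitter_sd=0.0,
    )
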