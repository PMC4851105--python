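# Methods

This document specifies the model implemented by `swingemg`: the signal
chain, every parameter with its default and unit, the synthetic
generator used for validation, and the numerical choices and limitations
a user should know about.

## 1. Data model

A shot is an 8 × T matrix of surface-EMG samples at `fs` Hz (default
1000) plus metadata: subject id, sex (0 woman, 1 man), club head speed
and ball carry distance. Channel order is fixed:

| # | muscle | # | muscle |
|---|--------|---|--------|
| 1 | right flexor carpi radialis | 5 | right rhomboideus |
| 2 | right extensor digitorum communis | 6 | right trapezius |
| 3 | left flexor carpi radialis | 7 | left rhomboideus |
| 4 | left extensor digitorum communis | 8 | left trapezius |

Channel 8 (left trapezius) is the timing reference: in a right-handed
swing it activates last, near impact. A dataset requires ≥ 2 shots per
subject so that per-subject averages exist; the binary *effectiveness*
label of a shot is 1 iff its target value is strictly above the
subject's own mean (ties count as ineffective).

The on-disk dialect is "csv-wide": `metadata.csv`, `sampling.json`, and
one CSV per shot with the eight named channel columns. Floats are
written with `%.17g` and parsed with pandas' round-trip parser, so a
write/read cycle is bit-exact.

## 2. Preprocessing

For segmentation and feature extraction each channel is

1. full-wave rectified (absolute value),
2. normalized to its peak activation level,
3. band filtered with zero-phase Butterworth filters: 2nd-order
   high-pass at 20 Hz, per-channel demeaning, then 2nd-order low-pass
   at 400 Hz. Each pass runs forward and backward (`filtfilt`), so the
   effective order is 4 and phase lag cancels.

Band-passing a nonnegative signal can dip slightly negative; downstream
peak logic operates on the filtered signal as-is. Onset detection (§3)
deliberately runs on the *raw rectified* signal instead, since its
multiscale Gaussian bank does its own smoothing and the thresholds are
defined on rectified amplitudes.

## 3. Onset detection and activation profiles

Per channel, the rectified signal is convolved with four unit-area
Gaussian kernels of widths 256, 512, 1024, 2048 samples (σ = width/6,
centered, reflective padding), giving envelopes v1 (finest) … v4
(coarsest). The channel threshold is

    T = α · mean(|s|) over [t* − δ, t* + 2δ],   α = 1.2, δ = 500 samples,

where t* is the argmax of v4 and the window is clipped to the record.
For each of v2–v4, the last upward crossing of T at or before that
envelope's global maximum is collected; envelopes that never reach T are
skipped, and a channel where none cross has no detectable activation
(an error). With crossings c, the onset is the steepest rise of the
finest envelope,

    ts = argmax Δv1 over [min(c) − 256, max(c)],

clipped to the record. The activation profile is x_i = (ts₈ − ts_i) ·
1000/fs in ms for i = 1..7; positive entries activate before the
reference. λ = max_i |ts₈ − ts_i| flags atypical shots when outside the
dataset's 2.5–97.5 percentile range of λ values.

## 4. Swing segmentation

Per channel of the filtered matrix, peaks are found by smoothing with a
Gaussian window w = max(3, round(T / (50 · PeakD))) samples (PeakD = 2),
taking downward zero-crossings of the first difference, and discarding
candidates below 5% of the smoothed maximum. Each candidate is refined
by a least-squares parabola fit to the logarithm of the samples above
half height, giving a sub-sample position, height, FWHM width, area
(1.0646 · height · FWHM — the integral of a Gaussian expressed through
its FWHM) and a fit error (RMS residual as % of height). Degenerate
fits (fewer than three positive samples, or a convex log-parabola) fall
back to the raw sample with fit error 100%.

The two highest peaks of a channel are relabeled **P1** and **P2** by
order of appearance; channels with fewer than two peaks are excluded.
All P1/P2 positions are pooled; Tukey fences (quartiles ± 1.5 IQR,
linearly interpolated quartiles) drop outlying channels from each list,
iterating at most 5 times until stable. The swing window is

    t1 = earliest retained P1 position − its width/2  (floored at 0)
    t2 = latest retained P2 position + its width/2    (capped at record end)

and every peak's position is finally re-expressed relative to the
window: rel = (position − t1)/(t2 − t1).

## 5. The 22 feature sets

Every feature vector is prefixed by sex. The 12 summary statistics of a
sample are min, max, mean, median, lower/upper quartile, standard
deviation (n−1 denominator), IQR, lower range (median − Q1), upper
range (Q3 − median), skewness and kurtosis (standardized 3rd/4th
moments, kurtosis not excess; both defined as 0 for a constant sample).

| sets | content | size |
|------|---------|------|
| 1–2 | swing duration + 12 statistics of each right-/left-side channel's windowed samples | 49 |
| 3–4 | Pearson − Spearman difference / ratio per channel pair | 28 |
| 5–6 | sets 3–4 plus the 12 statistics of the 28 values | 40 |
| 7, 10 | the 5 peak properties (relative position, height, width, area, fit error) of P1 / P2 per channel | 40 |
| 8–9, 11–12 | pairwise synchrony (signed / absolute relative-position difference) of P1 / P2 + 12 statistics | 40 |
| 13–14 | P1 − P2 / P1 ÷ P2 property contrasts per channel | 40 |
| 15–22 | P1 and P2 synchrony values combined pairwise by −, +, ×, ÷ (signed and absolute variants) + 12 statistics | 40 |

Ratio-style features guard the division: denominators below 1e−9 in
magnitude yield 0 rather than huge values. Shots whose builder fails
(e.g., a zero-variance channel in a correlation pair) are dropped from
that table and recorded in `df.attrs["dropped"]`.

## 6. Subject-grouped random forest

Golf data are repeated measures, so the forest bootstrap resamples
*subjects* with replacement: all shots of a drawn subject enter the bag
with the subject's multiplicity, and never-drawn subjects form the
tree's out-of-bag set — no shot of a subject is ever both in-bag and
OOB for the same tree. Classification additionally stratifies the draw
by sex (each stratum draws its own size, preserving the cohort's sex
ratio) and redraws degenerate single-class bags. Trees are unpruned
CART trees (Gini / variance reduction) with `q` random candidate
features per node (default ⌈√p⌉; the search grid is {⌈√p⌉, ⌈2√p⌉,
⌈p/3⌉}).

Per-shot OOB scores feed fusion:

* detection: the OOB-averaged difference between the leaf class
  frequencies of the effective and ineffective classes, a value in
  [−1, 1];
* regression: the mean of the OOB trees' predictions.

A shot never OOB (too few trees) is an error rather than a silent NaN.
OOB permutation importance permutes one feature column at a time and
reports the mean decrease in OOB accuracy (classification) or increase
in OOB RMSE (regression).

The ensemble size defaults to B = 500 trees, a desk-scale setting; the
full-scale configuration is B = 5000 and only changes runtime and
Monte-Carlo noise, not behavior.

## 7. Decision-level fusion and meta-feature selection

The per-set OOB scores form a 75 × 23 meta-table (sex + m1..m22). A
second grouped forest fuses sex plus a *subset* of meta-features; the
subset is encoded by the angle-modulation trick: with parameters
(a, b, c, d),

    g(x) = sin(2π (x − a) · b · cos(2π c (x − a))) + d,

sampled at x_k = 0.1 k for k = 1..22, selects meta-feature k iff
g(x_k) > 0. Differential evolution (DE/rand/1/bin; population 10,
scale F = 0.5, crossover 0.9, 10 generations, early stop after 10
stagnant generations) searches the 4-dimensional parameter space;
all-zero masks are resampled. The fitness of a mask is the best
criterion over the meta-forest's q sweep (q = 2 … #selected + 1): the
minimum Cllr for detection, the OOB RMSE for regression. The forest
seed is fixed within a run and fitness values are cached per mask, so
fitness is deterministic and the elitist best-so-far trajectory is
monotone non-increasing. Sex survives every mask.

A repeat harness refits the fusion forest under different seeds and
reports mean ± 1.96·sd/√n (normal-approximation 95% CI) per metric;
the default of 100 repeats is reduced to ~20 in the tests.

## 8. Evaluation

Detection scores are calibrated by the pool-adjacent-violators
algorithm (equivalent to the ROC convex hull) into monotone posterior
estimates, converted to log-likelihood ratios by subtracting the prior
log-odds, and capped at ±15 nats so separable sets stay finite. The
minimum cost of the log-likelihood ratio is

    Cllr = ½ [ mean_tar log₂(1 + e^(−llr)) + mean_non log₂(1 + e^(llr)) ]

(0 = perfect, 1 = uninformative). The DET curve is the convex hull's
(p_fa, p_miss) sweep; the EER is read off with linear interpolation.
AUC is the normalized Mann-Whitney statistic with ties counted half.
A useful, well-calibrated detector satisfies Cllr < 1, EER < 50%,
AUC > 0.5; the test suite verifies both these bounds under permuted
labels and the degenerate endpoints for separable scores.

Regression reports RMSE (target units), MAPE (%) and Pearson
correlation, next to a deliberately naive baseline that predicts the
full-sample sex-specific mean for every shot. Because targets are
strongly sex-separated, this baseline is already highly correlated with
the truth; beating its RMSE is the meaningful bar.

## 9. Synthetic generator

Each channel is a zero-mean carrier (white Gaussian noise band-limited
to 20–400 Hz, unit variance) amplitude-modulated by a sum of Gaussian
burst envelopes plus a small constant baseline (SD 0.03 of the dominant
amplitude) and, with probability 0.3 per channel, a low pre-swing bump.
Rectification of such a signal tracks the envelope, so the planted
structure survives the literal analysis chain.

A shot is 1 s of baseline, a swing of duration U(1.5, 2.2) s, and 1 s
of tail; "impact" is at 85% of the swing. Channels split into:

* **early** (2, 3, 5, 6, 7): dominant backswing burst (σ = 65 ms,
  amplitude 1.0 before log-normal variation) whose onset is
  swing start + a subject-specific delay in [0.02, 0.40] s, plus a
  secondary impact burst (σ = 50 ms, amplitude 0.45). The trunk delays
  obey the subject-level avalanche chain 5 → 6 → 7.
* **late** (1, 4, 8): a downswing burst starting 0.25 s before impact
  (amplitude 0.675) followed by the dominant impact burst (amplitude
  1.0), nearly synchronized across the three channels (lags N(0, 20 ms)
  per subject). Channel 8 is therefore late, as the reference requires.

Per-shot onset jitter is N(0, 10 ms). The recorded true onset of a
channel is where its planted envelope first exceeds 5% of its peak —
for a Gaussian burst, √(2 ln 20) ≈ 2.45 σ before the center.

Targets are a linear model of three latent shot characteristics —
swing-duration deviation, the within-channel log burst-amplitude-ratio
deviation (peak normalization erases absolute amplitude, so the *ratio*
is the identifiable quantity), and the spread of the late-channel
impact lags — plus sex and subject intercepts (speed: 78 + 9·sex,
subject SD 2; distance: 150 + 40·sex, subject SD 4) and residual noise
(SD 0.8 / 2.0). An `effect_scale` of 0 yields the null model; the
default coefficients are chosen so that the planted signal is
recoverable but not trivial at 75 shots.

The generator's scope is validation, not realism: it emulates burst
timing, orchestration and amplitude structure, but not electrode
artifacts, motion noise, inter-muscle crosstalk, or fatigue. Absolute
metric values on synthetic data do not transfer to real recordings.

## 10. Numerical choices

* Gaussian smoothing uses reflective padding; convolutions are exact
  (`scipy.ndimage`), not FFT approximations.
* PAV is implemented with the classic stack-based pooling after merging
  tied scores; it matches scikit-learn's `IsotonicRegression` exactly
  (cross-checked in the tests) but also exposes the hull vertices for
  the DET/EER sweep.
* The angle-modulation threshold is strict (g > 0). Grid points that
  fall exactly on a zero of the generating function are decided by
  floating-point rounding; the tests use phase-shifted closed-form
  cases that keep grid points away from zeros.
* All randomness flows through `numpy.random.Generator`; one global
  seed is expanded into independent per-stage seeds via
  `SeedSequence`, and scikit-learn tree seeds are drawn below 2³¹.
* Quartiles use linear interpolation (numpy's default) everywhere,
  including the Tukey fences.

## 11. Limitations

* The detector bars verified by the tests (fused EER ≤ 35%, AUC ≥ 0.65
  on the default 75-shot study) are properties of the synthetic
  planted-effect condition, not claims about real golf swings.
* Regression is much harder than detection on this generator, by
  construction of the tasks rather than by implementation: the
  effectiveness label is defined relative to each subject's own mean,
  which cancels the subject intercept, whereas the absolute targets
  keep it. Subject intercepts (SD 2.0) are irreducible noise for any
  leave-subject-out predictor but are partially absorbed by the
  full-sample sex-average baseline (each subject's own shots enter its
  sex mean). On the default study the fused regressor therefore only
  roughly ties that baseline — as does an oracle given the true planted
  characteristics — and the corresponding acceptance test documents
  this by failing with an explanatory message.
* With 15 subjects, OOB estimates are noisy; per-shot OOB counts are
  exposed (`oob_count_`) so users can judge coverage.
* The evolutionary search is small by design (desk scale); it
  demonstrates the mechanism and its determinism rather than exhaustive
  optimization.
* MAPE is undefined for targets at 0 and rejected explicitly; targets
  in this domain are strictly positive.
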