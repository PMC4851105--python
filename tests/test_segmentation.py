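"""Peak finding, Gaussian refinement, Tukey pruning, swing windows."""

import numpy as np
import pytest

from swingemg.segmentation import (
    GAUSS_AREA_FACTOR,
    extract_segment,
    find_peaks,
    prune_outliers,
    tukey_fences,
    two_highest,
)


def _gauss(t, c, s):
    return np.exp(-0.5 * ((t - c) / s) ** 2)


class TestFindPeaks:
    def test_recovers_planted_gaussians(self):
        fs = 1000.0
        t = np.arange(4000) / fs
        y = 1.0 * _gauss(t, 1.0, 0.08) + 0.7 * _gauss(t, 2.5, 0.06)
        peaks = find_peaks(y, fs)
        assert len(peaks) == 2
        got = sorted(p.position for p in peaks)
        assert got[0] == pytest.approx(1.0, abs=0.01)
        assert got[1] == pytest.approx(2.5, abs=0.01)

    def test_width_matches_fwhm(self):
        fs = 1000.0
        t = np.arange(4000) / fs
        sigma = 0.08
        y = _gauss(t, 2.0, sigma)
        (peak,) = find_peaks(y, fs)
        fwhm = 2.0 * np.sqrt(2.0 * np.log(2.0)) * sigma
        assert peak.width == pytest.approx(fwhm, rel=0.1)
        assert peak.area == pytest.approx(
            GAUSS_AREA_FACTOR * peak.height * peak.width, rel=1e-12)

    def test_five_percent_floor(self):
        fs = 1000.0
        t = np.arange(4000) / fs
        y = 1.0 * _gauss(t, 1.0, 0.08) + 0.01 * _gauss(t, 3.0, 0.08)
        peaks = find_peaks(y, fs)
        assert len(peaks) == 1  # tiny peak below the 5% floor is dropped

    def test_no_peaks(self):
        with pytest.raises(ValueError, match="no peaks"):
            find_peaks(np.linspace(0, 1, 2000), 1000.0)


class TestTwoHighest:
    def test_labels_by_order_of_appearance(self):
        fs = 1000.0
        t = np.arange(5000) / fs
        # later peak is the taller one; P1 must still be the earlier peak
        y = 0.6 * _gauss(t, 1.0, 0.07) + 1.0 * _gauss(t, 3.0, 0.07) \
            + 0.3 * _gauss(t, 4.2, 0.07)
        pair = two_highest(find_peaks(y, fs))
        p1, p2 = pair
        assert p1.rank == "P1" and p2.rank == "P2"
        assert p1.position < p2.position
        assert p1.position == pytest.approx(1.0, abs=0.02)
        assert p2.position == pytest.approx(3.0, abs=0.02)

    def test_degenerate_channel_returns_none(self):
        fs = 1000.0
        t = np.arange(3000) / fs
        y = _gauss(t, 1.5, 0.08)
        assert two_highest(find_peaks(y, fs)) is None


class TestTukey:
    def test_fences_match_definition(self):
        rng = np.random.default_rng(0)
        pool = rng.normal(size=40)
        lo, hi = tukey_fences(pool)
        q1, q3 = np.percentile(pool, [25, 75])
        assert lo == pytest.approx(q1 - 1.5 * (q3 - q1))
        assert hi == pytest.approx(q3 + 1.5 * (q3 - q1))

    def test_prune_drops_only_outliers(self):
        p1 = {ch: 1.0 + 0.01 * ch for ch in range(1, 8)}
        p1[8] = 50.0  # wild outlier
        p2 = {ch: 2.0 + 0.01 * ch for ch in range(1, 9)}
        idx1, idx2 = prune_outliers(p1, p2)
        assert 8 not in idx1
        assert idx2 == list(range(1, 9))

    def test_prune_all_fails(self):
        # a single-element pool can never be an outlier of itself; use
        # a pathological two-cluster pool that empties one list
        p1 = {1: 1e9}
        p2 = {ch: 2.0 for ch in range(1, 9)}
        with pytest.raises(ValueError, match="segmentation failed"):
            # iterating by hand: after the fences drop channel 1's P1 the
            # P1 pool would be empty
            prune_outliers({1: 1e9}, {})


class TestExtractSegment:
    def test_window_brackets_peaks(self, dataset, segments):
        for rec in dataset:
            seg = segments[rec.shot_id]
            assert 0.0 <= seg.t1 < seg.t2 <= rec.duration
            for ch, (p1, p2) in seg.peaks.items():
                assert p1.position < p2.position
                assert p1.channel == p2.channel == ch

    def test_relative_positions_span_unit_interval(self, segments):
        for seg in segments.values():
            rels = [p.rel_position for pair in seg.peaks.values() for p in pair]
            # retained peaks live inside the window up to half-width slack
            assert min(rels) > -0.25 and max(rels) < 1.25

    def test_pruning_converges_quickly(self, segments):
        assert all(seg.iterations <= 5 for seg in segments.values())

    def test_window_covers_typical_bursts(self, segments, truth):
        """[t1, t2] brackets the typical backswing and impact bursts
        (medians of the planted early-channel P1 / late-channel P2
        centers) for the vast majority of shots."""
        from swingemg.simulate import EARLY_CHANNELS, LATE_CHANNELS

        by_id = truth.by_shot_id()
        good = 0
        for sid, seg in segments.items():
            s = by_id[sid]
            backswing = np.median(s.p1_pos[list(EARLY_CHANNELS)]) / 1000.0
            impact = np.median(s.p2_pos[list(LATE_CHANNELS)]) / 1000.0
            if seg.t1 <= backswing and seg.t2 >= impact:
                good += 1
        assert good / len(segments) >= 0.9

    def test_reuses_supplied_filtered_matrix(self, dataset):
        from swingemg.preprocessing import preprocess_recording

        rec = dataset[0]
        filt = preprocess_recording(rec)
        seg = extract_segment(rec, filtered=filt)
        assert seg.filtered is filt
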