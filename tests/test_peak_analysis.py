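"""Normalisation rules, the sliding-window peak caller against a
brute-force window enumerator, and interval-overlap summaries."""

import numpy as np
import pytest
from scipy.stats import norm

from oriclass.peak_analysis import (
    Peak,
    PeakCallConfig,
    assign_peaks_to_origins,
    bp_composition,
    call_peaks,
    estimate_null_sd,
    normalize_track,
    overlap_fraction,
    peak_area_over,
)
from oriclass.tracks_io import OriginAnnotation, ProbeTrack


def make_track(values, spacing=50, chrom="chrI", condition="x"):
    values = np.asarray(values, dtype=float)
    track = ProbeTrack(condition)
    track.add_chromosome(chrom, np.arange(values.size) * spacing + spacing // 2, values)
    return track


def brute_force_peaks(track, cfg):
    """Independent oracle: explicit enumeration of every window with direct
    Gaussian tail sums, then merging by scanning."""
    vals = track.values()
    negs = vals[vals < 0]
    sigma = np.sqrt(np.mean(negs**2)) if negs.size else 0.0
    windows = []
    n_windows = 0
    for chrom in sorted(track.chroms):
        mids, v = track.chroms[chrom]
        start = 0
        while start <= mids[-1]:
            inside = (mids >= start) & (mids < start + cfg.window)
            n = int(inside.sum())
            if n >= cfg.min_probes:
                n_windows += 1
                windows.append((chrom, start, float(v[inside].mean()), n))
            start += cfg.step
    peaks = []
    current = None
    for chrom, start, mean, n in windows:
        if sigma == 0.0:
            p = 0.0 if mean > 0 else 1.0
        else:
            p = float(norm.sf(mean / (sigma / np.sqrt(n))))
        p = min(p * n_windows, 1.0)
        if p > cfg.p_cutoff:
            continue
        if current and current[0] == chrom and start <= current[2]:
            current = (chrom, current[1], start + cfg.window, min(current[3], p))
        else:
            if current:
                peaks.append(current)
            current = (chrom, start, start + cfg.window, p)
    if current:
        peaks.append(current)
    out = []
    for chrom, s, e, p in peaks:
        mids, v = track.chroms[chrom]
        inside = (mids >= s) & (mids < e)
        out.append(Peak(chrom, s, e, float(v[inside].sum()), p, int(inside.sum())))
    return out


class TestNormalise:
    def test_constant_track_centres_to_zero(self):
        out = normalize_track(make_track([0.7] * 100), repetitive_fraction=0.0)
        assert np.allclose(out.values(), 0.0)

    def test_removes_one_point_one_percent(self, rng):
        track = make_track(rng.normal(size=1000))
        out = normalize_track(track)
        assert out.n_probes == 989

    def test_removed_probes_are_the_most_extreme(self, rng):
        vals = rng.normal(size=1000)
        vals[:11] = 100.0  # planted repetitive garbage
        out = normalize_track(make_track(vals))
        assert np.abs(out.values()).max() < 50

    def test_centering_is_idempotent(self, rng):
        track = make_track(rng.normal(0.5, 1.0, size=500))
        once = normalize_track(track, repetitive_fraction=0.0)
        twice = normalize_track(once, repetitive_fraction=0.0)
        np.testing.assert_allclose(twice.values(), once.values())
        assert abs(np.median(once.values())) <= 0.01

    def test_empty_track_errors(self):
        with pytest.raises(ValueError):
            normalize_track(ProbeTrack("x"))


class TestCallPeaks:
    def test_all_zero_track_has_no_peaks(self):
        assert call_peaks(make_track(np.zeros(200))) == []

    def test_single_planted_block(self):
        # a 240 bp block of value 3.0 amid exact-zero background
        vals = np.zeros(200)
        vals[100:104] = 3.0  # probes at 5000..5150 with spacing 50
        track = make_track(vals, spacing=50)
        peaks = call_peaks(track)
        assert len(peaks) == 1
        (peak,) = peaks
        assert peak.area == pytest.approx(3.0 * 4)
        assert peak.start <= 5025 and peak.end > 5175

    def test_matches_brute_force_on_random_tracks(self, rng):
        cfg = PeakCallConfig()
        for _ in range(50):
            vals = rng.normal(0, 0.3, size=200)  # 10 kb at 50 bp spacing
            for _ in range(rng.integers(0, 3)):
                start = int(rng.integers(0, 150))
                vals[start : start + 5] += rng.uniform(1.0, 3.0)
            track = make_track(vals)
            got = call_peaks(track, cfg)
            want = brute_force_peaks(track, cfg)
            assert [(p.chrom, p.start, p.end, p.n_probes) for p in got] == [
                (p.chrom, p.start, p.end, p.n_probes) for p in want
            ]
            np.testing.assert_allclose(
                [p.area for p in got], [p.area for p in want], atol=1e-9
            )
            np.testing.assert_allclose(
                [p.p_value for p in got], [p.p_value for p in want], rtol=1e-9
            )

    def test_pure_noise_rarely_yields_any_peak(self):
        # Bonferroni control: pure Gaussian tracks should essentially never
        # produce a corrected-significant window
        clean_runs = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            track = make_track(r.normal(0, 0.2, size=120_000), spacing=50)
            if not call_peaks(track):
                clean_runs += 1
        assert clean_runs >= 19

    def test_adding_positive_constant_keeps_the_peak(self):
        vals = np.zeros(200)
        vals[100:104] = 2.0
        base = call_peaks(make_track(vals))
        vals[100:104] += 1.0
        boosted = call_peaks(make_track(vals))
        assert len(boosted) >= len(base) == 1

    def test_area_invariant_to_step_refinement_for_aligned_block(self):
        vals = np.zeros(400)
        vals[200:204] = 2.0
        track = make_track(vals, spacing=60)  # probes every 60 bp
        coarse = call_peaks(track, PeakCallConfig(window=240, step=240))
        fine = call_peaks(track, PeakCallConfig(window=240, step=60))
        assert coarse and fine
        assert coarse[0].area == pytest.approx(fine[0].area)


class TestAreas:
    def test_simple_sum(self):
        track = make_track(np.ones(50))
        res = peak_area_over(track, "chrI", 0, 500)  # covers 10 probes
        assert res.area == pytest.approx(10.0) and res.n_probes == 10

    def test_negative_area_permitted(self):
        track = make_track([-0.2] * 5)
        res = peak_area_over(track, "chrI", 0, 250)
        assert res.area == pytest.approx(-1.0)

    def test_zero_probes_flagged(self):
        track = make_track(np.ones(5))
        res = peak_area_over(track, "chrI", 10_000, 10_100)
        assert res.area == 0.0 and res.empty

    def test_additivity_over_disjoint_adjacent_intervals(self, rng):
        track = make_track(rng.normal(size=100))
        ab = peak_area_over(track, "chrI", 0, 5000).area
        a = peak_area_over(track, "chrI", 0, 2000).area
        b = peak_area_over(track, "chrI", 2000, 5000).area
        assert ab == pytest.approx(a + b)


class TestOverlaps:
    def _peaks(self, intervals):
        return [Peak(c, s, e, 1.0, 1e-9, 2) for c, s, e in intervals]

    def test_identical_sets_fully_overlap(self):
        feats = [("chrI", 0, 100), ("chrI", 500, 700)]
        assert overlap_fraction(self._peaks(feats), feats) == 1.0

    def test_disjoint_sets(self):
        peaks = self._peaks([("chrI", 0, 100)])
        assert overlap_fraction(peaks, [("chrI", 200, 300)]) == 0.0

    def test_matches_brute_force_pairwise_intersection(self, rng):
        peaks = self._peaks(
            [("chrI", int(s), int(s) + int(w))
             for s, w in zip(rng.integers(0, 10_000, 40), rng.integers(1, 300, 40))]
        )
        feats = [
            ("chrI", int(s), int(s) + int(w))
            for s, w in zip(rng.integers(0, 10_000, 100), rng.integers(1, 300, 100))
        ]
        brute = sum(
            1
            for c, s, e in feats
            if any(min(e, p.end) > max(s, p.start) for p in peaks if p.chrom == c)
        ) / len(feats)
        assert overlap_fraction(peaks, feats) == pytest.approx(brute)

    def test_bp_composition_priority_partition(self):
        peaks = self._peaks([("chrI", 0, 100)])
        comp = bp_composition(
            peaks,
            [("origins", [("chrI", 0, 40)]), ("genes", [("chrI", 20, 80)])],
        )
        assert comp["origins"] == pytest.approx(0.4)
        assert comp["genes"] == pytest.approx(0.4)  # 40-80 after priority cut
        assert comp["other"] == pytest.approx(0.2)
        assert sum(comp.values()) == pytest.approx(1.0)


class TestAssignment:
    def test_largest_overlap_wins_with_tie_breaks(self):
        origins = [
            OriginAnnotation("ARS_b", "chrI", 100, 300, "confirmed"),
            OriginAnnotation("ARS_a", "chrI", 250, 450, "confirmed"),
        ]
        peak = Peak("chrI", 150, 350, 5.0, 1e-9, 4)
        assigned = assign_peaks_to_origins([peak], origins)
        assert set(assigned) == {"ARS_b"}  # 150 bp overlap beats 100 bp
        # fully symmetric overlaps and distances: lexicographic name decides
        peak2 = Peak("chrI", 225, 325, 5.0, 1e-9, 4)
        assigned2 = assign_peaks_to_origins([peak2], origins)
        assert set(assigned2) == {"ARS_a"}
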