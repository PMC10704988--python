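import numpy as np
import pytest

from rbpflow.intervals import GenomicInterval
from rbpflow.peaks import (
    Peak, PeakParams, call_peaks, gene_baseline, peak_stats, window_depths,
)
from rbpflow.reads import CoverageTrack, ReadPlacement
from _reference import reference_call_peaks, reference_window_means


def track(depth, start=0, chrom="chr1"):
    depth = np.asarray(depth)
    return CoverageTrack(
        GenomicInterval(chrom, start, start + len(depth)), depth
    )


class TestWindowDepths:
    def test_constant_track_tiles_exactly(self):
        out = window_depths(track([7] * 50), PeakParams())
        assert len(out) == 10
        assert all(m == 7 for _, m in out)
        assert out[0][0].start == 0 and out[-1][0].end == 50

    def test_two_block_track(self):
        out = window_depths(track([0] * 5 + [10] * 5), PeakParams())
        assert [m for _, m in out] == [0, 10]

    def test_trailing_partial_window_uses_actual_length(self):
        out = window_depths(track([2] * 12), PeakParams())
        assert [m for _, m in out] == [2, 2, 2]
        assert out[-1][0].end - out[-1][0].start == 2

    def test_track_shorter_than_window_is_empty(self):
        assert window_depths(track([1, 1]), PeakParams()) == []

    def test_matches_slicing_oracle_on_random_track(self, rng):
        depth = rng.integers(0, 30, 1000)
        out = [m for _, m in window_depths(track(depth), PeakParams())]
        assert out == pytest.approx(
            reference_window_means(list(depth), 5, 5)
        )


class TestCallPeaks:
    def test_all_zero_track_has_no_peaks(self):
        assert call_peaks(track([0] * 400), baseline=1.0) == []

    def test_enriched_block_extends_to_track_end_over_nonzero_background(self):
        """With background depth 1 and a depth-10 block, the termination
        rule (windows < 4% of the running max, i.e. < 0.4) can never fire
        on depth-1 windows, so the automaton keeps the peak open until the
        end of the track.  Frozen from the straight-line reference."""
        depth = np.ones(600)
        depth[100:300] = 10
        ref = reference_call_peaks(list(depth), 1.0)
        assert ref == [(100, 600, 10)]
        peaks = call_peaks(track(depth), baseline=1.0)
        assert len(peaks) == 1
        assert (peaks[0].interval.start, peaks[0].interval.end) == (100, 600)
        assert peaks[0].max_depth == 10

    def test_enriched_block_flanked_by_zeros_snaps_to_block(self):
        depth = np.zeros(600)
        depth[100:300] = 10
        peaks = call_peaks(track(depth), baseline=1.0)
        assert len(peaks) == 1
        # closes immediately before the first run of 8 zero windows
        assert (peaks[0].interval.start, peaks[0].interval.end) == (100, 300)

    def test_subthreshold_plateau_never_opens(self):
        # depth 2 < 2.5x baseline and run median 2 <= 50: neither rule fires
        depth = np.concatenate([np.ones(100), np.full(200, 2), np.ones(100)])
        assert call_peaks(track(depth), baseline=1.0) == []

    def test_median_start_rule_opens_without_ratio_rule(self):
        depth = np.zeros(400)
        depth[100:300] = 60  # median 60 > 50 opens even with huge baseline
        peaks = call_peaks(track(depth), baseline=1000.0)
        assert len(peaks) == 1

    def test_equivalent_to_straight_line_reference_on_random_tracks(self, rng):
        """Oracle equivalence over many random tracks: identical peak
        boundaries and max depths."""
        params = PeakParams()
        for trial in range(200):
            n = int(rng.integers(40, 1000))
            kind = trial % 3
            if kind == 0:
                depth = rng.integers(0, 8, n)
            elif kind == 1:
                depth = rng.poisson(2.0, n)
                for _ in range(int(rng.integers(0, 4))):
                    s = int(rng.integers(0, n))
                    w = int(rng.integers(10, 120))
                    depth[s : s + w] += int(rng.integers(5, 40))
            else:
                depth = np.zeros(n, dtype=int)
                for _ in range(int(rng.integers(1, 5))):
                    s = int(rng.integers(0, n))
                    w = int(rng.integers(5, 150))
                    depth[s : s + w] += int(rng.integers(1, 30))
            baseline = max(float(depth.mean()), 1.0)
            got = [
                (p.interval.start, p.interval.end, p.max_depth)
                for p in call_peaks(track(depth), baseline, params)
            ]
            want = reference_call_peaks(list(depth), baseline)
            assert got == [(s, e, float(m)) for s, e, m in want], (
                f"trial {trial}: mismatch on track of length {n}"
            )

    def test_raising_start_ratio_never_adds_peaks(self, rng):
        depth = rng.poisson(2.0, 800)
        depth[200:320] += 12
        baseline = max(float(depth.mean()), 1.0)
        counts = [
            len(call_peaks(track(depth), baseline, PeakParams(start_ratio=r)))
            for r in (1.5, 2.5, 4.0, 8.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_raising_end_fraction_never_lengthens_peaks(self, rng):
        depth = np.zeros(900, dtype=int)
        depth[100:300] = 20
        depth[320:340] = 1
        depth[340:500] = 15
        lengths = {}
        for frac in (0.02, 0.04, 0.2, 0.6):
            pks = call_peaks(track(depth), 1.0, PeakParams(end_fraction=frac))
            lengths[frac] = sum(len(p.interval) for p in pks)
        vals = [lengths[f] for f in (0.02, 0.04, 0.2, 0.6)]
        assert vals == sorted(vals, reverse=True)

    def test_peaks_disjoint_sorted_and_window_aligned(self, rng):
        depth = rng.poisson(1.5, 1000)
        for s in (100, 400, 700):
            depth[s : s + 80] += 20
        peaks = call_peaks(track(depth), max(float(depth.mean()), 1.0))
        assert peaks
        for a, b in zip(peaks, peaks[1:]):
            assert a.interval.end <= b.interval.start
        for p in peaks:
            assert p.interval.start % 5 == 0
            assert len(p.interval) >= 5
            assert p.max_depth >= p.median_depth >= 0


class TestPeakStats:
    def test_uniform_depth(self):
        t = track([4] * 50)
        reads = [
            ReadPlacement(GenomicInterval("chr1", 0, 10)),
            ReadPlacement(GenomicInterval("chr1", 60, 70)),
        ]
        mx, med, cnt = peak_stats(GenomicInterval("chr1", 10, 40), t, reads)
        assert (mx, med, cnt) == (4, 4, 0)

    def test_ramp_median_and_max(self):
        t = track(list(range(1, 10)))
        mx, med, _ = peak_stats(GenomicInterval("chr1", 0, 9), t, [])
        assert (mx, med) == (9, 5)

    def test_interval_outside_track_raises(self):
        with pytest.raises(ValueError):
            peak_stats(GenomicInterval("chr1", 40, 80), track([1] * 50), [])

    def test_matches_brute_force_on_random_fixture(self, rng):
        depth = rng.integers(0, 40, 300)
        t = track(depth)
        reads = [
            ReadPlacement(GenomicInterval("chr1", int(s), int(s) + 30))
            for s in rng.integers(0, 280, 50)
        ]
        lo, hi = 50, 200
        mx, med, cnt = peak_stats(GenomicInterval("chr1", lo, hi), t, reads)
        assert mx == depth[lo:hi].max()
        assert med == np.median(depth[lo:hi])
        assert cnt == sum(
            1 for p in reads
            if max(p.interval.start, lo) < min(p.interval.end, hi)
        )


def test_gene_baseline_is_floored_mean():
    assert gene_baseline(track([0] * 100)) == 1.0
    assert gene_baseline(track([4] * 100)) == 4.0
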