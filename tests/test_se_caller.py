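import numpy as np
import pytest

from acetrank.io_formats import (
    GenomicInterval,
    Peak,
    SignalTrack,
    TSSAnnotation,
    TSSRecord,
)
from acetrank.se_caller import (
    call_superenhancers,
    geometric_cutoff,
    reproducible_peaks,
    stitch,
)


def brute_cutoff(values):
    """Independent O(N^2) reference: for every candidate point, count points
    strictly below the slope-(max-min)/N line through it; take the argmin."""
    v = np.sort(np.maximum(np.asarray(values, dtype=float), 0.0))
    n = len(v)
    if v[0] == v[-1]:
        return float(v[-1]), n
    s = (v[-1] - v[0]) / n
    idx = np.arange(n)
    best_c, best_x = None, None
    for x in range(n):
        c = int(np.sum(v < v[x] + s * (idx - x)))
        if best_c is None or c < best_c:
            best_c, best_x = c, x
    return float(v[best_x]), best_x + 1


def peaks_at(positions, width=100, chrom="chr1", signal=1.0):
    return [
        Peak(GenomicInterval(chrom, p, p + width), signal=signal) for p in positions
    ]


class TestStitch:
    def test_worked_example(self):
        regions = stitch(peaks_at([0, 5000, 20000]), stitch_distance=12500)
        assert [(r.start, r.end) for r in regions] == [(0, 5100), (20000, 20100)]

    def test_single_peak_identity(self):
        (r,) = stitch(peaks_at([500]))
        assert (r.start, r.end) == (500, 600)
        assert len(r.constituents) == 1

    def test_distance_zero_merges_only_touching(self):
        regions = stitch(peaks_at([0, 100, 300]), stitch_distance=0)
        assert [(r.start, r.end) for r in regions] == [(0, 200), (300, 400)]

    def test_idempotent_and_gap_postcondition(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = int(rng.integers(1, 60))
            starts = np.sort(rng.integers(0, 500_000, n))
            widths = rng.integers(50, 2000, n)
            chroms = rng.choice(["c1", "c2"], n)
            peaks = []
            for c, s, w in zip(chroms, starts, widths):
                peaks.append(Peak(GenomicInterval(str(c), int(s), int(s + w))))
            d = int(rng.integers(0, 20_000))
            regions = stitch(peaks, stitch_distance=d)
            # pairwise gaps along each chromosome exceed the stitch distance
            by_chrom = {}
            for r in regions:
                by_chrom.setdefault(r.chrom, []).append(r)
            for rs in by_chrom.values():
                rs.sort(key=lambda r: r.start)
                for a, b in zip(rs[:-1], rs[1:]):
                    assert b.start - a.end > d
            # idempotence: stitching the merged intervals changes nothing
            again = stitch(
                [Peak(r.interval) for r in regions], stitch_distance=d
            )
            assert [(r.chrom, r.start, r.end) for r in again] == [
                (r.chrom, r.start, r.end) for r in regions
            ]
            # every constituent is conserved
            assert sum(len(r.constituents) for r in regions) == n

    def test_tss_exclusion_removes_contained_peaks(self):
        tss = TSSAnnotation([TSSRecord("g1", "chr1", 5000)])
        peaks = peaks_at([4800, 30_000])  # first is inside TSS +/- 2500
        regions = stitch(peaks, tss_exclusion=tss, tss_window=2500)
        assert [(r.start, r.end) for r in regions] == [(30_000, 30_100)]
        # a peak merely overlapping (not contained in) the window survives
        wide = [Peak(GenomicInterval("chr1", 7400, 7700))]
        assert len(stitch(wide, tss_exclusion=tss, tss_window=2500)) == 1


class TestGeometricCutoff:
    def test_single_outlier_worked_example(self):
        cutoff, index = geometric_cutoff([0] * 9 + [100])
        assert (cutoff, index) == (0.0, 9)

    def test_all_equal_means_no_superenhancers(self):
        cutoff, _ = geometric_cutoff([7.0, 7.0, 7.0])
        assert cutoff == 7.0  # nothing is strictly above it

    def test_fewer_than_two_values_rejected(self):
        with pytest.raises(ValueError):
            geometric_cutoff([1.0])

    def test_planted_outliers_over_exponential_background(self):
        rng = np.random.default_rng(7)
        v = np.concatenate([rng.exponential(1.0, 200), np.full(5, 500.0)])
        cutoff, _ = geometric_cutoff(v)
        assert int(np.sum(v > cutoff)) == 5  # exactly the planted values

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            n = int(rng.integers(2, 200))
            v = rng.exponential(1.0, n)
            if rng.random() < 0.5:
                v = np.round(v, 1)  # introduce ties
            assert geometric_cutoff(v) == brute_cutoff(v)

    def test_scale_invariance_of_index(self):
        rng = np.random.default_rng(2)
        v = rng.lognormal(0, 1.5, 300)
        _, i1 = geometric_cutoff(v)
        cut_scaled, i2 = geometric_cutoff(v * 37.5)
        assert i1 == i2
        labels1 = np.sort(v) > geometric_cutoff(v)[0]
        labels2 = np.sort(v * 37.5) > cut_scaled
        assert np.array_equal(labels1, labels2)


class TestCallSuperenhancers:
    def _toy(self):
        # 5 isolated typical peaks + one hot 3-peak cluster
        positions = [10_000, 60_000, 110_000, 160_000, 210_000]
        peaks = peaks_at(positions, width=500)
        cluster = peaks_at([300_000, 302_000, 304_000], width=500)
        runs = [("chr1", p.start, p.end, 1.0) for p in peaks]
        runs += [("chr1", p.start, p.end, 50.0) for p in cluster]
        track = SignalTrack.from_runs(runs)
        return peaks + cluster, track

    def test_planted_cluster_is_top_ranked_se(self):
        peaks, track = self._toy()
        res = call_superenhancers(peaks, track)
        assert len(res.regions) == 6
        (se,) = res.superenhancers()
        assert (se.start, se.end) == (300_000, 304_500)
        assert se.rank == 1

    def test_no_input_equals_zero_input(self):
        peaks, track = self._toy()
        zero_input = SignalTrack.from_runs([])
        a = call_superenhancers(peaks, track)
        b = call_superenhancers(peaks, track, zero_input)
        assert a.signals.tolist() == b.signals.tolist()
        assert a.labels == b.labels

    def test_single_region_rejected(self):
        peaks = peaks_at([0, 1000])  # stitches into one region
        track = SignalTrack.from_runs([("chr1", 0, 2000, 1.0)])
        with pytest.raises(ValueError, match="at least 2"):
            call_superenhancers(peaks, track)

    def test_invariant_to_peak_order(self):
        peaks, track = self._toy()
        rng = np.random.default_rng(0)
        shuffled = [peaks[i] for i in rng.permutation(len(peaks))]
        a = call_superenhancers(peaks, track)
        b = call_superenhancers(shuffled, track)
        assert [(r.start, r.end, r.label) for r in a.regions] == [
            (r.start, r.end, r.label) for r in b.regions
        ]

    def test_input_correction_lowers_signal(self):
        peaks, track = self._toy()
        input_track = SignalTrack.from_runs([("chr1", 0, 400_000, 0.5)])
        corrected = call_superenhancers(peaks, track, input_track)
        uncorrected = call_superenhancers(peaks, track)
        assert np.all(corrected.signals <= uncorrected.signals)


class TestReproduciblePeaks:
    def test_overlap_required_and_signals_averaged(self):
        rep1 = [
            Peak(GenomicInterval("chr1", 0, 100), signal=4.0),
            Peak(GenomicInterval("chr1", 1000, 1100), signal=9.0),
        ]
        rep2 = [Peak(GenomicInterval("chr1", 50, 150), signal=6.0)]
        out = reproducible_peaks(rep1, rep2)
        assert len(out) == 1
        assert out[0].start == 0 and out[0].signal == 5.0
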