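"""Interval model, readers, dataset/replicate filters, merging, ranking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fbscan.core import (
    CENTER_WINDOW,
    GenomicInterval,
    Peak,
    PeakSet,
    ParseError,
    center_window,
    coverage_summary,
    cumulative_curve,
    filter_dataset,
    merge_windows,
    overlap_sets,
    peak_center,
    rank_mps,
    read_peaks,
    reconcile_replicates,
)


def iv(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


def peakset(tf, intervals):
    return PeakSet(tf=tf, peaks=[Peak(i, tf=tf) for i in intervals])


class TestGenomicInterval:
    @pytest.mark.parametrize(
        "chrom,start,end", [("", 0, 10), ("chr1", -1, 10), ("chr1", 10, 10),
                            ("chr1", 10, 5)]
    )
    def test_invariants_rejected(self, chrom, start, end):
        with pytest.raises(ValueError):
            GenomicInterval(chrom, start, end)

    def test_overlap_is_half_open(self):
        assert iv(100, 200).overlaps(iv(199, 300))
        assert not iv(100, 200).overlaps(iv(200, 300))
        assert not iv(100, 200).overlaps(iv(100, 200, chrom="chr2"))


class TestReadPeaks:
    def test_bed3_and_narrowpeak(self, tmp_path):
        bed = tmp_path / "a.bed"
        bed.write_text("chr1\t100\t400\n")
        ps = read_peaks(bed, tf="TFA")
        assert ps.n_peaks == 1
        assert ps.peaks[0].interval == iv(100, 400)
        np_file = tmp_path / "a.narrowPeak"
        np_file.write_text(
            "chr1\t100\t400\tpk1\t0\t.\t7.5\t-1\t-1\t150\n")
        ps = read_peaks(np_file, tf="TFA", fmt="narrowPeak")
        assert ps.peaks[0].score == 7.5

    def test_malformed_line_names_line_number(self, tmp_path):
        bed = tmp_path / "bad.bed"
        bed.write_text("chr1\t100\t400\nchr1\t500\t450\n")
        with pytest.raises(ParseError, match=":2:"):
            read_peaks(bed, tf="TFA")

    def test_too_few_columns(self, tmp_path):
        bed = tmp_path / "bad.bed"
        bed.write_text("chr1\t100\n")
        with pytest.raises(ParseError, match=":1:"):
            read_peaks(bed, tf="TFA")


class TestDatasetFilter:
    @pytest.mark.parametrize("n,accepted", [(1999, False), (2000, True),
                                            (50_000, True)])
    def test_min_peaks_boundary(self, n, accepted):
        ps = peakset("TFA", [iv(i * 1000, i * 1000 + 100) for i in range(n)])
        assert filter_dataset(ps).accepted is accepted


def _uniform_peakset(tf, n, rng, width=300, span=10_000_000):
    starts = rng.integers(0, span, size=n)
    return peakset(tf, [iv(int(s), int(s) + width) for s in starts])


class TestReconcileReplicates:
    def test_rule1_keeps_dominant_replicate(self):
        big = peakset("T", [iv(i * 10_000, i * 10_000 + 100)
                            for i in range(10_000)])
        small = peakset("T", [iv(i * 10_000 + 5_000, i * 10_000 + 5_100)
                              for i in range(2_800)])
        res = reconcile_replicates([small, big])
        assert res.accepted and res.rule == "rule1"
        assert res.peakset.n_peaks == 10_000

    def test_rule2_overlapping_set(self):
        # 3,500 of the larger replicate's peaks coincide with the smaller's
        a = [iv(i * 1000, i * 1000 + 200) for i in range(5000)]
        b = [iv(i * 1000 + 100, i * 1000 + 300) for i in range(3500)]
        b += [iv(10_000_000 + i * 1000, 10_000_000 + i * 1000 + 200)
              for i in range(500)]
        res = reconcile_replicates([peakset("T", a), peakset("T", b)])
        assert res.accepted and res.rule == "rule2"
        assert res.peakset.n_peaks == 3500

    def test_low_concordance_rejected(self):
        # 1,200 overlaps: below 3000 and below 40% of both replicates
        a = [iv(i * 1000, i * 1000 + 200) for i in range(5000)]
        b = [iv(i * 1000 + 100, i * 1000 + 300) for i in range(1200)]
        b += [iv(20_000_000 + i * 1000, 20_000_000 + i * 1000 + 200)
              for i in range(2800)]
        res = reconcile_replicates([peakset("T", a), peakset("T", b)])
        assert not res.accepted and res.rule == "rejected"

    def test_rule2_symmetric_in_replicate_order(self):
        a = [iv(i * 1000, i * 1000 + 200) for i in range(5000)]
        b = [iv(i * 1000 + 100, i * 1000 + 300) for i in range(3500)]
        r1 = reconcile_replicates([peakset("T", a), peakset("T", b)])
        r2 = reconcile_replicates([peakset("T", b), peakset("T", a)])
        assert [p.interval for p in r1.peakset.peaks] == [
            p.interval for p in r2.peakset.peaks]

    def test_three_replicates_picks_most_concordant_pair(self):
        shared = [iv(i * 1000, i * 1000 + 200) for i in range(4000)]
        r1 = peakset("T", shared)
        r2 = peakset("T", [iv(s.start + 50, s.end + 50) for s in shared])
        rng = np.random.default_rng(0)
        r3 = _uniform_peakset("T", 4000, rng)
        res = reconcile_replicates([r3, r1, r2])
        assert res.accepted and res.rule == "rule2"
        assert res.peakset.n_peaks == 4000

    def test_mixed_tfs_and_empty_rejected(self):
        with pytest.raises(ValueError):
            reconcile_replicates([])
        with pytest.raises(ValueError):
            reconcile_replicates(
                [peakset("A", [iv(0, 10)] * 1), peakset("B", [iv(0, 10)])])


class TestCenterWindow:
    @pytest.mark.parametrize("interval,center", [
        (iv(100, 400), 250), (iv(100, 401), 250), (iv(0, 1), 0),
    ])
    def test_peak_center_floor(self, interval, center):
        assert peak_center(Peak(interval, tf="T")) == center

    def test_window_is_centered(self):
        p = Peak(iv(100, 400), tf="T")
        assert center_window(p, 300) == iv(100, 400)

    def test_left_edge_clip(self):
        p = Peak(iv(50, 150), tf="T")  # center 100
        assert center_window(p, 300) == iv(0, 250)

    def test_narrow_peak_gets_full_width_window(self):
        p = Peak(iv(1000, 1100), tf="T")  # 100 bp peak, center 1050
        w = center_window(p, 300)
        assert w.width == 300 and w.midpoint == 1050

    def test_chromosome_end_clip(self):
        p = Peak(iv(900, 1000), tf="T")
        w = center_window(p, 300, chrom_sizes={"chr1": 1000})
        assert w == iv(800, 1000)


def _brute_union_bp(windows):
    """O(n * span) union length by painting bases."""
    by_chrom = {}
    for w in windows:
        by_chrom.setdefault(w.chrom, set()).update(range(w.start, w.end))
    return sum(len(s) for s in by_chrom.values())


class TestMergeWindows:
    def test_bookended_windows_merge(self):
        mps = merge_windows([(iv(100, 400), "A", 250),
                             (iv(400, 700), "B", 550)])
        assert len(mps) == 1
        assert mps[0].interval == iv(100, 700)
        assert mps[0].n_points == 2 and mps[0].n_tfs == 2

    def test_gap_preserved(self):
        mps = merge_windows([(iv(100, 400), "A", 250),
                             (iv(500, 700), "B", 600)])
        assert [m.interval for m in mps] == [iv(100, 400), iv(500, 700)]

    def test_union_matches_brute_force_and_conserves_centers(self):
        rng = np.random.default_rng(42)
        windows = []
        for i in range(1000):
            chrom = f"chr{rng.integers(1, 4)}"
            s = int(rng.integers(0, 20_000))
            w = int(rng.integers(1, 400))
            windows.append((GenomicInterval(chrom, s, s + w), f"T{i % 7}",
                            s + w // 2))
        mps = merge_windows(windows)
        assert sum(m.n_points for m in mps) == len(windows)
        merged_bp = sum(m.interval.width for m in mps)
        assert merged_bp == _brute_union_bp([w for w, _, _ in windows])
        # disjoint and sorted within each chromosome
        for chrom in {m.interval.chrom for m in mps}:
            ivs = [m.interval for m in mps if m.interval.chrom == chrom]
            for a, b in zip(ivs, ivs[1:]):
                assert a.end < b.start

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 3000), st.integers(1, 300)),
                    min_size=1, max_size=60))
    def test_union_length_property(self, raw):
        windows = [(iv(s, s + w), "T", s + w // 2) for s, w in raw]
        mps = merge_windows(windows)
        assert sum(m.interval.width for m in mps) == _brute_union_bp(
            [w for w, _, _ in windows])
        assert sum(m.n_points for m in mps) == len(windows)


class TestRanking:
    def _mps(self, counts):
        windows = []
        for i, c in enumerate(counts):
            base = i * 10_000
            for j in range(c):
                windows.append((iv(base, base + 300), f"T{j}", base + 150))
        return merge_windows(windows)

    def test_rank_descending_with_genomic_tiebreak(self):
        ranked = rank_mps(self._mps([1, 8, 1]))
        assert [m.n_points for m in ranked] == [8, 1, 1]
        assert ranked[0].rank == 1
        assert ranked[1].interval.start < ranked[2].interval.start

    def test_rank_is_permutation_invariant(self):
        mps = self._mps([3, 1, 4, 1, 5])
        a = rank_mps(mps)
        b = rank_mps(list(reversed(mps)))
        assert [(m.interval, m.rank) for m in a] == [
            (m.interval, m.rank) for m in b]

    @pytest.mark.parametrize("counts,level,k", [
        ([8, 1, 1], 0.8, 1), ([8, 1, 1], 1.0, 3), ([5, 5], 0.5, 1),
    ])
    def test_cumulative_curve(self, counts, level, k):
        assert cumulative_curve(rank_mps(self._mps(counts)), level) == k

    def test_cumulative_curve_non_decreasing_in_level(self):
        ranked = rank_mps(self._mps([7, 3, 3, 2, 1]))
        ks = [cumulative_curve(ranked, lv)
              for lv in (0.1, 0.3, 0.5, 0.7, 0.9, 1.0)]
        assert ks == sorted(ks)


class TestCoverageAndOverlap:
    def test_coverage_identity_and_empty(self):
        ref = [iv(0, 100), iv(200, 300)]
        centers = {"chr1": np.array([10, 50, 250])}
        full = coverage_summary(ref, ref, centers)
        assert full.bp_fraction == 1.0 and full.event_fraction == 1.0
        empty = coverage_summary([], ref, centers)
        assert empty.bp_fraction == 0.0 and empty.event_fraction == 0.0

    def test_coverage_matches_direct_count(self):
        rng = np.random.default_rng(7)
        ref = [iv(i * 1000, i * 1000 + 500) for i in range(50)]
        sites = [iv(i * 1000 + 100, i * 1000 + 200) for i in range(0, 50, 3)]
        pos = np.sort(rng.integers(0, 50_000, size=400))
        centers = {"chr1": pos}
        cs = coverage_summary(sites, ref, centers)
        in_ref = [p for p in pos
                  if any(r.start <= p < r.end for r in ref)]
        in_site = [p for p in pos
                   if any(s.start <= p < s.end for s in sites)]
        assert cs.event_fraction == pytest.approx(
            len(in_site) / len(in_ref))
        assert cs.bp_fraction == pytest.approx(
            sum(s.width for s in sites) / sum(r.width for r in ref))

    def test_overlap_sets_vs_all_pairs_oracle(self):
        rng = np.random.default_rng(11)
        def rand_ivs(n):
            out = []
            for _ in range(n):
                chrom = f"chr{rng.integers(1, 3)}"
                s = int(rng.integers(0, 5000))
                out.append(GenomicInterval(chrom, s, s + int(
                    rng.integers(1, 300))))
            return out
        a, b = rand_ivs(80), rand_ivs(60)
        expected = sum(1 for x in a if any(x.overlaps(y) for y in b))
        assert overlap_sets(a, b) == expected
        assert overlap_sets(a, a) == len(a)
        assert overlap_sets(a, []) == 0
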