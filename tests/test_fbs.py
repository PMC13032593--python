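"""The three-step focused-binding-site caller."""

import numpy as np
import pytest
from collections import Counter

from fbscan.core import GenomicInterval, MergedPeak
from fbscan.fbs import (
    BinDensityTable,
    CandidateFBS,
    CountDistribution,
    assign_width_group,
    bin_point_counts,
    build_density_table,
    call_fbs,
    candidate_fbs,
    derive_threshold,
    profile_distribution,
    quantile_count,
    select_fbs,
    sensitivity_curve,
)


def mp_from_centers(centers, start, end, chrom="chr1", rank=None):
    return MergedPeak(
        interval=GenomicInterval(chrom, start, end),
        centers=[("T", int(c)) for c in centers],
        rank=rank,
    )


def mp_from_bin_counts(counts, bin_width=10, start=0):
    """An MP whose 10-bp bin counts equal ``counts`` (centers at bin mids)."""
    centers = []
    for i, c in enumerate(counts):
        centers.extend([start + i * bin_width + 5] * c)
    return mp_from_centers(centers, start, start + len(counts) * bin_width)


class TestBinning:
    def test_direct_binning(self):
        mp = mp_from_centers([12, 15, 27], 0, 40)
        bins = bin_point_counts(mp, 10)
        assert [c for _, c in bins] == [0, 2, 1, 0]
        assert bins[1][0] == GenomicInterval("chr1", 10, 20)

    def test_empty_region_all_zero(self):
        mp = mp_from_centers([5], 0, 50)
        assert [c for _, c in bin_point_counts(mp, 10)] == [1, 0, 0, 0, 0]

    def test_counts_conserved(self):
        rng = np.random.default_rng(3)
        centers = rng.integers(1000, 6000, size=500)
        mp = mp_from_centers(centers, 1000, 6000)
        assert sum(c for _, c in bin_point_counts(mp)) == 500

    def test_partial_last_bin_kept(self):
        mp = mp_from_centers([44], 0, 45)
        bins = bin_point_counts(mp, 10)
        assert bins[-1][0] == GenomicInterval("chr1", 40, 45)
        assert bins[-1][1] == 1


class TestThreshold:
    def test_empirical_cdf_example(self):
        # 90 bins of count 0 and 10 of count 5: 90% of bins lie below 5
        table = BinDensityTable(10, Counter({0: 90, 5: 10}))
        assert derive_threshold(table, 0.90) == 5

    def test_degenerate_all_equal_warns(self, caplog):
        table = BinDensityTable(10, Counter({3: 42}))
        with caplog.at_level("WARNING", logger="fbscan"):
            assert derive_threshold(table, 0.90) == 3
        assert "degenerate" in caplog.text

    def test_zero_bins_are_included_in_the_table(self):
        # one dense MP + one empty-ish MP: zeros pull the threshold down
        dense = mp_from_bin_counts([5] * 10)
        sparse = mp_from_centers([100_005], 100_000, 100_900)
        table = build_density_table([dense, sparse])
        assert table.n_bins == 10 + 90
        assert derive_threshold(table, 0.90) == 5

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            derive_threshold(BinDensityTable(10, Counter()))


class TestCandidates:
    def test_short_runs_discarded(self):
        mp = mp_from_bin_counts([0, 1, 5, 6, 4, 2, 7, 0])
        assert candidate_fbs(mp, c_t=4) == []

    def test_single_run_combined(self):
        mp = mp_from_bin_counts([5, 4, 4, 6])
        (cand,) = candidate_fbs(mp, c_t=4)
        assert cand.interval == GenomicInterval("chr1", 0, 40)
        assert cand.width == 40 and cand.total_count == 19

    def test_all_below_threshold(self):
        mp = mp_from_bin_counts([1, 2, 3, 1])
        assert candidate_fbs(mp, c_t=4) == []

    def test_two_separated_runs(self):
        mp = mp_from_bin_counts([4, 4, 4, 4, 0, 5, 5, 5, 5, 5])
        cands = candidate_fbs(mp, c_t=4)
        assert [(c.interval.start, c.interval.end) for c in cands] == [
            (0, 40), (50, 100)]

    def test_min_width_never_violated(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            counts = rng.integers(0, 8, size=30).tolist()
            mp = mp_from_bin_counts(counts)
            for cand in candidate_fbs(mp, c_t=4):
                assert cand.width >= 40


class TestDistributions:
    def test_window_count_in_one_mp(self):
        mp = mp_from_centers([10, 50, 230], 0, 240)
        d = profile_distribution([mp], unit_length=200, step=20)
        assert len(d.samples) == 3  # (240 - 200) / 20 + 1

    def test_short_mp_contributes_whole_window(self):
        mp = mp_from_centers([10, 20, 30], 0, 100)
        d = profile_distribution([mp], unit_length=200)
        assert list(d.samples) == [3]
        d_skip = profile_distribution([mp], unit_length=200,
                                      short_mp_policy="skip")
        assert len(d_skip.samples) == 0

    def test_uniform_centers_mean_matches_density(self):
        rng = np.random.default_rng(9)
        span, n = 100_000, 5000
        mp = mp_from_centers(rng.integers(0, span, size=n), 0, span)
        L = 200
        d = profile_distribution([mp], unit_length=L, step=20)
        expected = n / span * L
        se = np.sqrt(expected) / np.sqrt(len(d.samples) / (L // 20))
        assert abs(d.samples.mean() - expected) < 3 * max(se, 0.2)

    def test_shorter_windows_give_stochastically_smaller_counts(self):
        rng = np.random.default_rng(13)
        mp = mp_from_centers(rng.integers(0, 10_000, size=800), 0, 10_000)
        d80 = profile_distribution([mp], 80)
        d200 = profile_distribution([mp], 200)
        for pct in (50, 90, 95, 99):
            assert quantile_count(d80, pct) <= quantile_count(d200, pct)


class TestQuantile:
    def test_nearest_rank_definition(self):
        d = CountDistribution(200, np.arange(1, 101))
        assert quantile_count(d, 95) == 95
        assert quantile_count(d, 0.5) == 1

    def test_constant_samples(self):
        d = CountDistribution(200, np.full(50, 7))
        for pct in (10, 50, 95):
            assert quantile_count(d, pct) == 7

    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(21)
        samples = rng.integers(0, 60, size=997)
        d = CountDistribution(200, samples)
        for pct in (5, 50, 90, 95, 98):
            srt = sorted(samples)
            k = int(np.ceil(pct / 100 * len(srt)))
            assert quantile_count(d, pct) == srt[k - 1]

    def test_invalid_pct_rejected(self):
        d = CountDistribution(200, np.arange(10))
        for pct in (0, 100, -5):
            with pytest.raises(ValueError):
                quantile_count(d, pct)


class TestWidthGroups:
    @pytest.mark.parametrize("width,group", [
        (40, 80), (95, 80), (99, 80), (100, 100), (110, 100), (119, 100),
        (120, 120), (140, 140), (160, 160), (180, 180), (199, 180),
        (200, 200), (350, 200),
    ])
    def test_mapping(self, width, group):
        assert assign_width_group(width) == group


def _dist_with_quantile(unit_length, q95):
    """Samples whose nearest-rank 95% quantile is exactly ``q95``."""
    samples = np.concatenate([np.zeros(94, dtype=int),
                              np.full(6, q95, dtype=int)])
    d = CountDistribution(unit_length, samples)
    assert quantile_count(d, 95) == q95
    return d


class TestSelection:
    def test_threshold_is_inclusive(self):
        # quantile 58: a candidate with total count 58 is kept, 57 dropped
        dists = {100: _dist_with_quantile(100, 58)}
        mk = lambda count, start: CandidateFBS(
            GenomicInterval("chr1", start, start + 110), None, count)
        kept = select_fbs([mk(58, 0), mk(57, 1000)], dists, 95)
        assert [f.total_count for f in kept] == [58]
        assert kept[0].width_group == 100 and kept[0].tier == 95

    def test_higher_percentile_selects_subset(self, default_call):
        _, result = default_call
        sets = {
            pct: {f.interval for f in result.fbs_by_pct[pct]}
            for pct in (90, 95, 98)
        }
        assert sets[98] <= sets[95] <= sets[90]

    def test_selection_matches_brute_force(self):
        rng = np.random.default_rng(31)
        dists = {L: CountDistribution(L, rng.integers(0, 30, size=200))
                 for L in (80, 100, 120, 140, 160, 180, 200)}
        cands = []
        for i in range(100):
            w = int(rng.integers(40, 320))
            s = i * 1000
            cands.append(CandidateFBS(
                GenomicInterval("chr1", s, s + w), None,
                int(rng.integers(0, 40))))
        for pct in (85, 90, 95, 98):
            kept = select_fbs(cands, dists, pct)
            expected = {
                (c.interval, c.total_count)
                for c in cands
                if c.total_count >= quantile_count(
                    dists[assign_width_group(c.width)], pct)
            }
            assert {(f.interval, f.total_count) for f in kept} == expected

    def test_missing_distribution_is_an_error(self):
        c = CandidateFBS(GenomicInterval("chr1", 0, 50), None, 10)
        with pytest.raises(KeyError):
            select_fbs([c], {200: _dist_with_quantile(200, 5)}, 95)


class TestSensitivity:
    def test_curve_counts_match_repeated_selection(self, default_call):
        _, result = default_call
        curve = sensitivity_curve(result.candidates, result.distributions)
        for pct, n in curve.items():
            assert n == len(select_fbs(result.candidates,
                                       result.distributions, pct))

    def test_monotone_non_increasing(self, default_call):
        _, result = default_call
        curve = sensitivity_curve(result.candidates, result.distributions,
                                  pcts=(85, 90, 95, 98))
        ns = [curve[p] for p in (85, 90, 95, 98)]
        assert ns == sorted(ns, reverse=True)


class TestCallerInvariants:
    def test_fbss_lie_in_disjoint_positions(self, default_call):
        mps, result = default_call
        for pct, fbss in result.fbs_by_pct.items():
            ordered = sorted(fbss, key=lambda f: (f.interval.chrom,
                                                  f.interval.start))
            for a, b in zip(ordered, ordered[1:]):
                if a.interval.chrom == b.interval.chrom:
                    assert a.interval.end <= b.interval.start

    def test_every_fbs_inside_one_mp(self, default_call):
        mps, result = default_call
        mp_ivs = [m.interval for m in mps]
        for f in result.fbs_by_pct[90]:
            hits = [m for m in mp_ivs
                    if m.chrom == f.interval.chrom
                    and m.start <= f.interval.start
                    and f.interval.end <= m.end]
            assert len(hits) == 1

    def test_kept_plus_dropped_is_all_candidates(self, default_call):
        _, result = default_call
        kept = {f.interval for f in result.fbs_by_pct[90]}
        dropped = {c.interval for c in result.candidates} - kept
        assert len(kept) + len(dropped) == len(result.candidates)
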