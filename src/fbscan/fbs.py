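"""Calling focused TF binding sites (FBSs) inside TF-enriched merged peaks.

The caller works on peak *center points* only. Within the top TF-enriched
MPs it proceeds in three steps:

1. scan each MP in consecutive non-overlapping 10-bp bins, build the
   empirical bin-density table over all scanned bins, derive the threshold
   count C_T at the ~90% level, combine runs of consecutive bins with
   count >= C_T into candidate windows, and discard windows under 40 bp;
2. profile the distribution D_L of TF-point counts in sliding windows of
   unit length L (80-200 bp, step 20 bp) across the same MPs;
3. keep a candidate iff its total count reaches the right-tail percentile
   (e.g. the 90th or 95th) of the distribution matching its width group.

All steps are deterministic given the MPs; percentiles are nearest-rank so
thresholds are realizable counts.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import GenomicInterval, MergedPeak

logger = logging.getLogger("fbscan")

DEFAULT_BIN = 10
DEFAULT_DENSITY_LEVEL = 0.90
DEFAULT_MIN_WIDTH = 40
DEFAULT_STEP = 20
UNIT_LENGTHS = (80, 100, 120, 140, 160, 180, 200)


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass
class BinDensityTable:
    """Histogram of TF-point counts per bin over all scanned MP bins."""

    bin_width: int
    counts_histogram: Counter
    c_t: int | None = None

    @property
    def n_bins(self) -> int:
        return sum(self.counts_histogram.values())


@dataclass
class CandidateFBS:
    """A run of dense bins inside one MP, before percentile selection."""

    interval: GenomicInterval
    mp_rank: int | None
    total_count: int

    @property
    def width(self) -> int:
        return self.interval.width


@dataclass
class CountDistribution:
    """Empirical distribution D_L of window TF-point counts at one length."""

    unit_length: int
    samples: np.ndarray  # sorted int counts

    def __post_init__(self) -> None:
        self.samples = np.sort(np.asarray(self.samples, dtype=np.int64))

    def quantile(self, pct: float) -> int:
        return quantile_count(self, pct)


@dataclass
class FBS:
    """A focused TF binding site selected at a percentile tier."""

    interval: GenomicInterval
    total_count: int
    width_group: int
    tier: float
    mp_rank: int | None = None
    promoter_flag: bool | None = None
    cell: str = ""

    @property
    def width(self) -> int:
        return self.interval.width


@dataclass
class FBSCallResult:
    """All intermediates of one caller run, for reporting and export."""

    density_table: BinDensityTable
    candidates: list[CandidateFBS]
    distributions: dict[int, CountDistribution]
    fbs_by_pct: dict[float, list[FBS]]


# ---------------------------------------------------------------------------
# Step 1: bin scanning, density table, candidate windows
# ---------------------------------------------------------------------------

def bin_point_counts(
    mp: MergedPeak, bin_width: int = DEFAULT_BIN
) -> list[tuple[GenomicInterval, int]]:
    """TF-point counts in consecutive non-overlapping bins across one MP.

    The bin grid is anchored at the MP start and the last partial bin is
    kept, so the counts sum to the MP's n_points.
    """
    start, end = mp.interval.start, mp.interval.end
    n_bins = -(-(end - start) // bin_width)  # ceil
    counts = np.zeros(n_bins, dtype=np.int64)
    for _, pos in mp.centers:
        counts[(pos - start) // bin_width] += 1
    out = []
    for i in range(n_bins):
        b_start = start + i * bin_width
        b_end = min(b_start + bin_width, end)
        out.append((GenomicInterval(mp.interval.chrom, b_start, b_end),
                    int(counts[i])))
    return out


def build_density_table(
    mps: Iterable[MergedPeak], bin_width: int = DEFAULT_BIN
) -> BinDensityTable:
    """Pool per-bin counts of all scanned MPs (zero-count bins included)."""
    hist: Counter = Counter()
    for mp in mps:
        start, end = mp.interval.start, mp.interval.end
        n_bins = -(-(end - start) // bin_width)
        counts = np.zeros(n_bins, dtype=np.int64)
        for _, pos in mp.centers:
            counts[(pos - start) // bin_width] += 1
        vals, freqs = np.unique(counts, return_counts=True)
        for v, f in zip(vals, freqs):
            hist[int(v)] += int(f)
    return BinDensityTable(bin_width=bin_width, counts_histogram=hist)


def derive_threshold(
    table: BinDensityTable, level: float = DEFAULT_DENSITY_LEVEL
) -> int:
    """Threshold count C_T at the given density level.

    C_T is the smallest observed count c such that the fraction of bins
    with a *smaller* count is at least ``level``. If no observed count
    qualifies (e.g. all bins share one count), the maximum observed count
    is returned with a warning.
    """
    if not table.counts_histogram:
        raise ValueError("empty density table")
    total = table.n_bins
    below = 0
    for c in sorted(table.counts_histogram):
        if below / total >= level:
            table.c_t = int(c)
            return table.c_t
        below += table.counts_histogram[c]
    c_max = max(table.counts_histogram)
    logger.warning(
        "degenerate bin-count histogram: no count has %.0f%% of bins below "
        "it; using max observed count %d as C_T", 100 * level, c_max,
    )
    table.c_t = int(c_max)
    return table.c_t


def candidate_fbs(
    mp: MergedPeak,
    c_t: int,
    min_width: int = DEFAULT_MIN_WIDTH,
    bin_width: int = DEFAULT_BIN,
) -> list[CandidateFBS]:
    """Runs of consecutive bins with count >= C_T, width-filtered.

    Candidate intervals are bin-grid aligned (clipped to the MP end for a
    partial last bin); total_count is recounted over the final interval.
    """
    if c_t < 1:
        raise ValueError("c_t must be >= 1")
    bins = bin_point_counts(mp, bin_width)
    positions = np.sort(np.array([pos for _, pos in mp.centers],
                                 dtype=np.int64))
    out: list[CandidateFBS] = []
    run_start: int | None = None
    prev_end = None
    for iv, count in bins + [(None, -1)]:  # sentinel flushes the last run
        if iv is not None and count >= c_t:
            if run_start is None:
                run_start = iv.start
            prev_end = iv.end
        elif run_start is not None:
            if prev_end - run_start >= min_width:
                lo = int(np.searchsorted(positions, run_start, "left"))
                hi = int(np.searchsorted(positions, prev_end, "left"))
                out.append(
                    CandidateFBS(
                        interval=GenomicInterval(
                            mp.interval.chrom, run_start, prev_end),
                        mp_rank=mp.rank,
                        total_count=hi - lo,
                    )
                )
            run_start = None
    return out


# ---------------------------------------------------------------------------
# Step 2: count distributions per unit length
# ---------------------------------------------------------------------------

def profile_distribution(
    mps: Sequence[MergedPeak],
    unit_length: int,
    step: int = DEFAULT_STEP,
    short_mp_policy: str = "whole",
) -> CountDistribution:
    """Sample TF-point counts of step-spaced windows of one length.

    Windows lie fully inside an MP. MPs shorter than ``unit_length``
    contribute one whole-MP window by default (``short_mp_policy="skip"``
    drops them instead).
    """
    if not mps:
        raise ValueError("no MPs to profile")
    samples: list[int] = []
    for mp in mps:
        positions = np.sort(np.array([p for _, p in mp.centers],
                                     dtype=np.int64))
        start, end = mp.interval.start, mp.interval.end
        if end - start < unit_length:
            if short_mp_policy == "whole":
                samples.append(len(positions))
            continue
        w_starts = np.arange(start, end - unit_length + 1, step,
                             dtype=np.int64)
        lo = np.searchsorted(positions, w_starts, side="left")
        hi = np.searchsorted(positions, w_starts + unit_length, side="left")
        samples.extend((hi - lo).tolist())
    return CountDistribution(unit_length=unit_length,
                             samples=np.array(samples, dtype=np.int64))


def quantile_count(d: CountDistribution, pct: float) -> int:
    """Nearest-rank right-tail quantile: smallest count with CDF >= pct/100."""
    if not 0 < pct < 100:
        raise ValueError("pct must be in (0, 100)")
    if len(d.samples) == 0:
        raise ValueError("empty sample set")
    idx = int(np.ceil(pct / 100 * len(d.samples))) - 1
    return int(d.samples[idx])


def profile_all_distributions(
    mps: Sequence[MergedPeak],
    unit_lengths: Sequence[int] = UNIT_LENGTHS,
    step: int = DEFAULT_STEP,
    short_mp_policy: str = "whole",
) -> dict[int, CountDistribution]:
    return {
        L: profile_distribution(mps, L, step, short_mp_policy)
        for L in unit_lengths
    }


# ---------------------------------------------------------------------------
# Step 3: width groups, percentile selection, sensitivity curve
# ---------------------------------------------------------------------------

def assign_width_group(width: int) -> int:
    """Unit length whose distribution selects a candidate of this width.

    Width groups: below 100 bp -> D_80; [100, 120) -> D_100; ... ;
    [180, 200) -> D_180; 200 bp and above -> D_200.
    """
    if width < 40:
        raise ValueError("candidate widths below 40 bp are filtered earlier")
    if width < 100:
        return 80
    if width >= 200:
        return 200
    return 100 + 20 * ((width - 100) // 20)


def select_fbs(
    candidates: Sequence[CandidateFBS],
    dists: Mapping[int, CountDistribution],
    pct: float,
    cell: str = "",
) -> list[FBS]:
    """Keep candidates whose total count reaches the percentile threshold.

    A candidate is kept iff total_count >= the nearest-rank ``pct``
    quantile of the distribution for its width group. Output is sorted
    genomically.
    """
    out: list[FBS] = []
    for cand in candidates:
        group = assign_width_group(cand.width)
        if group not in dists:
            raise KeyError(f"no count distribution for unit length {group}")
        if cand.total_count >= quantile_count(dists[group], pct):
            out.append(
                FBS(interval=cand.interval, total_count=cand.total_count,
                    width_group=group, tier=pct, mp_rank=cand.mp_rank,
                    cell=cell)
            )
    out.sort(key=lambda f: (f.interval.chrom, f.interval.start))
    return out


def sensitivity_curve(
    candidates: Sequence[CandidateFBS],
    dists: Mapping[int, CountDistribution],
    pcts: Sequence[float] = (85, 90, 95, 98),
) -> dict[float, int]:
    """Number of selected FBSs at each threshold percentile."""
    return {pct: len(select_fbs(candidates, dists, pct)) for pct in pcts}


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def call_fbs(
    ranked_mps: Sequence[MergedPeak],
    top_mps: int | None = None,
    bin_width: int = DEFAULT_BIN,
    level: float = DEFAULT_DENSITY_LEVEL,
    min_width: int = DEFAULT_MIN_WIDTH,
    step: int = DEFAULT_STEP,
    unit_lengths: Sequence[int] = UNIT_LENGTHS,
    pcts: Sequence[float] = (90, 95),
    cell: str = "",
) -> FBSCallResult:
    """Run the full three-step caller on ranked MPs.

    ``top_mps`` restricts scanning to the most TF-enriched MPs (the study
    design: FBSs are a refinement of highly TF-bound loci); ``None`` scans
    all supplied MPs.
    """
    scanned = list(ranked_mps[:top_mps]) if top_mps else list(ranked_mps)
    if not scanned:
        raise ValueError("no MPs to scan")
    table = build_density_table(scanned, bin_width)
    c_t = derive_threshold(table, level)
    candidates = [
        c
        for mp in scanned
        for c in candidate_fbs(mp, c_t, min_width, bin_width)
    ]
    dists = profile_all_distributions(scanned, unit_lengths, step)
    fbs_by_pct = {
        pct: select_fbs(candidates, dists, pct, cell=cell) for pct in pcts
    }
    logger.info(
        "scanned %d MPs: C_T=%d, %d candidates, %s",
        len(scanned), c_t, len(candidates),
        {p: len(v) for p, v in fbs_by_pct.items()},
    )
    return FBSCallResult(
        density_table=table,
        candidates=candidates,
        distributions=dists,
        fbs_by_pct=fbs_by_pct,
    )


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def write_fbs_bed(fbss: Sequence[FBS], path: str | Path) -> None:
    """BED6 with name ``FBS_<tier>_<idx>`` and score = total_count."""
    with open(path, "w") as fh:
        for i, f in enumerate(fbss, start=1):
            fh.write(
                f"{f.interval.chrom}\t{f.interval.start}\t{f.interval.end}"
                f"\tFBS_P{f.tier:g}_{i}\t{f.total_count}\t.\n"
            )


def write_fbs_tsv(fbss: Sequence[FBS], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\ttotal_count\twidth_group\ttier"
                 "\tmp_rank\tpromoter\n")
        for f in fbss:
            fh.write(
                f"{f.interval.chrom}\t{f.interval.start}\t{f.interval.end}"
                f"\t{f.total_count}\t{f.width_group}\t{f.tier:g}"
                f"\t{f.mp_rank}\t{f.promoter_flag}\n"
            )


def write_density_table(table: BinDensityTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("count\tn_bins\n")
        for c in sorted(table.counts_histogram):
            fh.write(f"{c}\t{table.counts_histogram[c]}\n")


def write_sensitivity_curve(curve: Mapping[float, int],
                            path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("pct\tn_selected\n")
        for pct in sorted(curve):
            fh.write(f"{pct:g}\t{curve[pct]}\n")
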