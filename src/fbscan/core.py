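"""Genomic data model, standard-format I/O and peak preprocessing.

Foundation for the focused-binding-site pipeline: interval arithmetic on
0-based half-open coordinates, readers for BED/narrowPeak/chromosome-size
files, the dataset and replicate quality filters applied to per-TF ChIP-seq
peak sets, peak-center windows, bedtools-style merging into merged peaks
(MPs), MP ranking by TF-peak content, and coverage summaries.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger("fbscan")

# Pipeline-wide defaults (units: bp unless noted).
MIN_PEAKS_PER_DATASET = 2000      # datasets below this are discarded
REPLICATE_RATIO = 3.0             # rule 1: one replicate > 3x the other
REPLICATE_LOW_COUNT = 3000        # rule 1: lesser replicate below this fails
REPLICATE_OVERLAP_COUNT = 3000    # rule 2: overlapping peaks above this pass
REPLICATE_OVERLAP_FRACTION = 0.4  # rule 2: or > 40% of at least one replicate
CENTER_WINDOW = 300               # width of the peak-center window


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share at least 1 bp."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Peak:
    """One called ChIP-seq peak for a TF."""

    interval: GenomicInterval
    tf: str
    lab: str = ""
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.tf:
            raise ValueError("tf must be non-empty")

    @property
    def center(self) -> int:
        """Peak center point: floor of the interval midpoint."""
        return self.interval.midpoint


@dataclass
class PeakSet:
    """All called peaks of one ChIP-seq experiment (one TF)."""

    tf: str
    peaks: list[Peak]

    def __post_init__(self) -> None:
        for p in self.peaks:
            if p.tf != self.tf:
                raise ValueError(
                    f"peak TF {p.tf!r} does not match set TF {self.tf!r}"
                )

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)


@dataclass
class MergedPeak:
    """A maximal merged interval of peak-center windows (an MP).

    ``centers`` keeps every contributing (tf, center position) pair so that
    downstream density scanning can recount TF points inside sub-windows.
    """

    interval: GenomicInterval
    centers: list[tuple[str, int]]
    rank: int | None = None

    def __post_init__(self) -> None:
        for tf, pos in self.centers:
            if not (self.interval.start <= pos < self.interval.end):
                raise ValueError(
                    f"center {tf}:{pos} outside MP {self.interval}"
                )

    @property
    def n_points(self) -> int:
        return len(self.centers)

    @property
    def n_tfs(self) -> int:
        return len({tf for tf, _ in self.centers})


@dataclass(frozen=True)
class CoverageSummary:
    """Base-pair and binding-event fractions of a site set vs a reference."""

    bp_fraction: float
    event_fraction: float


@dataclass(frozen=True)
class FilterResult:
    """Outcome of a dataset-level quality filter."""

    accepted: bool
    reason: str | None = None


@dataclass(frozen=True)
class ReconcileResult:
    """Outcome of replicate reconciliation for one TF."""

    peakset: "PeakSet | None"
    rule: str            # "single", "rule1", "rule2", "rejected"
    accepted: bool
    detail: str = ""


# ---------------------------------------------------------------------------
# Interval array helpers (shared by all modules)
# ---------------------------------------------------------------------------

def intervals_by_chrom(
    intervals: Iterable[GenomicInterval],
) -> dict[str, np.ndarray]:
    """Group intervals into per-chromosome (n, 2) start/end arrays, sorted."""
    acc: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for iv in intervals:
        acc[iv.chrom].append((iv.start, iv.end))
    return {
        chrom: np.array(sorted(pairs), dtype=np.int64).reshape(-1, 2)
        for chrom, pairs in acc.items()
    }


def merge_interval_array(arr: np.ndarray) -> np.ndarray:
    """Union of sorted intervals on one chromosome; bookended runs merge."""
    if len(arr) == 0:
        return arr.reshape(0, 2)
    out: list[list[int]] = [[int(arr[0, 0]), int(arr[0, 1])]]
    for s, e in arr[1:]:
        if s <= out[-1][1]:  # overlap or touch
            out[-1][1] = max(out[-1][1], int(e))
        else:
            out.append([int(s), int(e)])
    return np.array(out, dtype=np.int64)


def total_bp(intervals: Iterable[GenomicInterval]) -> int:
    """Total bases covered by the union of the intervals."""
    n = 0
    for arr in intervals_by_chrom(intervals).values():
        merged = merge_interval_array(arr)
        n += int((merged[:, 1] - merged[:, 0]).sum())
    return n


def points_in_intervals(
    points: dict[str, np.ndarray], intervals: Iterable[GenomicInterval]
) -> int:
    """Count points (per-chrom sorted position arrays) inside the union."""
    count = 0
    grouped = intervals_by_chrom(intervals)
    for chrom, arr in grouped.items():
        pos = points.get(chrom)
        if pos is None or len(pos) == 0:
            continue
        merged = merge_interval_array(arr)
        lo = np.searchsorted(pos, merged[:, 0], side="left")
        hi = np.searchsorted(pos, merged[:, 1], side="left")
        count += int((hi - lo).sum())
    return count


def positions_by_chrom(peaksets: Iterable[PeakSet]) -> dict[str, np.ndarray]:
    """Sorted peak-center positions per chromosome, pooled over peak sets."""
    acc: dict[str, list[int]] = defaultdict(list)
    for ps in peaksets:
        for p in ps.peaks:
            acc[p.interval.chrom].append(p.center)
    return {c: np.array(sorted(v), dtype=np.int64) for c, v in acc.items()}


# ---------------------------------------------------------------------------
# Readers and writers
# ---------------------------------------------------------------------------

class ParseError(ValueError):
    """A malformed line in a tabular genomic file, with line context."""


def read_peaks(
    path: str | Path,
    tf: str,
    fmt: str = "auto",
    lab: str = "",
) -> PeakSet:
    """Read a BED3/BED6 or ENCODE narrowPeak file into a :class:`PeakSet`.

    narrowPeak is the 10-column BED6+4 ENCODE format; its 7th column
    (signalValue) is stored as the peak score. Plain BED uses column 5
    (score) when present. Malformed lines raise :class:`ParseError` naming
    the offending line number.
    """
    path = Path(path)
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path.name}:{lineno}: expected >= 3 tab-separated "
                    f"columns, got {len(fields)}"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(
                    f"{path.name}:{lineno}: non-integer coordinates"
                ) from exc
            if start < 0 or end <= start:
                raise ParseError(
                    f"{path.name}:{lineno}: invalid interval "
                    f"[{start}, {end})"
                )
            is_narrowpeak = fmt == "narrowPeak" or (
                fmt == "auto" and len(fields) >= 10
            )
            score: float | None = None
            try:
                if is_narrowpeak and len(fields) >= 7:
                    score = float(fields[6])
                elif len(fields) >= 5 and fields[4] not in (".", ""):
                    score = float(fields[4])
            except ValueError:
                score = None
            peaks.append(
                Peak(GenomicInterval(chrom, start, end), tf=tf, lab=lab,
                     score=score)
            )
    return PeakSet(tf=tf, peaks=peaks)


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column (name, length) chromosome-sizes TSV."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"line {lineno}: expected name<TAB>length")
            sizes[fields[0]] = int(fields[1])
    return sizes


def write_mps_bed(mps: Sequence[MergedPeak], path: str | Path) -> None:
    """Write ranked MPs as BED with name ``MP<rank>`` and score n_points."""
    with open(path, "w") as fh:
        for mp in mps:
            name = f"MP{mp.rank}" if mp.rank is not None else "MP"
            fh.write(
                f"{mp.interval.chrom}\t{mp.interval.start}\t"
                f"{mp.interval.end}\t{name}\t{mp.n_points}\n"
            )


def write_mps_tsv(mps: Sequence[MergedPeak], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("rank\tchrom\tstart\tend\tn_points\tn_tfs\n")
        for mp in mps:
            fh.write(
                f"{mp.rank}\t{mp.interval.chrom}\t{mp.interval.start}\t"
                f"{mp.interval.end}\t{mp.n_points}\t{mp.n_tfs}\n"
            )


# ---------------------------------------------------------------------------
# Dataset and replicate filtering
# ---------------------------------------------------------------------------

def filter_dataset(
    ps: PeakSet, min_peaks: int = MIN_PEAKS_PER_DATASET
) -> FilterResult:
    """Discard datasets with fewer than ``min_peaks`` peaks.

    Datasets that sparse are almost always failed ChIP-seq
    experiments rather than genuinely narrow binding repertoires.
    """
    if ps.n_peaks < min_peaks:
        return FilterResult(
            accepted=False,
            reason=f"{ps.tf}: {ps.n_peaks} peaks < {min_peaks}",
        )
    return FilterResult(accepted=True)


def _overlap_count(a: PeakSet, b: PeakSet) -> int:
    """Number of peaks of ``a`` whose interval intersects >= 1 bp of ``b``."""
    b_arr = intervals_by_chrom(p.interval for p in b.peaks)
    b_merged = {c: merge_interval_array(arr) for c, arr in b_arr.items()}
    n = 0
    for p in a.peaks:
        arr = b_merged.get(p.interval.chrom)
        if arr is None or len(arr) == 0:
            continue
        # candidate: the last merged interval starting before p.end
        i = np.searchsorted(arr[:, 0], p.interval.end, side="left") - 1
        if i >= 0 and arr[i, 1] > p.interval.start:
            n += 1
    return n


def _overlapping_set(larger: PeakSet, other: PeakSet) -> PeakSet:
    """Peaks of the larger replicate that intersect the other replicate."""
    arr = intervals_by_chrom(p.interval for p in other.peaks)
    merged = {c: merge_interval_array(a) for c, a in arr.items()}
    kept = []
    for p in larger.peaks:
        a = merged.get(p.interval.chrom)
        if a is None or len(a) == 0:
            continue
        i = np.searchsorted(a[:, 0], p.interval.end, side="left") - 1
        if i >= 0 and a[i, 1] > p.interval.start:
            kept.append(p)
    return PeakSet(tf=larger.tf, peaks=kept)


def _reconcile_pair(a: PeakSet, b: PeakSet) -> ReconcileResult:
    big, small = (a, b) if a.n_peaks >= b.n_peaks else (b, a)
    # Rule 1: one replicate dwarfs the other and the lesser looks failed.
    if (
        big.n_peaks > REPLICATE_RATIO * small.n_peaks
        and small.n_peaks < REPLICATE_LOW_COUNT
    ):
        return ReconcileResult(
            peakset=big, rule="rule1", accepted=True,
            detail=f"kept {big.n_peaks}-peak replicate, "
                   f"dropped {small.n_peaks}-peak replicate",
        )
    # Rule 2: concordance high enough -> use the overlapping set.
    ov = _overlap_count(big, small)
    if ov > REPLICATE_OVERLAP_COUNT or (
        ov > REPLICATE_OVERLAP_FRACTION * min(a.n_peaks, b.n_peaks)
        or ov > REPLICATE_OVERLAP_FRACTION * max(a.n_peaks, b.n_peaks)
    ):
        return ReconcileResult(
            peakset=_overlapping_set(big, small), rule="rule2",
            accepted=True, detail=f"{ov} overlapping peaks",
        )
    return ReconcileResult(
        peakset=None, rule="rejected", accepted=False,
        detail=f"only {ov} overlapping peaks "
               f"({a.n_peaks} and {b.n_peaks} replicates)",
    )


def reconcile_replicates(reps: Sequence[PeakSet]) -> ReconcileResult:
    """Reduce replicate peak sets of one TF to a single set, or reject.

    Two replicates: rule 1 keeps the larger set when the other is more
    than 3x smaller and has fewer than 3000 peaks (a failed experiment);
    rule 2 keeps the overlapping set when more than 3000 peaks, or more
    than 40% of at least one replicate, overlap; otherwise the TF is
    rejected. More than two replicates: the pair with the highest overlap
    percentage (ties: highest overlap count) is chosen and rules 1-2
    applied (rule 3). Overlap is >= 1 bp intersection of original peak
    intervals; the overlapping set is materialized from the replicate
    with more peaks.
    """
    if not reps:
        raise ValueError("no replicates supplied")
    tfs = {ps.tf for ps in reps}
    if len(tfs) > 1:
        raise ValueError(f"mixed TFs in replicate list: {sorted(tfs)}")
    if len(reps) == 1:
        return ReconcileResult(peakset=reps[0], rule="single", accepted=True)
    if len(reps) == 2:
        return _reconcile_pair(reps[0], reps[1])
    # Rule 3: pick the most concordant pair.
    best: tuple[float, int, int, int] | None = None  # (pct, count, -i, -j)
    for i in range(len(reps)):
        for j in range(i + 1, len(reps)):
            big, small = (
                (reps[i], reps[j])
                if reps[i].n_peaks >= reps[j].n_peaks
                else (reps[j], reps[i])
            )
            ov = _overlap_count(big, small)
            pct = ov / small.n_peaks if small.n_peaks else 0.0
            key = (pct, ov, -i, -j)
            if best is None or key > best:
                best = key
                pair = (reps[i], reps[j])
    return _reconcile_pair(*pair)


# ---------------------------------------------------------------------------
# Peak-center windows and merging
# ---------------------------------------------------------------------------

def peak_center(p: Peak) -> int:
    """Peak center point: floor((start + end) / 2)."""
    return p.center


def center_window(
    p: Peak,
    width: int = CENTER_WINDOW,
    chrom_sizes: dict[str, int] | None = None,
) -> GenomicInterval:
    """The center ``width`` bp window of a peak.

    Emitted at full width even for peaks narrower than ``width`` (the
    center window stands in for the strongest-signal region regardless of
    the called width); clipped at position 0 and, when sizes are known, at
    the chromosome end.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    c = p.center
    start = max(0, c - width // 2)
    end = c + (width - width // 2)
    if chrom_sizes is not None:
        size = chrom_sizes.get(p.interval.chrom)
        if size is not None:
            end = min(end, size)
    return GenomicInterval(p.interval.chrom, start, end)


def merge_windows(
    windows: Sequence[tuple[GenomicInterval, str, int]],
) -> list[MergedPeak]:
    """Merge center windows into MPs (bedtools-merge semantics).

    ``windows`` is a sequence of (window, tf, center position) triples.
    Overlapping and bookended (touching) windows merge; each MP carries
    every contributing (tf, center) pair, so the total number of centers
    is conserved.
    """
    by_chrom: dict[str, list[tuple[int, int, str, int]]] = defaultdict(list)
    for iv, tf, center in windows:
        by_chrom[iv.chrom].append((iv.start, iv.end, tf, center))
    mps: list[MergedPeak] = []
    for chrom in sorted(by_chrom):
        rows = sorted(by_chrom[chrom], key=lambda r: (r[0], r[1]))
        cur_start, cur_end = rows[0][0], rows[0][1]
        cur_centers: list[tuple[str, int]] = [(rows[0][2], rows[0][3])]
        for s, e, tf, c in rows[1:]:
            if s <= cur_end:
                cur_end = max(cur_end, e)
                cur_centers.append((tf, c))
            else:
                mps.append(
                    MergedPeak(GenomicInterval(chrom, cur_start, cur_end),
                               centers=cur_centers)
                )
                cur_start, cur_end, cur_centers = s, e, [(tf, c)]
        mps.append(
            MergedPeak(GenomicInterval(chrom, cur_start, cur_end),
                       centers=cur_centers)
        )
    return mps


def build_mps(
    peaksets: Iterable[PeakSet],
    width: int = CENTER_WINDOW,
    chrom_sizes: dict[str, int] | None = None,
) -> list[MergedPeak]:
    """Center-window + merge convenience: peak sets -> unranked MPs."""
    windows = [
        (center_window(p, width, chrom_sizes), p.tf, p.center)
        for ps in peaksets
        for p in ps.peaks
    ]
    return merge_windows(windows)


def rank_mps(mps: Sequence[MergedPeak]) -> list[MergedPeak]:
    """Rank MPs by contributing TF-peak count, most enriched first.

    Ties are broken by genomic order (chrom, start) so the ranking is a
    deterministic permutation of the input.
    """
    ordered = sorted(
        mps,
        key=lambda mp: (-mp.n_points, mp.interval.chrom, mp.interval.start),
    )
    return [replace_rank(mp, i + 1) for i, mp in enumerate(ordered)]


def replace_rank(mp: MergedPeak, rank: int) -> MergedPeak:
    return MergedPeak(interval=mp.interval, centers=mp.centers, rank=rank)


def cumulative_curve(ranked: Sequence[MergedPeak], level: float) -> int:
    """Smallest k such that the top-k MPs hold >= ``level`` of all centers."""
    if not ranked:
        raise ValueError("no MPs supplied")
    if not 0 < level <= 1:
        raise ValueError("level must be in (0, 1]")
    counts = np.array([mp.n_points for mp in ranked], dtype=np.int64)
    target = level * counts.sum()
    return int(np.searchsorted(np.cumsum(counts), target, side="left") + 1)


# ---------------------------------------------------------------------------
# Coverage summaries and set overlap
# ---------------------------------------------------------------------------

def coverage_summary(
    site_set: Sequence[GenomicInterval],
    reference: Sequence[GenomicInterval],
    centers: dict[str, np.ndarray],
) -> CoverageSummary:
    """Fraction of reference bases and of TF binding events in a site set.

    ``centers`` maps chromosome -> sorted peak-center positions; the event
    fraction is the share of centers inside the reference that also fall
    in the site set.
    """
    bp_ref = total_bp(reference)
    if bp_ref == 0:
        raise ValueError("empty reference set")
    if not site_set:
        return CoverageSummary(0.0, 0.0)
    n_ref = points_in_intervals(centers, reference)
    n_site = points_in_intervals(centers, site_set)
    return CoverageSummary(
        bp_fraction=total_bp(site_set) / bp_ref,
        event_fraction=n_site / n_ref if n_ref else 0.0,
    )


def overlap_sets(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> int:
    """Count a-intervals intersecting (>= 1 bp) any b-interval."""
    merged_b = {
        c: merge_interval_array(arr)
        for c, arr in intervals_by_chrom(b).items()
    }
    n = 0
    for iv in a:
        arr = merged_b.get(iv.chrom)
        if arr is None or len(arr) == 0:
            continue
        i = np.searchsorted(arr[:, 0], iv.end, side="left") - 1
        if i >= 0 and arr[i, 1] > iv.start:
            n += 1
    return n
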