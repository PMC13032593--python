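"""Nucleosome occupancy metaprofiles and the depletion statistic F.

MNase-seq reads come from the ends of mononucleosome fragments, so each
read is shifted 50 bp toward the nucleosome dyad before pile-up. Average
coverage is then profiled around site midpoints, and nucleosome depletion
of a test site group is scored relative to the within-FBS group as

    F = (G3_high - G3_low) / (G1_high - G1_low)

where G_low is the signal at the valley of the central nucleosome-depleted
region and G_high the signal at its edges; F >= 0.5 is called strong
depletion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import GenomicInterval, MergedPeak, PeakSet
from .cooccurrence import extend_site
from .fbs import FBS

logger = logging.getLogger("fbscan")

MNASE_SHIFT = 50          # bp toward the nucleosome dyad
DEFAULT_FLANK = 1000      # metaprofile half-width
VALLEY_WINDOW = (-80, 80)         # NDR valley search window
EDGE_WINDOW = (100, 300)          # NDR edge search window (mirrored)
STRONG_DEPLETION_F = 0.5
LONELY_MAX_PARTNERS = 10
LONELY_WINDOW = 150       # bp; ~one nucleosome around a site center


@dataclass
class SignalTrack:
    """Dense per-base coverage over named chromosomes."""

    coverage: dict[str, np.ndarray]
    shift_applied: int = 0
    source: str = ""

    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(a) for c, a in self.coverage.items()}

    def total_mass(self) -> float:
        return float(sum(a.sum() for a in self.coverage.values()))


@dataclass
class MetaProfile:
    """Mean coverage per offset in [-flank, +flank] over a site group."""

    flank: int
    values: np.ndarray          # length 2*flank + 1
    n_sites: int
    n_dropped: int = 0
    per_site_matrix: np.ndarray | None = None

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.flank, self.flank + 1)


@dataclass
class DepletionResult:
    g1_high: float
    g1_low: float
    g3_high: float
    g3_low: float
    f: float
    strong: bool
    defined: bool = True


@dataclass(frozen=True)
class StrandedRead:
    chrom: str
    start: int
    end: int
    strand: str  # "+" or "-"


# ---------------------------------------------------------------------------
# Track construction and I/O
# ---------------------------------------------------------------------------

def build_shifted_track(
    reads: Iterable[StrandedRead],
    chrom_sizes: Mapping[str, int],
    shift: int = MNASE_SHIFT,
    source: str = "",
) -> SignalTrack:
    """Pile up stranded reads after shifting them toward the dyad.

    Plus-strand reads move +shift, minus-strand reads -shift. Total
    coverage mass equals the summed read lengths exactly for reads whose
    shifted footprint stays inside chromosome bounds; footprints crossing
    a boundary are clipped.
    """
    diffs = {
        c: np.zeros(size + 1, dtype=np.float64)
        for c, size in chrom_sizes.items()
    }
    for r in reads:
        if r.strand == "+":
            s, e = r.start + shift, r.end + shift
        elif r.strand == "-":
            s, e = r.start - shift, r.end - shift
        else:
            raise ValueError(
                f"unstranded read {r.chrom}:{r.start}-{r.end}; "
                "use shift=0 for pre-shifted or unstranded data"
            )
        d = diffs[r.chrom]
        size = len(d) - 1
        s, e = max(0, s), min(size, e)
        if e > s:
            d[s] += 1
            d[e] -= 1
    coverage = {c: np.cumsum(d[:-1]) for c, d in diffs.items()}
    return SignalTrack(coverage=coverage, shift_applied=shift, source=source)


def read_bedgraph(
    path: str | Path,
    chrom_sizes: Mapping[str, int],
    shift_applied: int = 0,
    source: str = "",
) -> SignalTrack:
    """Load a bedGraph file into a dense :class:`SignalTrack`."""
    coverage = {
        c: np.zeros(size, dtype=np.float64)
        for c, size in chrom_sizes.items()
    }
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, value = line.split("\t")[:4]
            if chrom not in coverage:
                continue
            arr = coverage[chrom]
            s, e = max(0, int(start)), min(len(arr), int(end))
            if e > s:
                arr[s:e] = float(value)
    return SignalTrack(coverage=coverage, shift_applied=shift_applied,
                       source=source)


def write_bedgraph(track: SignalTrack, path: str | Path,
                   decimals: int = 4) -> None:
    """Write a dense track as run-length-compressed bedGraph."""
    with open(path, "w") as fh:
        for chrom in sorted(track.coverage):
            arr = np.round(track.coverage[chrom], decimals)
            if len(arr) == 0:
                continue
            change = np.nonzero(np.diff(arr))[0] + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(arr)]))
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


# ---------------------------------------------------------------------------
# Metaprofiles
# ---------------------------------------------------------------------------

def meta_profile(
    track: SignalTrack,
    sites: Sequence[GenomicInterval],
    flank: int = DEFAULT_FLANK,
    keep_matrix: bool = False,
) -> MetaProfile:
    """Mean coverage around site midpoints, one value per bp offset.

    Sites whose +/-flank window exceeds chromosome bounds are dropped and
    counted; an all-dropped input is an error.
    """
    rows = []
    dropped = 0
    for iv in sites:
        arr = track.coverage.get(iv.chrom)
        if arr is None:
            dropped += 1
            continue
        mid = iv.midpoint
        lo, hi = mid - flank, mid + flank + 1
        if lo < 0 or hi > len(arr):
            dropped += 1
            continue
        rows.append(arr[lo:hi])
    if not rows:
        raise ValueError("no usable sites within track bounds")
    if dropped:
        logger.info("meta_profile: dropped %d/%d out-of-bounds sites",
                    dropped, len(sites))
    matrix = np.vstack(rows)
    return MetaProfile(
        flank=flank,
        values=matrix.mean(axis=0),
        n_sites=len(rows),
        n_dropped=dropped,
        per_site_matrix=matrix if keep_matrix else None,
    )


# ---------------------------------------------------------------------------
# Site grouping for one TF
# ---------------------------------------------------------------------------

def _extended_site_arrays(
    fbss: Sequence[FBS], target: int, exclude_promoter: bool
) -> dict[str, np.ndarray]:
    """Union (merged, sorted) of extended FBS intervals per chromosome."""
    from .core import merge_interval_array

    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for f in fbss:
        if exclude_promoter and f.promoter_flag:
            continue
        iv = extend_site(f.interval, target)
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    return {
        c: merge_interval_array(
            np.array(sorted(v), dtype=np.int64).reshape(-1, 2))
        for c, v in by_chrom.items()
    }


def _center_in_any(arr: np.ndarray | None, pos: int) -> bool:
    """Point membership in a merged, sorted interval array."""
    if arr is None or len(arr) == 0:
        return False
    i = int(np.searchsorted(arr[:, 0], pos, side="right")) - 1
    return i >= 0 and arr[i, 1] > pos


def group_sites(
    tf: PeakSet,
    fbs_p95: Sequence[FBS],
    fbs_p90: Sequence[FBS],
    mps: Sequence[MergedPeak],
    lonely_max_partners: int = LONELY_MAX_PARTNERS,
    lonely_window: int = LONELY_WINDOW,
    extension: int = 180,
) -> dict[str, list[GenomicInterval]]:
    """Split one TF's peaks into the three depletion-comparison groups.

    g1: peaks whose center lies in a strong (P95) FBS extended to 180 bp,
    excluding promoter-flagged FBSs. g2: peaks whose center lies in no
    extended P90 FBS. g3 ("lonely sites"): the subset of g2 with fewer
    than ``lonely_max_partners`` distinct other TFs having peak centers
    within +/-``lonely_window`` bp; partner centers are taken from the MPs'
    contributing (tf, center) pairs.
    """
    p95 = _extended_site_arrays(fbs_p95, extension, exclude_promoter=True)
    p90 = _extended_site_arrays(fbs_p90, extension, exclude_promoter=False)

    partners: dict[str, tuple[np.ndarray, list[str]]] = {}
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for mp in mps:
        for other_tf, pos in mp.centers:
            by_chrom.setdefault(mp.interval.chrom, []).append((pos, other_tf))
    for chrom, rows in by_chrom.items():
        rows.sort()
        partners[chrom] = (
            np.array([p for p, _ in rows], dtype=np.int64),
            [t for _, t in rows],
        )

    g1: list[GenomicInterval] = []
    g2: list[GenomicInterval] = []
    g3: list[GenomicInterval] = []
    for p in tf.peaks:
        c = p.center
        chrom = p.interval.chrom
        if _center_in_any(p95.get(chrom), c):
            g1.append(p.interval)
        if not _center_in_any(p90.get(chrom), c):
            g2.append(p.interval)
            pos_names = partners.get(chrom)
            n_partners = 0
            if pos_names is not None:
                pos, names = pos_names
                lo = int(np.searchsorted(pos, c - lonely_window, "left"))
                hi = int(np.searchsorted(pos, c + lonely_window, "right"))
                n_partners = len(
                    {names[i] for i in range(lo, hi)} - {tf.tf}
                )
            if n_partners < lonely_max_partners:
                g3.append(p.interval)
    return {"g1": g1, "g2": g2, "g3": g3}


# ---------------------------------------------------------------------------
# Depletion statistic
# ---------------------------------------------------------------------------

def _high_low(profile: MetaProfile,
              valley: tuple[int, int] = VALLEY_WINDOW,
              edge: tuple[int, int] = EDGE_WINDOW) -> tuple[float, float]:
    off = profile.offsets
    v = profile.values
    in_valley = (off >= valley[0]) & (off <= valley[1])
    left = (off >= -edge[1]) & (off <= -edge[0])
    right = (off >= edge[0]) & (off <= edge[1])
    g_low = float(v[in_valley].min())
    g_high = float((v[left].max() + v[right].max()) / 2)
    return g_high, g_low


def depletion_fraction(
    g1_profile: MetaProfile,
    g3_profile: MetaProfile,
    valley: tuple[int, int] = VALLEY_WINDOW,
    edge: tuple[int, int] = EDGE_WINDOW,
    strong_threshold: float = STRONG_DEPLETION_F,
) -> DepletionResult:
    """Relative depletion F of a test group vs the within-FBS group.

    G_low is the minimum over the valley window and G_high the mean of
    the two maxima over the mirrored edge windows. F is undefined (NaN,
    ``defined=False``) when the reference span G1_high - G1_low is not
    positive.
    """
    if g1_profile.flank != g3_profile.flank:
        raise ValueError("profiles must share the same flank")
    g1h, g1l = _high_low(g1_profile, valley, edge)
    g3h, g3l = _high_low(g3_profile, valley, edge)
    span1 = g1h - g1l
    if span1 <= 0:
        logger.warning("reference group shows no depletion span; F undefined")
        return DepletionResult(g1h, g1l, g3h, g3l, float("nan"), False,
                               defined=False)
    f = (g3h - g3l) / span1
    return DepletionResult(g1h, g1l, g3h, g3l, f,
                           strong=f >= strong_threshold)


def write_profile_tsv(profile: MetaProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("offset\tmean\n")
        for o, v in zip(profile.offsets, profile.values):
            fh.write(f"{o}\t{v:.6g}\n")
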