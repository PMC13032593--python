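"""Variant enrichment, chromatin-state assignment and CRE classification.

Variant enrichment fold is the density of variants in a sample of sites
divided by the density expected by chance:

    fold = (N_var_S / length_S) / (N_var_T / length_T)

with a one-sided binomial test (enrichment claims only). Chromatin-state
assignment follows a majority-overlap rule with a strict exception for
the quiescent state; promoters are -2 kb/+1 kb windows around TSSs of
expressed genes, enhancers are mark-overlapping non-promoter MPs with
target promoters assigned within 50 kb.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    GenomicInterval,
    intervals_by_chrom,
    merge_interval_array,
    points_in_intervals,
    total_bp,
)
from .nucleosome import MetaProfile, SignalTrack, meta_profile

logger = logging.getLogger("fbscan")

PROMOTER_UPSTREAM = 2000
PROMOTER_DOWNSTREAM = 1000
RPKM_MIN = 1.0
TARGET_PROMOTER_RANGE = 50_000
LOOP_MAX_ANCHOR_WIDTH = 2000
CONSERVATION_WINDOW = 800


@dataclass(frozen=True)
class VariantSet:
    """Positions (0-based) of one functional-variant class."""

    positions: tuple[tuple[str, int], ...]
    label: str = ""

    def by_chrom(self) -> dict[str, np.ndarray]:
        acc: dict[str, list[int]] = {}
        for chrom, pos in self.positions:
            acc.setdefault(chrom, []).append(pos)
        return {c: np.array(sorted(v), dtype=np.int64)
                for c, v in acc.items()}

    @property
    def n(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class EnrichmentResult:
    fold: float
    p: float
    n_in: int
    n_total: int
    bp_sample: int
    bp_background: int
    defined: bool = True


@dataclass(frozen=True)
class TSSRecord:
    gene: str
    chrom: str
    tss: int
    strand: str
    rpkm: float

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")


# ---------------------------------------------------------------------------
# Variant enrichment
# ---------------------------------------------------------------------------

def _count_in(vars_by_chrom: Mapping[str, np.ndarray],
              intervals: Sequence[GenomicInterval]) -> int:
    return points_in_intervals(dict(vars_by_chrom), intervals)


def enrichment_fold(
    variants: VariantSet,
    sample: Sequence[GenomicInterval],
    background: Sequence[GenomicInterval] | None = None,
    genome_bp: int | None = None,
) -> EnrichmentResult:
    """Variant density in the sample relative to the chance expectation.

    With explicit ``background`` intervals the sample must be a subset of
    their union; with ``genome_bp`` the background is the whole genome
    and every variant counts. p is a one-sided (greater) binomial test of
    n_in successes out of n_background trials at p0 = bp_sample /
    bp_background.
    """
    bp_sample = total_bp(sample)
    if bp_sample == 0:
        raise ValueError("zero-length sample")
    pos = variants.by_chrom()
    n_in = _count_in(pos, sample)
    if background is not None:
        bp_bg = total_bp(background)
        n_bg = _count_in(pos, background)
    elif genome_bp is not None:
        bp_bg = genome_bp
        n_bg = variants.n
    else:
        raise ValueError("supply background intervals or genome_bp")
    if n_bg == 0:
        logger.warning("no variants in the background; fold undefined")
        return EnrichmentResult(float("nan"), float("nan"), n_in, 0,
                                bp_sample, bp_bg, defined=False)
    fold = (n_in / bp_sample) / (n_bg / bp_bg)
    p0 = bp_sample / bp_bg
    p = stats.binomtest(n_in, n_bg, p0, alternative="greater").pvalue
    return EnrichmentResult(fold, p, n_in, n_bg, bp_sample, bp_bg)


def relative_enrichment(
    variants: VariantSet,
    fbs: Sequence[GenomicInterval],
    mp: Sequence[GenomicInterval],
) -> EnrichmentResult:
    """Enrichment of variants in FBSs relative to their parent MPs."""
    return enrichment_fold(variants, sample=fbs, background=mp)


# ---------------------------------------------------------------------------
# Chromatin-state assignment
# ---------------------------------------------------------------------------

@dataclass
class StateSegmentation:
    """Non-overlapping labeled intervals (e.g. an 18-state segmentation)."""

    intervals: list[tuple[GenomicInterval, str]]
    quiescent_state: str = "18_Quies"

    def __post_init__(self) -> None:
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[str]]]
        by_chrom: dict[str, list[tuple[int, int, str]]] = {}
        for iv, state in self.intervals:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end,
                                                      state))
        self._by_chrom = {}
        for chrom, rows in by_chrom.items():
            rows.sort()
            for (s1, e1, _), (s2, _, _) in zip(rows, rows[1:]):
                if s2 < e1:
                    raise ValueError(
                        f"overlapping segmentation intervals on {chrom}")
            self._by_chrom[chrom] = (
                np.array([r[0] for r in rows], dtype=np.int64),
                np.array([r[1] for r in rows], dtype=np.int64),
                [r[2] for r in rows],
            )


def assign_state(site: GenomicInterval, seg: StateSegmentation) -> str:
    """Majority-overlap chromatin state of a site.

    The quiescent state is assigned only when 100% of the site's bases
    are quiescent; otherwise the best non-quiescent state wins. Sites
    with no annotated overlap return "unannotated".
    """
    data = seg._by_chrom.get(site.chrom)
    if data is None:
        return "unannotated"
    starts, ends, states = data
    lo = int(np.searchsorted(ends, site.start, side="right"))
    overlap: dict[str, int] = {}
    total = 0
    for i in range(lo, len(starts)):
        if starts[i] >= site.end:
            break
        bp = min(int(ends[i]), site.end) - max(int(starts[i]), site.start)
        if bp > 0:
            overlap[states[i]] = overlap.get(states[i], 0) + bp
            total += bp
    if total == 0:
        return "unannotated"
    quies = seg.quiescent_state
    if quies in overlap and overlap[quies] == site.width:
        return quies
    non_quies = {s: bp for s, bp in overlap.items() if s != quies}
    if not non_quies:
        # partially quiescent, partially unannotated: quiescent loses
        return "unannotated"
    # deterministic tie-break: larger overlap, then state name
    return max(sorted(non_quies), key=lambda s: non_quies[s])


# ---------------------------------------------------------------------------
# Promoter / enhancer classification
# ---------------------------------------------------------------------------

def promoter_windows(
    tss: Sequence[TSSRecord],
    rpkm_min: float = RPKM_MIN,
    upstream: int = PROMOTER_UPSTREAM,
    downstream: int = PROMOTER_DOWNSTREAM,
) -> list[tuple[GenomicInterval, str]]:
    """Active-promoter windows around TSSs of expressed genes.

    -``upstream``/+``downstream`` bp in the direction of transcription:
    [tss-2000, tss+1000) on +, [tss-1000, tss+2000) on -.
    """
    out = []
    for rec in tss:
        if rec.rpkm <= rpkm_min:
            continue
        if rec.strand == "+":
            s, e = rec.tss - upstream, rec.tss + downstream
        else:
            s, e = rec.tss - downstream, rec.tss + upstream
        out.append((GenomicInterval(rec.chrom, max(0, s), e), rec.gene))
    return out


def classify_promoter(
    site: GenomicInterval,
    tss: Sequence[TSSRecord],
    rpkm_min: float = RPKM_MIN,
) -> bool:
    """True iff the site intersects any active-promoter window."""
    for iv, _ in promoter_windows(tss, rpkm_min):
        if site.overlaps(iv):
            return True
    return False


def flag_promoters(
    sites: Sequence[GenomicInterval],
    tss: Sequence[TSSRecord],
    rpkm_min: float = RPKM_MIN,
) -> np.ndarray:
    """Vectorized promoter flags for many sites."""
    windows = [iv for iv, _ in promoter_windows(tss, rpkm_min)]
    merged = {
        c: merge_interval_array(arr)
        for c, arr in intervals_by_chrom(windows).items()
    }
    flags = np.zeros(len(sites), dtype=bool)
    for i, site in enumerate(sites):
        arr = merged.get(site.chrom)
        if arr is None or len(arr) == 0:
            continue
        j = int(np.searchsorted(arr[:, 0], site.end, side="left")) - 1
        flags[i] = j >= 0 and arr[j, 1] > site.start
    return flags


def classify_enhancer(
    sites: Sequence[GenomicInterval],
    marks: Sequence[GenomicInterval],
    tss: Sequence[TSSRecord],
    rpkm_min: float = RPKM_MIN,
) -> np.ndarray:
    """Enhancer flags: >= 1 bp overlap with H3K27ac/H3K4me1 marks and no
    overlap with any active promoter window."""
    merged_marks = {
        c: merge_interval_array(arr)
        for c, arr in intervals_by_chrom(marks).items()
    }
    promoter = flag_promoters(sites, tss, rpkm_min)
    flags = np.zeros(len(sites), dtype=bool)
    for i, site in enumerate(sites):
        if promoter[i]:
            continue
        arr = merged_marks.get(site.chrom)
        if arr is None or len(arr) == 0:
            continue
        j = int(np.searchsorted(arr[:, 0], site.end, side="left")) - 1
        flags[i] = j >= 0 and arr[j, 1] > site.start
    return flags


def assign_target_promoter(
    enhancer: GenomicInterval,
    tss: Sequence[TSSRecord],
    rpkm_min: float = RPKM_MIN,
    max_distance: int = TARGET_PROMOTER_RANGE,
) -> list[str]:
    """Genes whose active promoter lies within 50 kb of the enhancer.

    Distance is enhancer midpoint to promoter-window midpoint, same
    chromosome. When no promoter is within range the single nearest one
    is returned; an empty list means no active promoter on the
    chromosome at all.
    """
    mid = enhancer.midpoint
    candidates = [
        (abs(iv.midpoint - mid), gene)
        for iv, gene in promoter_windows(tss, rpkm_min)
        if iv.chrom == enhancer.chrom
    ]
    if not candidates:
        return []
    within = [gene for d, gene in candidates if d <= max_distance]
    if within:
        return within
    return [min(candidates)[1]]


# ---------------------------------------------------------------------------
# Loop-contact enrichment
# ---------------------------------------------------------------------------

def contact_enrichment(
    fbss: Sequence[GenomicInterval],
    anchors: Sequence[GenomicInterval],
    chrom_sizes: Mapping[str, int],
    n_random: int = 100,
    seed: int = 0,
    max_anchor_width: int = LOOP_MAX_ANCHOR_WIDTH,
) -> EnrichmentResult:
    """FBS overlap with loop anchors vs length-matched random site sets.

    Anchors wider than ``max_anchor_width`` are removed first. fold is
    the observed fraction of FBSs overlapping any anchor divided by the
    mean fraction over ``n_random`` seeded random site sets (uniform
    placement, lengths matched to the FBSs); p is the empirical
    (1 + #random >= observed) / (n_random + 1).
    """
    anchors = [a for a in anchors if a.width <= max_anchor_width]
    if not anchors:
        raise ValueError("no loop anchors after the width filter")
    if not fbss:
        raise ValueError("no FBSs supplied")
    merged = {
        c: merge_interval_array(arr)
        for c, arr in intervals_by_chrom(anchors).items()
    }

    def frac_overlapping(sites: Sequence[GenomicInterval]) -> float:
        n = 0
        for iv in sites:
            arr = merged.get(iv.chrom)
            if arr is None or len(arr) == 0:
                continue
            j = int(np.searchsorted(arr[:, 0], iv.end, side="left")) - 1
            if j >= 0 and arr[j, 1] > iv.start:
                n += 1
        return n / len(sites)

    observed = frac_overlapping(fbss)
    rng = np.random.default_rng(seed)
    chroms = sorted(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=np.float64)
    probs = sizes / sizes.sum()
    widths = [iv.width for iv in fbss]
    rand_fracs = np.empty(n_random)
    for r in range(n_random):
        picks = rng.choice(len(chroms), size=len(widths), p=probs)
        sites = []
        for w, ci in zip(widths, picks):
            chrom = chroms[ci]
            hi = int(chrom_sizes[chrom]) - w
            start = int(rng.integers(0, max(1, hi)))
            sites.append(GenomicInterval(chrom, start, start + w))
        rand_fracs[r] = frac_overlapping(sites)
    mean_rand = float(rand_fracs.mean())
    if mean_rand == 0:
        fold = float("inf") if observed > 0 else float("nan")
    else:
        fold = observed / mean_rand
    p = float((1 + (rand_fracs >= observed).sum()) / (n_random + 1))
    anchor_bp = sum(int((a[:, 1] - a[:, 0]).sum()) for a in merged.values())
    return EnrichmentResult(
        fold, p, n_in=int(round(observed * len(fbss))),
        n_total=len(fbss), bp_sample=anchor_bp,
        bp_background=int(sizes.sum()),
        defined=np.isfinite(fold),
    )


# ---------------------------------------------------------------------------
# Conservation profile
# ---------------------------------------------------------------------------

def conservation_profile(
    track: SignalTrack,
    sites: Sequence[GenomicInterval],
    window: int = CONSERVATION_WINDOW,
) -> MetaProfile:
    """Mean per-base conservation score in a window around site centers."""
    return meta_profile(track, sites, flank=window // 2)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_variants(
    path: str | Path, label: str = "", zero_based: bool = False
) -> VariantSet:
    """Read a (chrom, pos[, ...]) variant TSV; positions 1-based unless
    ``zero_based``. Lines starting with '#' or a non-numeric second column
    are treated as headers."""
    positions: list[tuple[str, int]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                continue
            try:
                pos = int(fields[1])
            except ValueError:
                continue  # header
            positions.append((fields[0], pos if zero_based else pos - 1))
    return VariantSet(positions=tuple(positions), label=label)


def read_segmentation(
    path: str | Path, quiescent_state: str = "18_Quies"
) -> StateSegmentation:
    """Read a chromHMM-style BED (state label in the name column)."""
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            intervals.append(
                (GenomicInterval(fields[0], int(fields[1]), int(fields[2])),
                 fields[3] if len(fields) > 3 else "unknown")
            )
    return StateSegmentation(intervals=intervals,
                             quiescent_state=quiescent_state)


def read_tss_table(path: str | Path) -> list[TSSRecord]:
    """Read a TSS/expression TSV (gene, chrom, tss, strand, rpkm)."""
    df = pd.read_csv(path, sep="\t")
    return [
        TSSRecord(gene=str(r.gene), chrom=str(r.chrom), tss=int(r.tss),
                  strand=str(r.strand), rpkm=float(r.rpkm))
        for r in df.itertuples()
    ]


def read_bedpe_anchors(path: str | Path) -> list[GenomicInterval]:
    """Both anchors of each BEDPE loop contact, as plain intervals."""
    anchors = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            anchors.append(GenomicInterval(f[0], int(f[1]), int(f[2])))
            anchors.append(GenomicInterval(f[3], int(f[4]), int(f[5])))
    return anchors


def read_bed_intervals(path: str | Path) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2])))
    return out
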