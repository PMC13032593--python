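"""Seeded synthetic data emulating a deep multi-TF ChIP-seq compendium.

The generator plants focal binding sites on a small genome and emits every
input the pipeline consumes: per-TF peak sets whose centers cluster tightly
at the focal sites over a uniform background, optional replicate pairs with
controllable concordance, an MNase-style coverage track with a
nucleosome-depleted valley and phased flanking peaks at each planted site,
variant sets with a planted density ratio inside the focal windows, and
small TSS / histone-mark / chromatin-state / loop / conservation fixtures.
Ground truth (site coordinates, planted depletion fraction, planted variant
fold) is returned for parameter-recovery tests.

All randomness flows through one ``numpy`` generator: the same seed yields
byte-identical fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import GenomicInterval, Peak, PeakSet
from .enrichment import TSSRecord, StateSegmentation, VariantSet
from .nucleosome import SignalTrack


@dataclass
class SimulationConfig:
    """Knobs of the synthetic compendium; defaults are the study conditions
    scaled to a 2 Mb two-chromosome genome."""

    seed: int = 0
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 1_000_000, "chr2": 1_000_000})
    n_focal_sites: int = 200
    n_lonely_sites: int = 100
    n_tfs: int = 50
    peaks_per_tf: int = 400
    focal_fraction: float = 0.5       # share of a TF's peaks at focal sites
    center_jitter_sd: float = 20.0    # bp; truncated at +/- jitter_max
    jitter_max: int = 90
    peak_width_mean: float = 400.0    # called-peak widths (bp)
    peak_width_sd: float = 80.0
    peak_width_min: int = 150
    peak_width_max: int = 800
    make_replicates: bool = False
    replicate_concordance: float = 0.7
    # MNase track
    mnase_baseline: float = 10.0
    valley_depth: float = 0.8         # fractional depth of the NDR valley
    phase_amplitude: float = 0.5      # fractional height of flanking peaks
    phase_period: int = 190           # bp between phased nucleosome peaks
    phase_decay: float = 0.7          # geometric decay of successive peaks
    n_phased: int = 3
    mnase_noise_sd: float = 0.3
    lonely_scale: float = 0.6         # planted depletion fraction F
    # Variants
    variant_background_density: float = 0.005   # per bp, outside focal
    variant_rho: float = 10.0         # planted fold vs genome-mean density
    variant_window: int = 90          # half-width of the focal window
    # Annotation fixtures
    n_genes: int = 30
    n_families: int = 12
    n_cofactors: int = 10
    margin: int = 3000                # bp kept clear at chromosome ends

    def validate(self) -> None:
        fr = [self.focal_fraction, self.replicate_concordance,
              self.valley_depth, self.lonely_scale]
        if any(not 0 <= x <= 1 for x in fr):
            raise ValueError("fractions must lie in [0, 1]")
        if any(length < 100_000 for length in self.chrom_lengths.values()):
            raise ValueError("chromosomes must be >= 100 kb")
        g = sum(self.chrom_lengths.values())
        s = 2 * self.variant_window * self.n_focal_sites
        if self.variant_rho * s >= g:
            raise ValueError("planted fold too large for the focal span")


@dataclass
class GroundTruth:
    focal_sites: list[tuple[str, int]]       # (chrom, center)
    lonely_sites: list[tuple[str, int]]
    tf_focal_sites: dict[str, list[int]]     # tf -> planted site indices
    planted_f: float
    planted_rho: float


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    truth: GroundTruth
    peaksets: list[PeakSet]
    replicates: dict[str, tuple[PeakSet, PeakSet]]
    mnase: SignalTrack
    variants: dict[str, VariantSet]          # "planted" and "null"
    tss: list[TSSRecord]
    marks: list[GenomicInterval]
    segmentation: StateSegmentation
    loop_anchors: list[GenomicInterval]
    conservation: SignalTrack

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return dict(self.config.chrom_lengths)

    def write(self, outdir: str | Path) -> None:
        write_dataset(self, outdir)


# ---------------------------------------------------------------------------
# Placement helpers
# ---------------------------------------------------------------------------

def _place_sites(cfg: SimulationConfig, rng: np.random.Generator,
                 ) -> tuple[list[tuple[str, int]], list[tuple[str, int]]]:
    """Plant focal + lonely sites pairwise >= 2 kb apart, away from ends."""
    slots: list[tuple[str, int]] = []
    for chrom in sorted(cfg.chrom_lengths):
        length = cfg.chrom_lengths[chrom]
        pos = cfg.margin
        while pos + 2000 + cfg.margin <= length:
            slots.append((chrom, pos))
            pos += 4000
    need = cfg.n_focal_sites + cfg.n_lonely_sites
    if need > len(slots):
        raise ValueError(
            f"genome too small: {need} sites requested, {len(slots)} slots")
    chosen = rng.permutation(len(slots))[:need]
    sites = [
        (slots[i][0], slots[i][1] + int(rng.integers(0, 2000)))
        for i in chosen
    ]
    return sites[: cfg.n_focal_sites], sites[cfg.n_focal_sites:]


def _jitter(cfg: SimulationConfig, rng: np.random.Generator) -> int:
    while True:
        j = rng.normal(0.0, cfg.center_jitter_sd)
        if abs(j) <= cfg.jitter_max:
            return int(round(j))


def _peak_width(cfg: SimulationConfig, rng: np.random.Generator) -> int:
    w = int(round(rng.normal(cfg.peak_width_mean, cfg.peak_width_sd)))
    w = min(max(w, cfg.peak_width_min), cfg.peak_width_max)
    return w + (w % 2)  # even width: interval midpoint == planted center


def _peak_at(cfg: SimulationConfig, chrom: str, center: int, width: int,
             tf: str) -> Peak:
    length = cfg.chrom_lengths[chrom]
    start = max(0, center - width // 2)
    end = min(length, center + width // 2)
    return Peak(GenomicInterval(chrom, start, end), tf=tf, lab="sim")


# ---------------------------------------------------------------------------
# Peak sets
# ---------------------------------------------------------------------------

def _simulate_peaks(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    focal: list[tuple[str, int]],
    lonely: list[tuple[str, int]],
) -> tuple[list[PeakSet], dict[str, list[int]]]:
    tf_names = [f"TF{i + 1:03d}" for i in range(cfg.n_tfs)]
    chroms = sorted(cfg.chrom_lengths)
    sizes = np.array([cfg.chrom_lengths[c] for c in chroms],
                     dtype=np.float64)
    probs = sizes / sizes.sum()

    n_focal_peaks = int(round(cfg.peaks_per_tf * cfg.focal_fraction))
    per_tf_centers: dict[str, list[tuple[str, int]]] = {}
    tf_focal_sites: dict[str, list[int]] = {}
    for tf in tf_names:
        centers: list[tuple[str, int]] = []
        site_idx = rng.integers(0, len(focal), size=n_focal_peaks)
        tf_focal_sites[tf] = sorted(set(int(i) for i in site_idx))
        for i in site_idx:
            chrom, pos = focal[int(i)]
            centers.append((chrom, pos + _jitter(cfg, rng)))
        for _ in range(cfg.peaks_per_tf - n_focal_peaks):
            ci = int(rng.choice(len(chroms), p=probs))
            chrom = chroms[ci]
            c = int(rng.integers(cfg.margin,
                                 cfg.chrom_lengths[chrom] - cfg.margin))
            centers.append((chrom, c))
        per_tf_centers[tf] = centers

    # Lonely sites: a few TFs each, carved out of their background quota so
    # per-TF totals stay at peaks_per_tf.
    n_lonely_tfs = 3
    n_replaced = {tf: 0 for tf in tf_names}
    n_background = cfg.peaks_per_tf - n_focal_peaks
    for chrom, pos in lonely:
        picked = rng.choice(cfg.n_tfs, size=n_lonely_tfs, replace=False)
        for t in picked:
            tf = tf_names[int(t)]
            if n_replaced[tf] >= n_background:
                continue  # quota exhausted; skip rather than grow the set
            per_tf_centers[tf][-1 - n_replaced[tf]] = (
                chrom, pos + _jitter(cfg, rng))
            n_replaced[tf] += 1

    peaksets = []
    for tf in tf_names:
        peaks = [
            _peak_at(cfg, chrom, c, _peak_width(cfg, rng), tf)
            for chrom, c in per_tf_centers[tf]
        ]
        peaksets.append(PeakSet(tf=tf, peaks=peaks))
    return peaksets, tf_focal_sites


def _simulate_replicates(
    cfg: SimulationConfig, rng: np.random.Generator, ps: PeakSet
) -> tuple[PeakSet, PeakSet]:
    """A replicate pair sharing ``replicate_concordance`` of its peaks."""
    n = ps.n_peaks
    n_shared = int(round(cfg.replicate_concordance * n))
    shared_idx = set(rng.choice(n, size=n_shared, replace=False).tolist())
    chroms = sorted(cfg.chrom_lengths)
    sizes = np.array([cfg.chrom_lengths[c] for c in chroms],
                     dtype=np.float64)
    probs = sizes / sizes.sum()

    def novel_peak() -> Peak:
        ci = int(rng.choice(len(chroms), p=probs))
        chrom = chroms[ci]
        c = int(rng.integers(cfg.margin,
                             cfg.chrom_lengths[chrom] - cfg.margin))
        return _peak_at(cfg, chrom, c, _peak_width(cfg, rng), ps.tf)

    rep2 = []
    for i, p in enumerate(ps.peaks):
        if i in shared_idx:
            wobble = int(rng.integers(-20, 21))
            rep2.append(
                _peak_at(cfg, p.interval.chrom, p.center + wobble,
                         p.interval.width, ps.tf))
        else:
            rep2.append(novel_peak())
    return ps, PeakSet(tf=ps.tf, peaks=rep2)


# ---------------------------------------------------------------------------
# MNase-style coverage
# ---------------------------------------------------------------------------

def _site_pattern(cfg: SimulationConfig, half: int) -> np.ndarray:
    """Unit-strength coverage deviation around a planted site.

    A Gaussian-shaped nucleosome-depleted valley (depth ``valley_depth`` x
    baseline at the center) flanked by cos^2 phased nucleosome peaks at
    multiples of ``phase_period`` with geometric decay.
    """
    t = np.arange(-half, half + 1, dtype=np.float64)
    pattern = -cfg.valley_depth * np.exp(-((t / 70.0) ** 2))
    peak_half = 75
    for k in range(1, cfg.n_phased + 1):
        amp = cfg.phase_amplitude * cfg.phase_decay ** (k - 1)
        for sign in (-1, 1):
            center = sign * k * cfg.phase_period
            mask = np.abs(t - center) < peak_half
            pattern[mask] += amp * np.cos(
                np.pi * (t[mask] - center) / (2 * peak_half)) ** 2
    return pattern * cfg.mnase_baseline


def _simulate_mnase(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    focal: list[tuple[str, int]],
    lonely: list[tuple[str, int]],
) -> SignalTrack:
    half = cfg.n_phased * cfg.phase_period + 100
    pattern = _site_pattern(cfg, half)
    coverage = {}
    for chrom in sorted(cfg.chrom_lengths):
        length = cfg.chrom_lengths[chrom]
        arr = np.full(length, cfg.mnase_baseline, dtype=np.float64)
        if cfg.mnase_noise_sd > 0:
            arr += rng.normal(0.0, cfg.mnase_noise_sd, size=length)
        coverage[chrom] = arr
    for sites, scale in ((focal, 1.0), (lonely, cfg.lonely_scale)):
        for chrom, pos in sites:
            arr = coverage[chrom]
            lo, hi = pos - half, pos + half + 1
            if lo < 0 or hi > len(arr):
                continue
            arr[lo:hi] += scale * pattern
    for arr in coverage.values():
        np.maximum(arr, 0.0, out=arr)
    return SignalTrack(coverage=coverage, shift_applied=0, source="sim")


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------

def _focal_windows(cfg: SimulationConfig, focal: list[tuple[str, int]],
                   ) -> list[GenomicInterval]:
    return [
        GenomicInterval(chrom, pos - cfg.variant_window,
                        pos + cfg.variant_window)
        for chrom, pos in focal
    ]


def _sample_in_intervals(rng: np.random.Generator,
                         intervals: Sequence[GenomicInterval],
                         n: int) -> list[tuple[str, int]]:
    widths = np.array([iv.width for iv in intervals], dtype=np.float64)
    picks = rng.choice(len(intervals), size=n, p=widths / widths.sum())
    out = []
    for i in picks:
        iv = intervals[int(i)]
        out.append((iv.chrom, int(rng.integers(iv.start, iv.end))))
    return out


def simulate_variants(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    focal: list[tuple[str, int]],
    rho: float,
    label: str = "",
) -> VariantSet:
    """Plant variants at ``rho``-fold the genome-mean density in focal
    windows.

    Outside the +/-``variant_window`` focal windows variants arrive as a
    Poisson process at the background density; inside, the density is
    solved so that the in-window density is ``rho`` times the expected
    genome-wide mean, making the standard enrichment-fold estimator
    unbiased for ``rho``.
    """
    windows = _focal_windows(cfg, focal)
    s = sum(iv.width for iv in windows)
    g = sum(cfg.chrom_lengths.values())
    lam = cfg.variant_background_density
    if rho * s >= g:
        raise ValueError("rho too large for this focal span")
    mu = rho * lam * (g - s) / (g - rho * s)

    # complement of the focal windows
    complement: list[GenomicInterval] = []
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in windows:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom in sorted(cfg.chrom_lengths):
        length = cfg.chrom_lengths[chrom]
        prev = 0
        for iv in sorted(by_chrom.get(chrom, []),
                         key=lambda v: v.start):
            if iv.start > prev:
                complement.append(GenomicInterval(chrom, prev, iv.start))
            prev = max(prev, iv.end)
        if prev < length:
            complement.append(GenomicInterval(chrom, prev, length))

    n_out = int(rng.poisson(lam * (g - s)))
    n_in = int(rng.poisson(mu * s))
    positions = _sample_in_intervals(rng, complement, n_out)
    if n_in:
        positions += _sample_in_intervals(rng, windows, n_in)
    positions.sort()
    return VariantSet(positions=tuple(positions), label=label)


# ---------------------------------------------------------------------------
# Annotation fixtures
# ---------------------------------------------------------------------------

def _simulate_tss(cfg: SimulationConfig, rng: np.random.Generator,
                  focal: list[tuple[str, int]]) -> list[TSSRecord]:
    """Genes with alternating strand; a third promoter-adjacent to focal
    sites, the rest elsewhere; ~1/4 below the expression cutoff."""
    records = []
    chroms = sorted(cfg.chrom_lengths)
    for i in range(cfg.n_genes):
        strand = "+" if i % 2 == 0 else "-"
        rpkm = 0.5 if i % 4 == 3 else float(rng.uniform(2.0, 50.0))
        if i < cfg.n_genes // 3 and i < len(focal):
            chrom, pos = focal[i * 3 % len(focal)]
            tss = pos + int(rng.integers(-800, 800))
        else:
            chrom = chroms[i % len(chroms)]
            tss = int(rng.integers(cfg.margin,
                                   cfg.chrom_lengths[chrom] - cfg.margin))
        records.append(TSSRecord(gene=f"GENE{i + 1:03d}", chrom=chrom,
                                 tss=tss, strand=strand, rpkm=rpkm))
    return records


def _simulate_marks(cfg: SimulationConfig, rng: np.random.Generator,
                    focal: list[tuple[str, int]]) -> list[GenomicInterval]:
    marks = []
    for i, (chrom, pos) in enumerate(focal):
        if i % 5 == 4:
            continue  # leave some focal sites unmarked
        marks.append(GenomicInterval(chrom, pos - 500, pos + 500))
    chroms = sorted(cfg.chrom_lengths)
    for _ in range(20):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        s = int(rng.integers(cfg.margin,
                             cfg.chrom_lengths[chrom] - cfg.margin))
        marks.append(GenomicInterval(chrom, s, s + 1000))
    return marks


def _simulate_segmentation(
    cfg: SimulationConfig,
    focal: list[tuple[str, int]],
    tss: list[TSSRecord],
) -> StateSegmentation:
    """Tile the genome: promoter state at TSSs, enhancer state at focal
    sites, quiescent elsewhere."""
    features: dict[str, list[tuple[int, int, str]]] = {
        c: [] for c in cfg.chrom_lengths
    }
    for rec in tss:
        features[rec.chrom].append(
            (max(0, rec.tss - 1000), rec.tss + 1000, "1_TssA"))
    for chrom, pos in focal:
        features[chrom].append((pos - 1000, pos + 1000, "9_EnhA1"))
    intervals: list[tuple[GenomicInterval, str]] = []
    for chrom in sorted(cfg.chrom_lengths):
        length = cfg.chrom_lengths[chrom]
        rows = sorted(features[chrom])
        # resolve overlaps greedily: earlier start wins the overlap
        clipped: list[tuple[int, int, str]] = []
        prev_end = 0
        for s, e, state in rows:
            s = max(s, prev_end)
            if e > s:
                clipped.append((s, e, state))
                prev_end = e
        pos = 0
        for s, e, state in clipped:
            if s > pos:
                intervals.append(
                    (GenomicInterval(chrom, pos, s), "18_Quies"))
            intervals.append((GenomicInterval(chrom, s, e), state))
            pos = e
        if pos < length:
            intervals.append(
                (GenomicInterval(chrom, pos, length), "18_Quies"))
    return StateSegmentation(intervals=intervals)


def _simulate_loops(cfg: SimulationConfig, rng: np.random.Generator,
                    focal: list[tuple[str, int]]) -> list[GenomicInterval]:
    """Loop anchors (width 800 bp) at a subset of focal sites plus a few
    random background anchors."""
    anchors = []
    order = rng.permutation(len(focal))
    for i in order[: len(focal) // 2]:
        chrom, pos = focal[int(i)]
        anchors.append(GenomicInterval(chrom, pos - 400, pos + 400))
    chroms = sorted(cfg.chrom_lengths)
    for _ in range(10):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        s = int(rng.integers(cfg.margin,
                             cfg.chrom_lengths[chrom] - cfg.margin))
        anchors.append(GenomicInterval(chrom, s, s + 800))
    return anchors


def _simulate_conservation(cfg: SimulationConfig,
                           focal: list[tuple[str, int]]) -> SignalTrack:
    coverage = {
        c: np.full(cfg.chrom_lengths[c], 0.1, dtype=np.float64)
        for c in cfg.chrom_lengths
    }
    t = np.arange(-200, 201, dtype=np.float64)
    bump = 0.5 * np.exp(-((t / 80.0) ** 2))
    for chrom, pos in focal:
        arr = coverage[chrom]
        lo, hi = pos - 200, pos + 201
        if 0 <= lo and hi <= len(arr):
            arr[lo:hi] += bump
    return SignalTrack(coverage=coverage, shift_applied=0,
                       source="sim-conservation")


def make_family_map(cfg: SimulationConfig) -> dict[str, str]:
    """TF -> family label; the last ``n_cofactors`` TFs map to themselves."""
    fam = {}
    n_family_tfs = cfg.n_tfs - cfg.n_cofactors
    for i in range(cfg.n_tfs):
        tf = f"TF{i + 1:03d}"
        if i >= n_family_tfs:
            fam[tf] = tf
        else:
            fam[tf] = f"FAM{i % cfg.n_families + 1:02d}"
    return fam


# ---------------------------------------------------------------------------
# Top level
# ---------------------------------------------------------------------------

def simulate(config: SimulationConfig | None = None,
             outdir: str | Path | None = None) -> SyntheticDataset:
    """Generate the full synthetic compendium (optionally writing files)."""
    cfg = config or SimulationConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    focal, lonely = _place_sites(cfg, rng)
    peaksets, tf_focal_sites = _simulate_peaks(cfg, rng, focal, lonely)
    replicates = {}
    if cfg.make_replicates:
        for ps in peaksets:
            replicates[ps.tf] = _simulate_replicates(cfg, rng, ps)
    mnase = _simulate_mnase(cfg, rng, focal, lonely)
    variants = {
        "planted": simulate_variants(cfg, rng, focal, cfg.variant_rho,
                                     label="planted"),
        "null": simulate_variants(cfg, rng, focal, 1.0, label="null"),
    }
    tss = _simulate_tss(cfg, rng, focal)
    marks = _simulate_marks(cfg, rng, focal)
    segmentation = _simulate_segmentation(cfg, focal, tss)
    loops = _simulate_loops(cfg, rng, focal)
    conservation = _simulate_conservation(cfg, focal)
    truth = GroundTruth(
        focal_sites=focal,
        lonely_sites=lonely,
        tf_focal_sites=tf_focal_sites,
        planted_f=cfg.lonely_scale,
        planted_rho=cfg.variant_rho,
    )
    ds = SyntheticDataset(
        config=cfg, truth=truth, peaksets=peaksets, replicates=replicates,
        mnase=mnase, variants=variants, tss=tss, marks=marks,
        segmentation=segmentation, loop_anchors=loops,
        conservation=conservation,
    )
    if outdir is not None:
        write_dataset(ds, outdir)
    return ds


def tiny_config(seed: int = 0) -> SimulationConfig:
    """A sub-second fixture for unit tests."""
    return SimulationConfig(
        seed=seed,
        chrom_lengths={"chr1": 200_000, "chr2": 150_000},
        n_focal_sites=20,
        n_lonely_sites=10,
        n_tfs=12,
        peaks_per_tf=60,
        n_genes=8,
        n_families=4,
        n_cofactors=3,
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> None:
    from .nucleosome import write_bedgraph

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "chrom.sizes", "w") as fh:
        for chrom in sorted(ds.chrom_sizes):
            fh.write(f"{chrom}\t{ds.chrom_sizes[chrom]}\n")
    peak_dir = outdir / "peaks"
    peak_dir.mkdir(exist_ok=True)
    manifest = []
    for ps in ds.peaksets:
        path = peak_dir / f"{ps.tf}.narrowPeak"
        _write_narrowpeak(ps, path)
        manifest.append((ps.tf, f"peaks/{path.name}", "sim"))
    with open(outdir / "manifest.tsv", "w") as fh:
        fh.write("tf\tpath\tlab\n")
        for row in manifest:
            fh.write("\t".join(row) + "\n")
    for tf, (r1, r2) in ds.replicates.items():
        _write_narrowpeak(r1, peak_dir / f"{tf}.rep1.narrowPeak")
        _write_narrowpeak(r2, peak_dir / f"{tf}.rep2.narrowPeak")
    write_bedgraph(ds.mnase, outdir / "mnase.bedgraph")
    write_bedgraph(ds.conservation, outdir / "conservation.bedgraph")
    for label, vs in ds.variants.items():
        with open(outdir / f"variants_{label}.tsv", "w") as fh:
            fh.write("chrom\tpos\n")
            for chrom, pos in vs.positions:
                fh.write(f"{chrom}\t{pos + 1}\n")  # 1-based on disk
    with open(outdir / "tss.tsv", "w") as fh:
        fh.write("gene\tchrom\ttss\tstrand\trpkm\n")
        for r in ds.tss:
            fh.write(f"{r.gene}\t{r.chrom}\t{r.tss}\t{r.strand}"
                     f"\t{r.rpkm:.3f}\n")
    with open(outdir / "marks.bed", "w") as fh:
        for iv in ds.marks:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
    with open(outdir / "chromhmm.bed", "w") as fh:
        for iv, state in ds.segmentation.intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{state}\n")
    with open(outdir / "loops.bedpe", "w") as fh:
        anchors = ds.loop_anchors
        for a, b in zip(anchors[::2], anchors[1::2]):
            fh.write(f"{a.chrom}\t{a.start}\t{a.end}"
                     f"\t{b.chrom}\t{b.start}\t{b.end}\n")
    fam = make_family_map(ds.config)
    with open(outdir / "families.tsv", "w") as fh:
        fh.write("tf\tfamily\tis_cofactor\n")
        for tf, family in fam.items():
            is_cof = "1" if family == tf else "0"
            fh.write(f"{tf}\t{family}\t{is_cof}\n")
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("kind\tchrom\tcenter\n")
        for chrom, pos in ds.truth.focal_sites:
            fh.write(f"focal\t{chrom}\t{pos}\n")
        for chrom, pos in ds.truth.lonely_sites:
            fh.write(f"lonely\t{chrom}\t{pos}\n")
    with open(outdir / "truth_params.tsv", "w") as fh:
        fh.write(f"planted_f\t{ds.truth.planted_f}\n")
        fh.write(f"planted_rho\t{ds.truth.planted_rho}\n")


def _write_narrowpeak(ps: PeakSet, path: Path) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(ps.peaks, start=1):
            iv = p.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{ps.tf}_{i}\t0\t."
                f"\t1.0\t-1\t-1\t{iv.width // 2}\n"
            )


# ---------------------------------------------------------------------------
# Recovery metrics
# ---------------------------------------------------------------------------

def match_calls(
    calls: Sequence[GenomicInterval],
    truth_sites: Sequence[tuple[str, int]],
    tol: int = 100,
) -> tuple[float, float]:
    """(recall, precision): a call hits a planted site when its midpoint is
    within ``tol`` bp of the site center; each site counts once."""
    hit_sites = set()
    n_true_pos = 0
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for j, (chrom, pos) in enumerate(truth_sites):
        by_chrom.setdefault(chrom, []).append((pos, j))
    for chrom in by_chrom:
        by_chrom[chrom].sort()
    for iv in calls:
        mid = iv.midpoint
        hits = [
            j for pos, j in by_chrom.get(iv.chrom, [])
            if abs(pos - mid) <= tol
        ]
        if hits:
            n_true_pos += 1
            hit_sites.update(hits)
    recall = len(hit_sites) / len(truth_sites) if truth_sites else 0.0
    precision = n_true_pos / len(calls) if calls else 0.0
    return recall, precision


def recovery_report(ds: SyntheticDataset, tol: int = 100,
                    pct: float = 90) -> dict[str, float]:
    """Run the caller + depletion + enrichment on a dataset and compare
    each recovered quantity with its planted value."""
    from .core import build_mps, rank_mps
    from .enrichment import enrichment_fold
    from .fbs import call_fbs
    from .nucleosome import depletion_fraction, meta_profile

    mps = rank_mps(build_mps(ds.peaksets, chrom_sizes=ds.chrom_sizes))
    result = call_fbs(mps, pcts=(pct,))
    calls = [f.interval for f in result.fbs_by_pct[pct]]
    recall, precision = match_calls(calls, ds.truth.focal_sites, tol)

    site_iv = lambda sites: [
        GenomicInterval(c, p - 1, p + 1) for c, p in sites
    ]
    g1 = meta_profile(ds.mnase, site_iv(ds.truth.focal_sites), flank=1000)
    g3 = meta_profile(ds.mnase, site_iv(ds.truth.lonely_sites), flank=1000)
    dep = depletion_fraction(g1, g3)

    windows = _focal_windows(ds.config, ds.truth.focal_sites)
    genome_bp = sum(ds.chrom_sizes.values())
    fold = enrichment_fold(ds.variants["planted"], windows,
                           genome_bp=genome_bp)
    return {
        "recall": recall,
        "precision": precision,
        "n_calls": float(len(calls)),
        "c_t": float(result.density_table.c_t or 0),
        "recovered_f": dep.f,
        "planted_f": ds.truth.planted_f,
        "recovered_fold": fold.fold,
        "planted_rho": ds.truth.planted_rho,
    }
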