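"""TF-to-FBS assignment, pairwise co-occurrence and family co-occupancy.

A TF is bound to an FBS when the center 10 bp of one of its ChIP-seq
peaks overlaps the FBS (extended to 180 bp if shorter — roughly one
nucleosome-depleted region) by at least 1 bp. The co-occurrence rate of
TFs A and B is N_both / max(N_A, N_B) over the FBSs each binds; family
co-occupancy is the fraction of FBSs at which both families are present.
Promoter and distal FBSs are analyzed separately by filtering the FBS
list before assignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import GenomicInterval, PeakSet
from .fbs import FBS

logger = logging.getLogger("fbscan")

FBS_EXTENSION = 180       # bp; ~one nucleosome-depleted region
CENTER_WINDOW_10 = 10     # bp; peak-center window used for assignment


@dataclass
class BindingMatrix:
    """Boolean TF x FBS bound/unbound matrix."""

    tfs: list[str]
    fbss: list[FBS]
    matrix: np.ndarray  # bool, shape (n_tfs, n_fbs)
    extension: int = FBS_EXTENSION

    def counts_per_tf(self) -> np.ndarray:
        return self.matrix.sum(axis=1)

    def counts_per_fbs(self) -> np.ndarray:
        return self.matrix.sum(axis=0)

    def tf_index(self, tf: str) -> int:
        return self.tfs.index(tf)


@dataclass
class CooccurrenceMatrix:
    """Symmetric co-occurrence (or co-occupancy) rates over TFs/families."""

    labels: list[str]
    rates: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rates, index=self.labels,
                            columns=self.labels)


# ---------------------------------------------------------------------------
# Site extension and binding assignment
# ---------------------------------------------------------------------------

def extend_site(iv: GenomicInterval, target: int = FBS_EXTENSION,
                ) -> GenomicInterval:
    """Extend an interval symmetrically about its midpoint to ``target`` bp.

    Intervals already at least ``target`` wide are returned unchanged; an
    odd remainder goes to the right. The left edge is clipped at 0 (the
    lost bases are not compensated).
    """
    if target <= 0:
        raise ValueError("target width must be positive")
    width = iv.width
    if width >= target:
        return iv
    extra = target - width
    left = extra // 2
    right = extra - left
    return GenomicInterval(iv.chrom, max(0, iv.start - left), iv.end + right)


def assign_bindings(
    peaksets: Sequence[PeakSet],
    fbss: Sequence[FBS],
    extension: int = FBS_EXTENSION,
    center_window: int = CENTER_WINDOW_10,
) -> BindingMatrix:
    """Build the TF x FBS binding matrix.

    TF bound to FBS iff [center - w/2, center + w/2) of any of its peaks
    intersects the extended FBS by >= 1 bp (half-open: boundary contact is
    not overlap).
    """
    half = center_window // 2
    ext = [extend_site(f.interval, extension) for f in fbss]
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom in {iv.chrom for iv in ext}:
        idx = np.array([j for j, iv in enumerate(ext) if iv.chrom == chrom])
        starts = np.array([ext[j].start for j in idx], dtype=np.int64)
        ends = np.array([ext[j].end for j in idx], dtype=np.int64)
        order = np.argsort(starts, kind="stable")
        starts, ends, idx = starts[order], ends[order], idx[order]
        max_w = int((ends - starts).max()) if len(starts) else 0
        by_chrom[chrom] = (starts, ends, idx, max_w)

    matrix = np.zeros((len(peaksets), len(fbss)), dtype=bool)
    for i, ps in enumerate(peaksets):
        for p in ps.peaks:
            chrom = p.interval.chrom
            if chrom not in by_chrom:
                continue
            starts, ends, idx, max_w = by_chrom[chrom]
            c = p.center
            lo, hi = c - half, c - half + center_window
            # candidates: FBS start < hi; among them need end > lo
            k = int(np.searchsorted(starts, hi, side="left"))
            if k == 0:
                continue
            # scan back while a start could still reach lo (bounded by
            # the widest extended site on this chromosome)
            j = k - 1
            while j >= 0 and starts[j] + max_w > lo:
                if ends[j] > lo:
                    matrix[i, idx[j]] = True
                j -= 1
    return BindingMatrix(
        tfs=[ps.tf for ps in peaksets], fbss=list(fbss), matrix=matrix,
        extension=extension,
    )


# ---------------------------------------------------------------------------
# Co-occurrence
# ---------------------------------------------------------------------------

def cooccurrence_rate(bm: BindingMatrix, a: str, b: str) -> float:
    """N_both / max(N_a, N_b) for two TFs."""
    ra = bm.matrix[bm.tf_index(a)]
    rb = bm.matrix[bm.tf_index(b)]
    n_a, n_b = int(ra.sum()), int(rb.sum())
    denom = max(n_a, n_b)
    if denom == 0:
        raise ValueError(f"neither {a} nor {b} is bound to any FBS")
    return int((ra & rb).sum()) / denom


def cooccurrence_matrix(bm: BindingMatrix) -> CooccurrenceMatrix:
    """Symmetric TF x TF co-occurrence rate matrix.

    TFs bound to no FBS get rate 0 against everything (including the
    diagonal), with a log note; bound TFs have diagonal 1.
    """
    m = bm.matrix.astype(np.int64)
    both = m @ m.T
    counts = m.sum(axis=1)
    denom = np.maximum.outer(counts, counts)
    unbound = counts == 0
    if unbound.any():
        logger.info("%d TFs bound to no FBS in scope", int(unbound.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        rates = np.where(denom > 0, both / np.maximum(denom, 1), 0.0)
    return CooccurrenceMatrix(labels=list(bm.tfs), rates=rates)


def family_cooccupancy(
    bm: BindingMatrix, fam: Mapping[str, str]
) -> CooccurrenceMatrix:
    """Fraction of FBSs at which both families are present.

    Cofactors map to themselves in ``fam``. Every TF in the matrix must be
    mapped.
    """
    missing = [tf for tf in bm.tfs if tf not in fam]
    if missing:
        raise KeyError(f"unmapped TFs: {missing[:5]}")
    families = sorted({fam[tf] for tf in bm.tfs})
    fam_rows = np.zeros((len(families), bm.matrix.shape[1]), dtype=bool)
    f_index = {f: i for i, f in enumerate(families)}
    for i, tf in enumerate(bm.tfs):
        fam_rows[f_index[fam[tf]]] |= bm.matrix[i]
    n_fbs = bm.matrix.shape[1]
    if n_fbs == 0:
        raise ValueError("no FBSs in scope")
    both = fam_rows.astype(np.int64) @ fam_rows.astype(np.int64).T
    return CooccurrenceMatrix(labels=families, rates=both / n_fbs)


def occupancy_summary(
    bm: BindingMatrix, fam: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Per-FBS counts of bound TFs (and families when a map is given)."""
    out = pd.DataFrame({
        "chrom": [f.interval.chrom for f in bm.fbss],
        "start": [f.interval.start for f in bm.fbss],
        "end": [f.interval.end for f in bm.fbss],
        "n_tfs": bm.counts_per_fbs(),
    })
    if fam is not None:
        families = sorted({fam[tf] for tf in bm.tfs})
        fam_rows = np.zeros((len(families), bm.matrix.shape[1]), dtype=bool)
        f_index = {f: i for i, f in enumerate(families)}
        for i, tf in enumerate(bm.tfs):
            fam_rows[f_index[fam[tf]]] |= bm.matrix[i]
        out["n_families"] = fam_rows.sum(axis=0)
    return out


def conserved_enrichment(
    bm: BindingMatrix, conserved_flags: Sequence[bool]
) -> pd.DataFrame:
    """Per-TF enrichment in conserved vs cell-specific FBSs.

    fold = (b_cons / B_cons) / (b_spec / B_spec); p from a one-sided
    binomial test of b_cons successes out of b_cons + b_spec trials with
    null probability B_cons / (B_cons + B_spec). TFs binding no FBS of
    either class get fold NaN; b_spec = 0 with b_cons > 0 gives fold inf.
    A Benjamini-Hochberg column is appended.
    """
    flags = np.asarray(conserved_flags, dtype=bool)
    if flags.shape[0] != bm.matrix.shape[1]:
        raise ValueError("flag vector length must match FBS count")
    b_cons_n = int(flags.sum())
    b_spec_n = int((~flags).sum())
    if b_cons_n == 0 or b_spec_n == 0:
        raise ValueError("both conserved and cell-specific classes "
                         "must be non-empty")
    p0 = b_cons_n / (b_cons_n + b_spec_n)
    rows = []
    for i, tf in enumerate(bm.tfs):
        b_cons = int(bm.matrix[i, flags].sum())
        b_spec = int(bm.matrix[i, ~flags].sum())
        n = b_cons + b_spec
        if n == 0:
            fold, p = float("nan"), float("nan")
        else:
            spec_rate = b_spec / b_spec_n
            cons_rate = b_cons / b_cons_n
            fold = cons_rate / spec_rate if spec_rate > 0 else float("inf")
            p = stats.binomtest(b_cons, n, p0,
                                alternative="greater").pvalue
        rows.append((tf, b_cons, b_spec, fold, p))
    df = pd.DataFrame(
        rows, columns=["tf", "n_conserved", "n_specific", "fold", "p"]
    )
    ok = df["p"].notna()
    df["p_bh"] = np.nan
    if ok.any():
        df.loc[ok, "p_bh"] = _benjamini_hochberg(df.loc[ok, "p"].to_numpy())
    return df


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_family_map(path: str | Path) -> dict[str, str]:
    """TSV (tf, family, is_cofactor): cofactors map to themselves."""
    fam: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            tf, family, is_cof = fields[:3]
            fam[tf] = tf if is_cof.lower() in ("1", "true", "yes") else family
    return fam


def write_binding_matrix(bm: BindingMatrix, path: str | Path) -> None:
    """Sparse triplet TSV (tf, fbs_index, bound=1)."""
    rows, cols = np.nonzero(bm.matrix)
    with open(path, "w") as fh:
        fh.write("tf\tfbs_index\tbound\n")
        for r, c in zip(rows, cols):
            fh.write(f"{bm.tfs[r]}\t{c}\t1\n")


def write_cooccurrence(cm: CooccurrenceMatrix, path: str | Path) -> None:
    cm.to_frame().to_csv(path, sep="\t", float_format="%.4f")
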