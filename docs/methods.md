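# Methods

## Problem and data model

The pipeline operates on *peak centers*. Every TF ChIP-seq peak is reduced
to the floor of its interval midpoint; all downstream density statistics
count these points, never read-level signal. Coordinates are 0-based
half-open throughout; BED-family files pass through unchanged, and
1-based inputs (variant TSVs) are converted at the reader boundary.

### Dataset and replicate filters

Peak sets with fewer than `min_peaks = 2000` peaks are discarded as
likely failed experiments. Replicate pairs are reconciled by three rules:

1. if one replicate has more than 3× the peaks of the other *and* the
   lesser has fewer than 3000 peaks, the larger set is kept;
2. otherwise, if the number of overlapping peaks exceeds 3000 or 40% of
   at least one replicate, the overlapping set is kept;
3. with more than two replicates, the pair with the highest overlap
   percentage (ties: highest overlap count) is chosen and rules 1–2
   applied.

"Overlap" is ≥ 1 bp intersection of the *original* peak intervals (not
center windows). The overlapping set is materialized as the peaks of the
replicate with more peaks that intersect the other replicate: this is a
deterministic, order-stable reading of a step the procedure leaves open
(which replicate's coordinates survive). With equal-sized replicates the
first supplied set's coordinates are kept. The 40% condition is read as
"at least one replicate"; the overlap percentage for rule-3 pair
selection is the overlap count relative to the smaller replicate.

### Center windows and merging

Each peak contributes its center `width = 300` bp window. The window is
emitted at full width even for narrower peaks (the center window stands
in for the strongest-signal region regardless of called width) and is
clipped at position 0 and, when a sizes table is given, at the chromosome
end. Windows merge with bedtools-merge semantics — overlapping *and*
bookended (touching) windows coalesce — into merged peaks (MPs). Merging
conserves centers exactly: every contributing (tf, center) pair is
carried on its MP. MPs are ranked by contributing center count,
descending, with genomic order (chrom, start) breaking ties so the
ranking is a deterministic permutation.

## The FBS caller

**Step 1 — bins and C_T.** Each scanned MP is divided into consecutive
non-overlapping `bin = 10` bp bins anchored at the MP start (last partial
bin kept). The pooled histogram of bin counts *includes zero-count bins*:
the threshold level is defined over all scanned bins, and excluding zeros
would inflate the threshold. C_T is the smallest *observed* count c such
that the fraction of bins with count < c is at least `level = 0.90`.
Searching observed values (not all integers) is what makes "90% of bins
have smaller counts" well defined on skewed histograms; when no observed
value qualifies (a degenerate all-equal histogram) the maximum observed
count is returned with a warning. Runs of consecutive bins with count
≥ C_T combine into candidate sites; candidates narrower than
`min_width = 40` bp are dropped. Candidate intervals are bin-grid aligned
and clipped to the MP; the total count is recounted over the final
interval rather than summed from bins (identical on the grid, robust to
clipped last bins).

**Step 2 — count distributions.** For each unit length
L ∈ {80, 100, 120, 140, 160, 180, 200} bp, a window of length L slides
along every scanned MP at `step = 20` bp, fully inside the MP, and its
center count is sampled into D_L. MPs shorter than L contribute one
whole-MP window by default (`short_mp_policy="skip"` drops them; the
original procedure does not state which was done).

**Step 3 — percentile selection.** Candidates are grouped by width
(< 100 → D_80; [100, 120) → D_100; …; [180, 200) → D_180; ≥ 200 → D_200)
and kept at tier P when `total_count ≥` the nearest-rank P-quantile of
their group's distribution. Nearest-rank (no interpolation) quantiles
keep thresholds realizable counts; the comparison is inclusive (≥), so a
quantile of 58 keeps counts "above 57". Selection at a higher percentile
is always a subset of a lower one, which the sensitivity curve
(n_selected vs P for P ∈ {85, 90, 95, 98}) makes visible. The number of
top-ranked MPs scanned is a parameter (`top_mps`), not a constant, since
it is corpus-size dependent.

## Nucleosome profiles and the depletion statistic

MNase-seq reads are single-end sequences from mononucleosome ends, so
each read is shifted `shift = 50` bp toward the dyad (+ strand: +50; −
strand: −50) before pile-up. Coverage mass equals summed read lengths
exactly except for reads whose shifted footprint crosses a chromosome
boundary, which are clipped. Metaprofiles average coverage at 1 bp
resolution over site midpoints across `[−flank, +flank]`
(`flank = 1000`); out-of-bounds sites are dropped and counted.

Per TF, binding sites split into: g1 — centers inside strong (P95) FBSs
extended to 180 bp, excluding promoter-flagged FBSs; g2 — centers in no
extended P90 FBS; g3 ⊆ g2 — "lonely" sites. "Fewer than 10 binding
partners" is made operational as: fewer than `lonely_max = 10` distinct
other TFs with peak centers within `lonely_window = ±150` bp (about one
nucleosome); both values are parameters because the original definition
does not fix the window.

Depletion is scored as `F = (G3_high − G3_low) / (G1_high − G1_low)`,
with G_low the minimum over offsets [−80, +80] and G_high the mean of
the two maxima over [−300, −100] and [+100, +300]. These extraction
windows match the visual valley and edge of averaged MNase plots and are
configurable. F ≥ 0.5 is classified strong; a non-positive reference
span makes F undefined (NaN, flagged) rather than raising. F is
invariant to scaling both profiles by a common positive constant.

## Co-occurrence

FBSs shorter than 180 bp are extended symmetrically about their midpoint
(odd remainder to the right) — 180 bp being roughly one
nucleosome-depleted region. A TF is bound to an FBS when the center
10 bp window `[center − 5, center + 5)` of any of its peaks overlaps the
extended FBS by ≥ 1 bp; half-open boundary contact is not overlap. The
pairwise rate is `N_both / max(N_A, N_B)`; promoter and distal FBSs are
analyzed separately by filtering the FBS list before assignment. Family
co-occupancy is `|FBSs with ≥1 TF of each family| / |FBSs in scope|`;
cofactors enter as their own single-member "family". Enrichment of a TF
in conserved vs cell-specific FBSs is the ratio of its per-class binding
rates, with a one-sided binomial test of `b_cons` out of
`b_cons + b_spec` at null probability `B_cons / (B_cons + B_spec)`; this
parametrization is declared here because the original does not state
one. Raw p-values are reported with a Benjamini–Hochberg column
appended. Heatmap ordering of co-occurrence matrices is presentation
only and deliberately not part of the tested surface.

## Variant enrichment and annotation

`fold = (n_in / bp_sample) / (n_bg / bp_background)`; the background is
either the whole genome (sizes-table total; no ungapped-genome
correction) or an explicit superset of intervals (e.g. MPs for the
FBS-vs-MP relative fold). p is a one-sided (greater) binomial test with
`n = n_bg`, `k = n_in`, `p0 = bp_sample / bp_background` — all claims
tested are enrichment claims.

Chromatin-state assignment is majority-overlap with one exception: the
quiescent state is assigned only when 100% of the site's bases are
quiescent; a partially-quiescent site falls to its best non-quiescent
state, or "unannotated" when there is none. The rule is invariant to
splitting segmentation intervals. Promoters are −2 kb/+1 kb around TSSs
of expressed genes (RPKM > 1), strand-oriented; enhancers are
mark-overlapping sites that touch no active promoter window; target
promoters are all active promoters within 50 kb
(enhancer-midpoint-to-window-midpoint), falling back to the single
nearest. Loop-contact enrichment filters anchors to width ≤ 2 kb and
compares the observed FBS-overlap fraction to the mean over `n_random`
seeded, length-matched, uniformly placed site sets (chromosome chosen
proportional to length); matching is by length only — GC matching
belongs to motif analyses that are out of scope here. Conservation
metaprofiles are plain per-base means over an 800 bp window around site
centers.

## The synthetic compendium

The generator's defaults define the conditions under which recovery is
demonstrated: a 2 Mb two-chromosome genome, 200 planted focal sites and
100 "lonely" sites (all pairwise ≥ 2 kb apart, so planted sites are
unambiguous), 50 TFs with 400 peaks each, half of each TF's peaks at
uniformly chosen focal sites with Normal(0, 20 bp) center jitter
truncated at ±90 bp (keeping planted sites below ~200 bp, where real FBS
widths concentrate), the rest uniform background. Called-peak widths are
Normal(400, 80) clipped to [150, 800] bp and rounded to even, echoing
the few-hundred-bp widths of real corpora. Each lonely site receives one
peak from each of three TFs, carved out of those TFs' background quota so
per-TF totals are exact.

The MNase-like track is a constant baseline (10) plus Gaussian noise
(sd 0.3) plus, at each planted site, a scaled site pattern: a
Gaussian-shaped valley of fractional depth 0.8 and cos²-shaped phased
flanking peaks at ±190, ±380, ±570 bp with amplitude 0.5 and geometric
decay 0.7. Focal sites carry the pattern at scale 1, lonely sites at
scale 0.6 — because F is a ratio of (G_high − G_low) spans and the whole
deviation scales linearly, the planted F equals the scale ratio (0.6)
exactly, up to noise.

Variants arrive as a Poisson process: density λ = 0.005/bp outside the
±90 bp focal windows, and inside them a density μ solved from
μ = ρλ(G − S)/(G − ρS) so that the planted fold ρ is defined *relative
to the genome-mean density* — exactly what the enrichment-fold estimator
measures, making it unbiased for ρ. (Defining ρ against the outside
density instead would make the genome-denominator fold systematically
smaller than ρ whenever the focal span is non-negligible.) Two sets are
emitted: ρ = 10 ("planted") and ρ = 1 ("null").

Small TSS/marks/chromHMM/loop/conservation fixtures are laid out around
the planted sites so the annotation operations have non-trivial inputs;
replicate pairs (concordance 0.7) are generated on request. Everything
derives from a single seeded generator: one seed, byte-identical files.

What the generator does *not* emulate: non-uniform mappability and
blacklist artifacts, GC-dependent peak density, correlated TF binding
(each TF picks focal sites independently), fragment-length effects in
MNase coverage, and linkage structure among variants. Passing recovery
tests therefore demonstrates the correctness of the algorithms under the
stated generative model, not corpus-scale performance on real ENCODE
data — corpus-scale figures (e.g. C_T values near 4, tens of thousands
of FBSs) require the real compendium and are reported by the pipeline
when it is supplied.

## Problem sizes and numerical choices

Tests run on two fixture scales: `tiny` (12 TFs, 20 focal sites, ~350 kb,
sub-second) for unit tests and the default scale above (~10 s end to end)
for recovery checks; null-calibration checks use 2,000 seeded replicates
with ≥ 10⁴ variants each so the discrete binomial p-values are close
enough to uniform for a KS check at the 1% level. Other choices:
nearest-rank quantiles everywhere a count threshold is derived; floor
midpoints for even-width intervals; right-side placement of odd
extension remainders; genomic-order tie-breaks wherever a ranking could
otherwise depend on input order; empirical p for loop enrichment as
`(1 + #random ≥ observed) / (n_random + 1)`.

## Known limitations

- The replicate "overlapping set" definition (which replicate's
  coordinates survive) is one defensible reading of an underspecified
  step; rule-2 outcomes are order-symmetric except for exactly
  equal-sized replicates.
- `build_shifted_track` clips shifted footprints at chromosome bounds,
  so mass conservation is exact only for interior reads.
- Whether MNase tracks should be normalized between cell types before
  cross-cell F comparisons is not addressed; profiles are compared as
  given.
- The quiescent-state label is configurable but must match the
  segmentation's naming.
- No paired-end fragment-midpoint mode, no nucleosome calling, no motif
  scanning, no liftover, no GC-matched sampling.
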