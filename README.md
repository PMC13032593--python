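# fbscan

Focused TF binding sites from deep ChIP-seq peak collections.

A single ChIP-seq experiment locates a transcription factor's binding only
to within a few hundred base pairs — the fragment size, not the footprint.
When hundreds of TF ChIP-seq peak sets from the same cell type are stacked,
however, the *centers* of peaks from many different factors pile up on
remarkably narrow stretches of DNA. `fbscan` implements a pipeline that
exploits this: it merges per-TF peak-center windows into merged peaks
(MPs), scans the most TF-enriched MPs for bins dense in peak centers, and
calls **focused binding sites (FBSs)** — mostly sub-200-bp, roughly
single-nucleosome-sized elements that concentrate the bulk of all TF
binding events. Around these sites the pipeline profiles nucleosome
occupancy from MNase-seq coverage, quantifies pairwise TF co-occurrence
and TF-family co-occupancy, and measures the enrichment of functional
variants (eQTL/raQTL/caQTL/GWAS) with a binomial null.

It is written for regulatory-genomics analysts who have per-TF peak calls
(ENCODE narrowPeak/BED), coverage tracks (bedGraph), and standard
annotation files, and who want the whole chain — filtering, calling,
profiling, statistics — as tested, scriptable Python.

## The method in brief

1. **Preprocessing.** Datasets with < 2000 peaks are discarded; replicate
   pairs are reconciled by three rules (keep the dominant replicate when
   the other looks failed; keep the overlapping set when > 3000 peaks or
   > 40% of a replicate overlap; otherwise reject). Each surviving peak
   is reduced to its center 300 bp window; windows are merged
   (bedtools-merge semantics) into MPs, ranked by the number of
   contributing peak centers.
2. **FBS calling.** The top MPs are scanned in consecutive 10-bp bins;
   the threshold count C_T is the bin count at the ~90% level of the
   pooled bin-density table. Runs of bins with count ≥ C_T become
   candidate sites (width ≥ 40 bp). The count distribution D_L of sliding
   windows (L = 80…200 bp, step 20 bp) over the MPs supplies
   width-matched right-tail thresholds: a candidate of width group L is
   an FBS at percentile P when its total center count reaches the
   nearest-rank P-quantile of D_L (FBS_P90, FBS_P95, …).
3. **Nucleosome depletion.** MNase reads are shifted 50 bp to the
   nucleosome dyad; mean coverage is profiled around site midpoints.
   Depletion of a test group vs the within-FBS group is
   `F = (G3_high − G3_low) / (G1_high − G1_low)`, with G_low the valley
   minimum (±80 bp) and G_high the mean of the flank maxima
   (±100–300 bp); F ≥ 0.5 is *strong* depletion.
4. **Co-occurrence.** A TF is bound to an FBS when the center 10 bp of
   one of its peaks overlaps the FBS (extended to 180 bp if shorter).
   The co-occurrence rate of TFs A and B is
   `N_both / max(N_A, N_B)`; family co-occupancy is the fraction of FBSs
   where both families are present.
5. **Variant enrichment.**
   `fold = (N_var_S / length_S) / (N_var_T / length_T)` with a one-sided
   binomial test; FBS-vs-MP relative enrichment, chromHMM majority-state
   assignment (quiescent only when 100%), promoter (−2 kb/+1 kb around
   expressed TSSs) and enhancer classification, loop-anchor overlap vs
   length-matched random sites, and conservation metaprofiles.

A seeded synthetic-data module generates every input the pipeline
consumes — peak sets clustered at planted focal sites, an MNase-like
track with planted valleys and phased flanking nucleosomes, variant sets
with a planted density fold — so the full chain runs and is tested
without any download.

## Worked example

```python
import fbscan

# a small seeded compendium: 12 TFs, 20 planted focal sites, ~350 kb
ds = fbscan.simulate(fbscan.tiny_config(seed=1))
report = fbscan.recovery_report(ds)
for k in ("c_t", "n_calls", "recall", "precision",
          "recovered_f", "planted_f", "recovered_fold", "planted_rho"):
    print(f"{k:>15}: {report[k]:.3f}")
```

prints

```
            c_t: 1.000
        n_calls: 20.000
         recall: 1.000
      precision: 1.000
    recovered_f: 0.618
      planted_f: 0.600
 recovered_fold: 8.646
    planted_rho: 10.000
```

Reading this: the bin-density threshold derived from this small compendium
is C_T = 1 center per 10-bp bin; the caller emits 20 FBS_P90 calls that
recover all 20 planted focal sites with no false positives; the
nucleosome-depletion statistic for the planted "lonely" site class is
F ≈ 0.62 against a planted 0.60; and the variant-density fold in focal
windows is ≈ 8.6 against a planted 10 (within sampling error at ~200
in-window variants — the default-scale fixture estimates it much more
tightly).

The same pipeline runs from the shell:

```sh
fbscan simulate --preset tiny --seed 1 --outdir fix
fbscan callfbs --manifest fix/manifest.tsv --chrom-sizes fix/chrom.sizes --outdir out
fbscan enrich --variants fix/variants_planted.tsv --sites out/fbs_p90.bed \
    --chrom-sizes fix/chrom.sizes
```

`fbscan prep`, `merge`, `rank` and `cooccur` cover filtering/replicate
reconciliation, MP construction, the cumulative enrichment curve and the
co-occurrence matrices. On real data, point the manifest at your
narrowPeak files and supply genome-sized chromosome sizes; the pipeline
then reports the corpus-scale quantities (C_T, FBS tallies at each
percentile, bp/event coverage fractions) for that corpus.

## Layout

- `src/fbscan/core.py` — interval model, I/O, filtering, merging, ranking
- `src/fbscan/fbs.py` — the three-step FBS caller
- `src/fbscan/nucleosome.py` — shifted tracks, metaprofiles, depletion F
- `src/fbscan/cooccurrence.py` — binding matrix, co-occurrence, families
- `src/fbscan/enrichment.py` — variant/loop enrichment, states, CREs
- `src/fbscan/simulate.py` — seeded synthetic compendium + ground truth
- `docs/methods.md` — models, parameters, numerical choices, limitations
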