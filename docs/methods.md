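# Methods

This document describes the statistical model behind each pipeline stage,
the default parameters and why they are set the way they are, what the
synthetic data generator does and does not emulate, and the numerical
choices that matter for reproducibility.

## Signal model

A FAIRE-chip experiment hybridizes FAIRE-enriched DNA against sheared
input DNA on a two-channel tiling array. The primary observable is the
per-probe log2(FAIRE/input) ratio. The working model is:

- probes inside a nucleosome-depleted region (NDR) have elevated mean
  ratio; probes outside sit at an array-specific baseline;
- probe noise is approximately independent across probes after
  normalization;
- the baseline varies between arrays (labeling and hybridization
  efficiency), so ratios must be centred per array before thresholding.

### Array scaling (Tukey biweight)

Each condition's ratios are centred by subtracting their Tukey biweight
(bisquare) location, computed over all probes of the array (all
chromosomes pooled). The biweight is an iteratively reweighted mean with
weights `w = (1 - u²)²` for `|u| < 1` and 0 otherwise, where
`u = (x - m) / (c · MAD)`. It is started at the median and iterated to a
tolerance of 1e-6 (at most 50 iterations). The tuning constant defaults
to `c = 5.0`, a conventional choice for microarray normalization that
keeps the estimator efficient while rejecting the enriched tail. When the
MAD is zero (more than half the probes identical) the median is returned
directly.

The biweight rather than the mean is used because the enriched probes are
exactly the signal of interest: a plain mean would be pulled upward by
them and thresholds anchored to it would drift with the amount of open
chromatin on the array.

### Peak calling (iterative-threshold sliding window)

Peaks are called per chromosome on the scaled ratios:

1. A *hypothetical maximum* is computed as `mean + sd_mult · SD` of the
   chromosome's scaled ratios (sample SD, `ddof = 1`); `sd_mult`
   defaults to 6.
2. A descending series of cutoffs is taken as percentages of the
   hypothetical maximum, from `p_start = 90` down to `p_end = 15` in
   steps of `p_step = 0.5` (151 cutoffs by default). An optional
   `max_steps` truncates the series from the top; it is off by default so
   the full percentage range is always scanned.
3. At each cutoff, a 300-bp window (`window_bp`) anchored at each probe
   start qualifies when at least `min_probes = 4` above-cutoff probes
   start inside it. Overlapping qualifying windows merge into regions.
4. Within a merged region, a run of more than `gap_probes = 2`
   consecutive below-cutoff probes splits the region. Each resulting
   segment is trimmed to its above-cutoff probes and kept if it still
   contains at least `min_probes` of them.
5. The final peak set is the union over all cutoffs; overlapping
   detections merge to their union span and each peak is scored with the
   highest percentage at which any part of it was detected (`score_pct`),
   together with the above-cutoff probe count of that detection.

The defaults (300-bp window, 4 probes, 90→15% in 0.5% steps, mean + 6 SD)
match the vendor-style sliding-window analysis that this caller
re-implements. At ~23 bp probe spacing a 300-bp window holds roughly 13
probes, so the 4-probe minimum demands that about a third of a window's
probes be elevated. Requiring `scale_tracks` before `call_peaks`
(`require_scaled = True`) is enforced because the percentage cutoffs are
meaningless on uncentred ratios.

Peak calling operates with prefix sums and `searchsorted` rather than
explicit window scans; the test suite checks its output is *identical* to
an exhaustive matrix-based oracle over the full default cutoff series.

## Concordance

NDRs are defined as regions detected under both formaldehyde
cross-linking conditions (8 and 12 min): `merge_conditions` builds the
overlap graph between the two per-condition peak sets (two intervals
overlap when they share at least 1 bp under half-open arithmetic) and
keeps each connected component that contains at least one peak from each
condition, reported as the component's union span. Cross-cell-type
comparison (`compare_cell_types`) uses the same component construction
and counts a component containing peaks from both cell types as one
shared region; shared fractions are reported per side to one decimal
place, because a component may contain several peaks from one side.

## Annotation

Peaks are classified against gene models with the precedence
`promoter_5utr > utr3 > exonic > intronic > intergenic`. The promoter
class is the strand-aware 2-kb window upstream of the TSS
(`promoter_bp = 2000`) together with the 5'UTR; a peak overlapping it for
any gene takes that class immediately. TSS distances are measured from
the peak midpoint to the nearest TSS, signed negative upstream with
respect to the gene's strand; ties break to the lexicographically smaller
gene id so results are deterministic. Summary statistics use a ±20-kb
window (`tss_window_bp = 20000`), a conventional "near a promoter" scale
for regulatory elements.

## Variant prioritization

Index SNPs are expanded to LD proxies with `r² ≥ 0.8` and `MAF ≥ 0.05`
(no distance cap); every index SNP is its own proxy at r² = 1. These
thresholds are the standard "proxy" definition for tag-SNP follow-up: at
r² ≥ 0.8 an association at the index transfers substantially to the
proxy, and the MAF floor excludes variants too rare for the LD estimate
to be stable. Proxies are intersected with each cell type's NDRs using
half-open containment (`start ≤ pos < end`); each SNP inside at least one
NDR becomes one prioritized record carrying the harboring peak per cell
type, a cell-specificity label (`<CT>_only` or `shared`), distance to its
index SNP, and a feature class when gene models are supplied. An optional
motif table flags SNPs where a motif instance exists for one allele but
not the other.

Lineage enrichment asks whether a cell type's NDRs cluster at that
lineage's signature genes: `lineage_peak_density` counts peaks
overlapping each gene ± 2 kb (`gene_flank_bp`) per megabase of gene
length, and `lineage_enrichment_test` compares the per-gene densities
between cell types with the exact Wilcoxon rank-sum test.

## Exact Wilcoxon rank-sum test

For combined sample sizes up to `exact_limit = 20`, the null distribution
of the rank sum is enumerated over all `C(n, n_a)` assignments of the
pooled mid-ranks (so ties are handled exactly); one-sided P-values count
assignments at least as extreme as observed, the two-sided P counts
assignments whose deviation from the null mean is at least as large, and
comparisons use a 1e-9 slack so that floating-point rank sums tie
correctly. Above the limit a normal approximation with tie-corrected
variance and continuity correction is used. Enumeration was chosen
because lineage gene panels are small (8 genes per lineage), where the
normal approximation is unreliable. Combination index arrays are cached
per `(n, n_a)`, so repeated small-sample tests (e.g. the type-I error
campaign in the acceptance suite) stay fast.

## Expression analyses

- **eQTL**: Spearman rank correlation between genotype dosage (0/1/2) and
  expression, with the nominal t-approximation P-value; cis testing uses
  a ±1 Mb TSS window. Rank correlation is preferred because it is
  invariant to monotone transformations of expression and robust to the
  coarse, tied genotype scale. Degenerate inputs (constant vectors, < 3
  samples) raise rather than returning NaN.
- **Differential expression**: per-gene log2 fold-change as the
  difference of group means on the log2 scale, a one-way ANOVA P-value
  (equivalent to a two-sample t-test for two groups), and a linear-scale
  fold-change cut-off: a gene passes when `|log2FC| ≥ log2(fc_min)` with
  `fc_min = 1.5`. Groups need at least 2 samples; the design target is a
  3 vs 3 knockout screen.
- **Over-representation**: hypergeometric upper tail
  `P[X ≥ k] = sf(k - 1, |universe|, |set|, |hits|)`.

## Network construction

Core proteins (e.g. orthologs of knockout-responsive genes, via
`map_orthologs`; unmapped genes are reported, not fatal) are expanded to
their first-order interactors in a pairwise interaction table. Non-core
interactors whose expression detection P exceeds `detection_p_max = 0.01`
— or that have no detection value at all — are removed; cores are exempt
unless `filter_cores` is set, because the cores were selected on
independent evidence. Edges are induced on the survivors and only the
largest connected component is retained (ties break to the component with
more edges, then the lexicographically smallest node set, making the
output deterministic).

## Synthetic data

The generators in `fairechip.simulate` are pure functions of their
parameters and a seed; every stage derives an independent substream from
`(seed, stage label)` so adding a stage never perturbs another stage's
draws. The defaults mirror the study-scale design: 62 tiled loci of
~155 kb (~9.6 Mb total), ~23 bp probe spacing with 50–75-mer probes, two
cross-linking conditions (8/12 min), two cell types (MK/EB) with 58% of
planted NDRs shared, 8 signature genes per lineage, and a 3 vs 3
knockout expression design.

What they emulate:

- two-level probe signal (baseline vs planted enrichment of
  `enrichment_log2 = 2`) with i.i.d. Gaussian noise (`noise_sd = 0.5`)
  and a per-condition mean offset emulating cross-linking differences;
- gene models with exon/intron structure, UTRs and strand-dependent TSS;
- star-shaped LD: index SNPs with proxies in the same locus, uniform r²
  and MAF; Hardy–Weinberg genotypes;
- group-structured expression with planted log2 fold-changes and
  detection P-values thresholded on expression level;
- random interactomes with a configurable expressed fraction.

What they do **not** emulate: probe GC/affinity bias, spatially
correlated noise, copy-number or mappability artifacts, realistic LD
block structure (proxy–proxy correlation is not modelled), linked
genotype–expression effects (eQTL signal must be planted by the caller),
or any real genome's gene density. Conclusions about absolute peak counts
or concordance percentages on synthetic data therefore characterize the
algorithms, not biology.

## Numerical and convention choices

- Intervals are 0-based half-open internally; BED I/O is 0-based
  half-open (score column = `score_pct × 10`), GFF3 is 1-based inclusive,
  SNP positions are 1-based on disk and 0-based in memory.
- `interval_length` supports both half-open and one-based-inclusive
  conventions explicitly, since published coordinates mix the two.
- Sample SD (`ddof = 1`) everywhere a spread is estimated from data.
- The cutoff-series length uses a floor with a 1e-9 slack so that an
  exactly divisible percentage range includes its endpoint.
- All ties (nearest gene, component selection) break lexicographically so
  repeated runs are byte-identical.

## Limitations

- The peak caller assumes probes are sorted and unique per chromosome
  (enforced at I/O) and that a chromosome has non-degenerate variance; a
  flat chromosome raises an error rather than guessing a threshold.
- `merge_conditions` requires only ≥ 1 bp overlap; with very dense peak
  sets, chained components can produce long union spans.
- The exact rank-sum enumeration is limited to combined n ≤ 20 by
  memory/time; larger samples use the normal approximation.
- The ANOVA assumes equal-variance Gaussian noise within groups; with 3
  samples per group its P-values are indicative, which is why the screen
  gates on fold-change rather than P alone.
- The eQTL stage reports nominal P-values only; multiple-testing control
  is left to the caller.
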