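# fairechip

Open-chromatin analysis for two-channel FAIRE tiling arrays (FAIRE-chip),
with downstream prioritization of GWAS variants that fall inside open
chromatin.

FAIRE (formaldehyde-assisted isolation of regulatory elements) enriches
protein-depleted, nucleosome-free DNA; hybridized against an input channel
on a tiling microarray it yields per-probe log2(FAIRE/input) ratios in
which nucleosome-depleted regions (NDRs) appear as runs of elevated
signal. NDRs concentrate active regulatory elements, so non-coding
trait-associated variants that land inside a cell-type's NDRs are strong
candidates for being the functional variant at a locus.

This package implements that analysis end to end:

- **Peak calling** (`fairechip.peaks`) — array-wide scaling by the Tukey
  biweight location, then an iterative-threshold sliding-window caller: a
  descending series of cutoffs taken as percentages of a per-chromosome
  hypothetical maximum (mean + 6 SD), 300-bp windows qualifying with ≥ 4
  above-cutoff probes, gap-based region splitting, and a union over all
  cutoffs scored by the highest detecting percentage.
- **Concordance** (`fairechip.concordance`) — NDRs are the regions
  detected in both formaldehyde cross-linking conditions (8 and 12 min);
  cross-cell-type comparison counts shared regions as connected components
  of the overlap graph between two peak sets.
- **Annotation** (`fairechip.annotation`) — feature classification
  (promoter/5'UTR, 3'UTR, exonic, intronic, intergenic) with strand-aware
  promoter windows and signed distance to the nearest TSS.
- **Variant prioritization** (`fairechip.prioritize`) — LD-proxy expansion
  of index SNPs (r² ≥ 0.8, MAF ≥ 0.05), intersection of proxies with
  cell-type-resolved NDRs, cell-specificity labels, and a lineage-gene
  peak-density enrichment test using an exact Wilcoxon rank-sum test
  (`fairechip.ranktest`).
- **Expression analyses** (`fairechip.expression`) — Spearman cis-eQTL
  association, a knockout-vs-wild-type fold-change + ANOVA screen, and a
  hypergeometric gene-set over-representation test.
- **Network construction** (`fairechip.ppi`) — first-order
  protein-interaction neighborhoods of core genes, filtered to expressed
  interactors (detection P ≤ 0.01), reduced to the largest connected
  component.
- **Synthetic data** (`fairechip.simulate`) — seeded generators for every
  input the pipeline consumes: tiled loci with gene models, planted NDRs,
  probe layouts and noisy two-condition signal, star-shaped LD panels,
  genotypes, group-structured expression, and random interactomes.

All genomic intervals are 0-based half-open internally; BED output is
0-based half-open, GFF3 output 1-based inclusive, and SNP positions are
1-based on disk.

## Test

```bash
python -m pytest -q tests/
```

The suite includes unit tests, derandomized property tests, and an
acceptance suite (`tests/test_acceptance.py`) that checks exact worked
examples and runs oracle-equivalence and sensitivity campaigns against
brute-force reference implementations in `tests/oracles.py`.

## Worked example

Simulate a small two-cell-type study, call NDRs per cross-linking
condition, keep the condition-concordant regions, and compare cell types:

```python
from fairechip import (
    PeakCallParams, simulate_locus_panel, simulate_ndr_truth,
    simulate_probe_track, simulate_faire_signal, scale_tracks, call_peaks,
    merge_conditions, compare_cell_types,
)

loci, genes = simulate_locus_panel(n_loci=8, locus_length_bp=60_000, seed=42)
truth, _ = simulate_ndr_truth(loci, seed=42)
layout = simulate_probe_track(loci, seed=42)

merged = {}
for ct in ("MK", "EB"):
    signal = simulate_faire_signal(layout, truth[ct], seed=42)
    per_cond = {}
    for cond in ("8min", "12min"):
        scaled = scale_tracks(signal, cond)
        per_cond[cond] = call_peaks(scaled, cond, PeakCallParams())
    merged[ct] = merge_conditions(per_cond["8min"], per_cond["12min"])
    print(f"{ct}: {len(merged[ct])} condition-concordant NDRs "
          f"({len(truth[ct])} planted)")

report = compare_cell_types(merged["MK"], merged["EB"])
print(f"shared regions: {report.n_shared} "
      f"({report.frac_a_shared}% of MK, {report.frac_b_shared}% of EB)")
top = max(merged["MK"], key=lambda r: r.score_pct)
print(f"top MK NDR: {top.interval.chrom}:{top.interval.start}-{top.interval.end} "
      f"score={top.score_pct}")
```

Output:

```
MK: 28 condition-concordant NDRs (28 planted)
EB: 20 condition-concordant NDRs (20 planted)
shared regions: 16 (57.1% of MK, 80.0% of EB)
top MK NDR: chr1:642990-644244 score=67.0
```

The same pipeline is available from the command line:

```bash
fairechip --seed 42 --out-dir out run-all --n-loci 8 --locus-length 60000
fairechip call-peaks --probes out/probes_MK_8min.tsv --condition 8min \
    --out out/peaks.bed
```

## Reproduction

`scripts/acceptance.py` runs the whole pipeline on a study-scale synthetic
dataset (62 tiled loci of ~155 kb each, ~23 bp probe spacing, 50–75-mer
probes, two cross-linking conditions, two cell types, a 3 vs 3 knockout
expression screen) and writes the main computed quantities — peak counts,
condition concordance, shared-NDR fractions, planted-NDR recovery, TSS
proximity, prioritized-variant counts, lineage Wilcoxon P, DE sensitivity
and network size — as JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Each entry has the form `{"<name>": {"value": <number>, "n": <size>}}`
where `n` is the number of observations the value was computed over. The
run takes about 20 seconds on one CPU and is fully deterministic given
`--seed`.

See `docs/methods.md` for the model, parameter defaults, and the scope and
limitations of the synthetic data generator.
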