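"""Synthetic inputs with the statistical structure the pipeline assumes.

Every generator is a pure function of its parameters and an integer seed,
so identical seeds give byte-identical outputs. The defaults emulate the
study layout this pipeline is built for: 62 loci totalling ~9.6 Mb of
tiled sequence, ~23 bp mean probe spacing with 50-75-mer probes, planted
nucleosome-depleted regions (NDRs) carrying a log2 enrichment over
Gaussian probe noise, two formaldehyde cross-linking conditions per cell
type, two cell types sharing a configurable fraction of NDRs, eight
lineage-specific reference genes per lineage, star-shaped LD panels around
index SNPs, 3 vs 3 knockout expression with planted fold-changes, and a
seed-centred interactome with per-node detection P-values.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    ExpressionMatrix,
    GeneModel,
    GenomicInterval,
    InteractionTable,
    LDPair,
    LDTable,
    PeakRecord,
    PeakSet,
    ProbeTrack,
    SNPRecord,
)

__all__ = [
    "SimulationTruth",
    "substream",
    "simulate_locus_panel",
    "simulate_ndr_truth",
    "simulate_probe_track",
    "simulate_faire_signal",
    "simulate_ld_panel",
    "simulate_genotypes",
    "simulate_expression",
    "simulate_interactome",
]


@dataclass
class SimulationTruth:
    """Ground truth of a simulation run, serializable to BED/TSV."""

    planted_ndrs: dict[str, PeakSet] = field(default_factory=dict)
    shared_flags: dict[str, list[bool]] = field(default_factory=dict)
    planted_proxy_map: dict[str, list[tuple[str, float]]] = field(default_factory=dict)
    planted_de_genes: dict[str, float] = field(default_factory=dict)
    seed: int = 0


def substream(seed: int, label: str) -> np.random.Generator:
    """Deterministic per-stage random generator derived from a global seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(zlib.crc32(label.encode()),))
    )


# ---------------------------------------------------------------------------
# loci and genes
# ---------------------------------------------------------------------------


def simulate_locus_panel(n_loci: int = 62, locus_length_bp: int = 155_000,
                         genes_per_locus: int = 2, seed: int = 0,
                         n_lineage_genes: int = 8,
                         loci_per_chrom: int = 8,
                         ) -> tuple[list[GenomicInterval], list[GeneModel]]:
    """Non-overlapping tiled loci with gene models inside.

    Locus lengths jitter uniformly within +/- 5% of ``locus_length_bp``;
    each gene gets a TSS at its strand-appropriate end, 2-6 exons, a 5'-
    and a 3'-UTR, and ``n_lineage_genes`` genes per lineage (MK, EB, MONO)
    carry lineage labels.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    rng = substream(seed, "locus_panel")
    loci: list[GenomicInterval] = []
    genes: list[GeneModel] = []
    gap = 50_000
    cursor: dict[str, int] = {}
    for li in range(n_loci):
        chrom = f"chr{li // loci_per_chrom + 1}"
        start = cursor.get(chrom, 100_000)
        length = int(rng.integers(int(locus_length_bp * 0.95), int(locus_length_bp * 1.05) + 1))
        locus = GenomicInterval(chrom, start, start + length)
        cursor[chrom] = locus.end + gap
        loci.append(locus)

        slot = length // genes_per_locus
        min_gene = 5_000
        if slot < min_gene + 2_000:
            raise ValueError(
                f"locus_length_bp={locus_length_bp} too small for {genes_per_locus} genes"
            )
        for gi in range(genes_per_locus):
            slot_start = locus.start + gi * slot
            gene_len = int(rng.integers(min_gene, min(40_000, slot - 1_000) + 1))
            offset = int(rng.integers(0, slot - gene_len))
            g_start = slot_start + offset
            g_end = g_start + gene_len
            strand = "+" if rng.random() < 0.5 else "-"
            gene_id = f"G{li:03d}_{gi}"
            genes.append(_make_gene(gene_id, chrom, g_start, g_end, strand, rng))

    order = rng.permutation(len(genes))
    per_lineage = min(n_lineage_genes, len(genes) // 3)
    for lineage, block in zip(("MK", "EB", "MONO"), range(3)):
        for k in range(per_lineage):
            idx = order[block * per_lineage + k]
            g = genes[idx]
            genes[idx] = GeneModel(
                g.gene_id, g.interval, g.strand, g.tss, g.exons, g.utr5, g.utr3, lineage
            )
    return loci, genes


def _make_gene(gene_id: str, chrom: str, start: int, end: int, strand: str,
               rng: np.random.Generator) -> GeneModel:
    length = end - start
    n_exons = int(rng.integers(2, 7))
    # split the gene body into alternating exon/intron segments
    cuts = np.sort(rng.choice(np.arange(1, length), size=2 * n_exons - 2, replace=False))
    bounds = np.concatenate(([0], cuts, [length]))
    exons = tuple(
        GenomicInterval(chrom, start + int(bounds[2 * k]), start + int(bounds[2 * k + 1]))
        for k in range(n_exons)
    )
    first, last = exons[0], exons[-1]
    if strand == "+":
        tss = start
        utr5 = GenomicInterval(chrom, first.start, first.start + max(1, len(first) // 3))
        utr3 = GenomicInterval(chrom, last.end - max(1, len(last) // 3), last.end)
    else:
        tss = end - 1
        utr5 = GenomicInterval(chrom, last.end - max(1, len(last) // 3), last.end)
        utr3 = GenomicInterval(chrom, first.start, first.start + max(1, len(first) // 3))
    return GeneModel(gene_id, GenomicInterval(chrom, start, end, strand), strand,
                     tss, exons, utr5, utr3, None)


# ---------------------------------------------------------------------------
# NDR truth and probe signal
# ---------------------------------------------------------------------------


def simulate_ndr_truth(loci: Sequence[GenomicInterval],
                       cell_types: Sequence[str] = ("MK", "EB"),
                       ndrs_per_locus: int = 4,
                       ndr_len_range: tuple[int, int] = (300, 1_500),
                       shared_fraction: float = 0.58,
                       min_gap_bp: int = 3_000,
                       seed: int = 0) -> tuple[dict[str, PeakSet], dict[str, list[bool]]]:
    """Plant NDRs per cell type; a ``shared_fraction`` of sites is common.

    Candidate sites are placed with at least ``min_gap_bp`` between them;
    each site is then either shared by all cell types or assigned to one
    cell type at random.
    """
    rng = substream(seed, "ndr_truth")
    per_cell: dict[str, list[PeakRecord]] = {ct: [] for ct in cell_types}
    flags: dict[str, list[bool]] = {ct: [] for ct in cell_types}
    for locus in loci:
        positions: list[tuple[int, int]] = []
        attempts = 0
        while len(positions) < ndrs_per_locus and attempts < 200:
            attempts += 1
            length = int(rng.integers(ndr_len_range[0], ndr_len_range[1] + 1))
            start = int(rng.integers(locus.start, locus.end - length))
            if all(
                start >= e + min_gap_bp or start + length + min_gap_bp <= s
                for s, e in positions
            ):
                positions.append((start, start + length))
        for start, end in sorted(positions):
            shared = rng.random() < shared_fraction
            owners = list(cell_types) if shared else [cell_types[int(rng.integers(len(cell_types)))]]
            for ct in owners:
                per_cell[ct].append(
                    PeakRecord(GenomicInterval(locus.chrom, start, end), 100.0, 1, f"truth_{ct}")
                )
                flags[ct].append(shared)
    return {ct: PeakSet(records) for ct, records in per_cell.items()}, flags


def simulate_probe_track(loci: Sequence[GenomicInterval], mean_span_bp: int = 23,
                         probe_len_range: tuple[int, int] = (50, 75),
                         seed: int = 0) -> list[ProbeTrack]:
    """Tile each locus with probes at ~``mean_span_bp`` start-to-start spacing.

    Spacings are uniform integers in ``mean_span_bp +/- 10`` (truncated to
    stay positive); probe lengths uniform in ``probe_len_range``.
    """
    if mean_span_bp <= 0:
        raise ValueError("mean_span_bp must be positive")
    rng = substream(seed, "probe_track")
    lo = max(1, mean_span_bp - 10)
    hi = mean_span_bp + (mean_span_bp - lo)  # symmetric around the mean
    per_chrom: dict[str, tuple[list[int], list[int]]] = {}
    for locus in sorted(loci, key=lambda l: (l.chrom, l.start)):
        starts, lengths = per_chrom.setdefault(locus.chrom, ([], []))
        n_est = (len(locus) // lo) + 2
        spans = rng.integers(lo, hi + 1, size=n_est)
        pos = locus.start + np.concatenate(([0], np.cumsum(spans)))
        pos = pos[pos < locus.end]
        plens = rng.integers(probe_len_range[0], probe_len_range[1] + 1, size=pos.size)
        starts.extend(int(p) for p in pos)
        lengths.extend(int(p) for p in plens)
    return [
        ProbeTrack(chrom, np.array(starts, dtype=np.int64), np.array(lengths, dtype=np.int64))
        for chrom, (starts, lengths) in sorted(per_chrom.items())
    ]


def simulate_faire_signal(tracks: Sequence[ProbeTrack], truth_ndrs: PeakSet,
                          enrichment_log2: float = 2.0, noise_sd: float = 0.5,
                          baseline: float = 0.0,
                          conditions: Sequence[str] = ("8min", "12min"),
                          condition_jitter: float = 0.2,
                          seed: int = 0) -> list[ProbeTrack]:
    """Attach per-condition log2 ratios to probe tracks.

    A probe starting inside a planted NDR has mean ratio
    ``baseline + enrichment_log2 (+ a per-condition offset drawn from
    N(0, condition_jitter) emulating cross-linking differences)``; all
    other probes sit at ``baseline``. Probe noise is i.i.d. Gaussian with
    ``noise_sd``, drawn independently per condition.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = substream(seed, "faire_signal")
    offsets = {
        cond: (float(rng.normal(0.0, condition_jitter)) if condition_jitter > 0 else 0.0)
        for cond in conditions
    }
    ndrs_by_chrom: dict[str, list[PeakRecord]] = truth_ndrs.by_chrom()
    out = []
    for track in tracks:
        inside = np.zeros(track.n_probes, dtype=bool)
        for rec in ndrs_by_chrom.get(track.chrom, []):
            lo = np.searchsorted(track.starts, rec.interval.start, side="left")
            hi = np.searchsorted(track.starts, rec.interval.end, side="left")
            inside[lo:hi] = True
        new = track
        for cond in conditions:
            mean = baseline + np.where(inside, enrichment_log2 + offsets[cond], 0.0)
            noise = rng.normal(0.0, noise_sd, size=track.n_probes) if noise_sd > 0 else 0.0
            new = new.with_ratios(cond, mean + noise)
        out.append(new)
    return out


# ---------------------------------------------------------------------------
# SNPs, LD, genotypes
# ---------------------------------------------------------------------------


def simulate_ld_panel(loci: Sequence[GenomicInterval], n_index: int = 7,
                      proxies_per_index: int = 10,
                      r2_range: tuple[float, float] = (0.5, 1.0),
                      maf_range: tuple[float, float] = (0.05, 0.5),
                      seed: int = 0,
                      ) -> tuple[dict[str, SNPRecord], LDTable, list[str]]:
    """Index SNPs with star-shaped proxy panels inside their loci.

    Each index SNP is placed in its own locus with proxies scattered in
    the same locus; index-proxy r2 is drawn uniformly from ``r2_range``
    and MAF from ``maf_range`` (proxy-proxy r2 is not modelled). The LD
    table carries the self pair (r2 = 1) for every index SNP.
    """
    if proxies_per_index < 0:
        raise ValueError("proxies_per_index must be >= 0")
    if n_index > len(loci):
        raise ValueError("more index SNPs than loci")
    rng = substream(seed, "ld_panel")
    chosen = rng.choice(len(loci), size=n_index, replace=False)
    snps: dict[str, SNPRecord] = {}
    pairs: list[LDPair] = []
    index_ids: list[str] = []
    for k, locus_idx in enumerate(chosen):
        locus = loci[int(locus_idx)]
        index_id = f"rsI{k:03d}"
        index_ids.append(index_id)
        pos = int(rng.integers(locus.start, locus.end))
        snps[index_id] = SNPRecord(index_id, locus.chrom, pos,
                                   maf=float(rng.uniform(*maf_range)))
        pairs.append(LDPair(index_id, index_id, 1.0))
        for p in range(proxies_per_index):
            proxy_id = f"rsP{k:03d}_{p:03d}"
            ppos = int(rng.integers(locus.start, locus.end))
            snps[proxy_id] = SNPRecord(proxy_id, locus.chrom, ppos,
                                       maf=float(rng.uniform(*maf_range)))
            pairs.append(LDPair(index_id, proxy_id, float(rng.uniform(*r2_range))))
    return snps, LDTable(pairs), index_ids


def simulate_genotypes(snps: Mapping[str, SNPRecord], n_samples: int,
                       seed: int = 0) -> pd.DataFrame:
    """Hardy-Weinberg genotype dosages (0/1/2) per SNP x sample."""
    rng = substream(seed, "genotypes")
    data = {}
    for snp_id in sorted(snps):
        q = snps[snp_id].maf
        data[snp_id] = rng.binomial(2, q, size=n_samples)
    return pd.DataFrame.from_dict(
        data, orient="index", columns=[f"S{i:02d}" for i in range(n_samples)]
    )


# ---------------------------------------------------------------------------
# expression and interactome
# ---------------------------------------------------------------------------


def simulate_expression(n_genes: int = 500,
                        groups: Sequence[str] = ("KO", "KO", "KO", "WT", "WT", "WT"),
                        n_de: int = 50, log2_fc: float = 1.5,
                        noise_sd: float = 0.3,
                        baseline_mean: float = 8.0, baseline_sd: float = 2.0,
                        detect_threshold: float = 6.0,
                        seed: int = 0) -> tuple[ExpressionMatrix, SimulationTruth]:
    """Group-structured log2 expression with planted fold-changes.

    The first listed group carries the planted shift: ``n_de`` random
    genes differ in group means by ``log2_fc`` with random sign (others by
    0). Detection P-values emulate probe detection: cells whose value
    exceeds ``detect_threshold`` draw P ~ U(0, 0.01), others U(0.01, 1).
    """
    rng = substream(seed, "expression")
    groups = list(groups)
    group_names = list(dict.fromkeys(groups))
    if len(group_names) != 2:
        raise ValueError("simulate_expression expects exactly 2 groups")
    gene_ids = [f"g{i:04d}" for i in range(n_genes)]
    samples = [f"{g}{i}" for i, g in enumerate(groups)]
    baseline = rng.normal(baseline_mean, baseline_sd, size=n_genes)
    de_idx = rng.choice(n_genes, size=n_de, replace=False) if n_de else np.array([], dtype=int)
    signs = rng.choice([-1.0, 1.0], size=de_idx.size)
    shift = np.zeros(n_genes)
    shift[de_idx] = signs * log2_fc

    in_first = np.array([g == group_names[0] for g in groups])
    means = baseline[:, None] + shift[:, None] * in_first[None, :]
    noise = rng.normal(0.0, noise_sd, size=means.shape) if noise_sd > 0 else 0.0
    values = pd.DataFrame(means + noise, index=gene_ids, columns=samples)

    detected = values.to_numpy() > detect_threshold
    dp = np.where(
        detected,
        rng.uniform(0.0, 0.01, size=values.shape),
        rng.uniform(0.01, 1.0, size=values.shape),
    )
    detection = pd.DataFrame(dp, index=gene_ids, columns=samples)
    sample_groups = pd.Series(groups, index=samples, name="group")
    truth = SimulationTruth(
        planted_de_genes={gene_ids[i]: float(shift[i]) for i in de_idx}, seed=seed
    )
    return ExpressionMatrix(values, detection, sample_groups), truth


def simulate_interactome(core_ids: Sequence[str], n_interactors: int = 100,
                         edge_density: float = 0.05,
                         expressed_fraction: float = 0.8,
                         seed: int = 0) -> tuple[InteractionTable, dict[str, float]]:
    """Random interactome around core proteins with detection P per node.

    Every possible core-interactor and interactor-interactor pair becomes
    an edge with probability ``edge_density``; ``expressed_fraction`` of
    interactors receive detection P <= 0.01 (cores are always detected).
    """
    if not 0.0 <= edge_density <= 1.0:
        raise ValueError("edge_density must be in [0, 1]")
    rng = substream(seed, "interactome")
    cores = sorted(set(core_ids))
    interactors = [f"INT{i:04d}" for i in range(n_interactors)]
    pairs: list[tuple[str, str]] = []
    for core in cores:
        hit = rng.random(n_interactors) < edge_density
        pairs.extend((core, interactors[i]) for i in np.flatnonzero(hit))
    for i in range(n_interactors):
        hit = rng.random(n_interactors - i - 1) < edge_density
        pairs.extend((interactors[i], interactors[i + 1 + j]) for j in np.flatnonzero(hit))

    detection: dict[str, float] = {}
    for core in cores:
        detection[core] = float(rng.uniform(0.0, 0.01))
    expressed = rng.random(n_interactors) < expressed_fraction
    for i, node in enumerate(interactors):
        if expressed[i]:
            detection[node] = float(rng.uniform(0.0, 0.01))
        else:
            detection[node] = float(rng.uniform(0.011, 1.0))
    return InteractionTable(pairs), detection
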