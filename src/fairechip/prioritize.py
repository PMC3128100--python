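"""LD-proxy expansion, SNP/NDR intersection and lineage-gene peak enrichment.

Mirrors the GWAS follow-up logic: each index SNP is expanded to its LD
proxies (r2 and MAF thresholds, no distance limit), proxies falling inside
cell-type-resolved open-chromatin regions are reported with their cell
specificity, and lineage-specific reference genes are tested for FAIRE
peak enrichment between cell types with an exact Wilcoxon rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .annotation import classify_peak
from .model import GeneModel, GenomicInterval, PeakRecord, PeakSet, SNPRecord
from .model import LDTable
from .ranktest import RankSumResult, rank_sum_test

__all__ = [
    "expand_proxies",
    "PrioritizedVariant",
    "intersect_snps_ndrs",
    "lineage_peak_density",
    "lineage_enrichment_test",
    "annotate_motif_overlap",
    "report_table",
]


def expand_proxies(index_snp_ids: Sequence[str], ld: LDTable,
                   snps: Mapping[str, SNPRecord], r2_min: float = 0.8,
                   maf_min: float = 0.05) -> dict[str, list[tuple[str, float]]]:
    """Map each index SNP to itself (r2 = 1) plus all qualifying proxies.

    A proxy qualifies when its r2 to the index is >= ``r2_min`` and its MAF
    is >= ``maf_min``; no distance filtering is applied. Unknown index SNPs
    raise an error naming them.
    """
    out: dict[str, list[tuple[str, float]]] = {}
    for index_id in index_snp_ids:
        if index_id not in snps:
            raise KeyError(f"index SNP {index_id!r} absent from SNP panel")
        proxies = [(index_id, 1.0)]
        for snp_id, r2 in sorted(ld.partners(index_id).items()):
            if snp_id == index_id or snp_id not in snps:
                continue
            if r2 >= r2_min and snps[snp_id].maf >= maf_min:
                proxies.append((snp_id, r2))
        out[index_id] = proxies
    return out


@dataclass
class PrioritizedVariant:
    """A proxy SNP located inside an NDR, with cell-type resolution."""

    snp: SNPRecord
    index_snp_id: str
    r2_to_index: float
    #: cell type -> the peak containing the SNP (only cell types with a hit)
    harboring_peaks: dict[str, PeakRecord]
    cell_specificity: str  # e.g. "MK_only", "EB_only", "shared"
    distance_to_index_bp: int
    feature_class: Optional[str] = None
    motif_flags: list[str] = field(default_factory=list)


def _containing_peak(peaks: PeakSet, chrom: str, pos: int) -> Optional[PeakRecord]:
    for rec in peaks:
        if rec.interval.contains_point(chrom, pos):
            return rec
    return None


def intersect_snps_ndrs(proxy_map: Mapping[str, Sequence[tuple[str, float]]],
                        snps: Mapping[str, SNPRecord],
                        peaks_by_celltype: Mapping[str, PeakSet],
                        genes: Sequence[GeneModel] = (),
                        promoter_bp: int = 2_000) -> list[PrioritizedVariant]:
    """Proxy SNPs located within an NDR, one record per SNP.

    Containment is half-open (a SNP exactly at a peak end is outside).
    ``cell_specificity`` is ``"<CT>_only"`` when exactly one cell type has a
    peak over the SNP and ``"shared"`` otherwise. When gene models are
    supplied, the genomic-location class of one harboring peak is attached.
    """
    out: list[PrioritizedVariant] = []
    for index_id, proxies in proxy_map.items():
        index_pos = snps[index_id].pos
        for snp_id, r2 in proxies:
            snp = snps[snp_id]
            hits = {
                ct: peak
                for ct, peaks in peaks_by_celltype.items()
                if (peak := _containing_peak(peaks, snp.chrom, snp.pos)) is not None
            }
            if not hits:
                continue
            specificity = f"{next(iter(hits))}_only" if len(hits) == 1 else "shared"
            feature = None
            if genes:
                feature = classify_peak(next(iter(hits.values())), genes, promoter_bp)
            out.append(
                PrioritizedVariant(
                    snp=snp,
                    index_snp_id=index_id,
                    r2_to_index=r2,
                    harboring_peaks=hits,
                    cell_specificity=specificity,
                    distance_to_index_bp=abs(snp.pos - index_pos),
                    feature_class=feature,
                )
            )
    return out


def lineage_peak_density(peaks: PeakSet, genes: Sequence[GeneModel],
                         flank_bp: int = 2_000,
                         lineage: Optional[str] = None) -> dict[str, float]:
    """Peaks per Mb of gene for each (optionally lineage-filtered) gene.

    Counts peaks overlapping the gene body extended by ``flank_bp`` on both
    sides and normalizes by the gene length in megabases.
    """
    out: dict[str, float] = {}
    for gene in genes:
        if lineage is not None and gene.lineage_label != lineage:
            continue
        window = GenomicInterval(
            gene.interval.chrom, gene.interval.start - flank_bp, gene.interval.end + flank_bp
        )
        count = sum(rec.interval.overlaps(window) for rec in peaks)
        out[gene.gene_id] = count / (len(gene.interval) / 1e6)
    if not out:
        raise ValueError("lineage_peak_density: no genes selected")
    return out


def lineage_enrichment_test(densities_cell_a: Mapping[str, float],
                            densities_cell_b: Mapping[str, float],
                            alternative: str = "two_sided") -> RankSumResult:
    """Wilcoxon rank-sum comparison of per-gene peak densities.

    Exact enumeration for small samples (mid-ranks under ties), normal
    approximation with continuity correction otherwise.
    """
    return rank_sum_test(
        list(densities_cell_a.values()), list(densities_cell_b.values()), alternative
    )


def annotate_motif_overlap(variants: Sequence[PrioritizedVariant],
                           motif_intervals: Optional[pd.DataFrame]) -> None:
    """Flag variants that fall in motifs predicted for only one allele.

    ``motif_intervals`` columns: motif_id, chrom, start, end (0-based
    half-open), allele ("ref" or "alt"). A variant is flagged with a motif
    id when the set of alleles whose predicted intervals contain it is a
    proper, non-empty subset of {ref, alt} — i.e. the substitution creates
    or disrupts the predicted site. With no motif table, flags stay empty.
    """
    if motif_intervals is None or len(motif_intervals) == 0:
        return
    for var in variants:
        chrom, pos = var.snp.chrom, var.snp.pos
        flags = []
        for motif_id, sub in motif_intervals.groupby("motif_id"):
            alleles_containing = {
                row.allele
                for row in sub.itertuples()
                if row.chrom == chrom and row.start <= pos < row.end
            }
            if alleles_containing and alleles_containing != {"ref", "alt"}:
                flags.append(str(motif_id))
        var.motif_flags = sorted(flags)


def report_table(variants: Sequence[PrioritizedVariant]) -> pd.DataFrame:
    """Tabular report: one row per prioritized variant.

    The distance column is proxy-to-index distance rounded to the nearest
    kilobase; positions are emitted 1-based.
    """
    rows = []
    for v in variants:
        rows.append(
            {
                "cell_type": v.cell_specificity,
                "snp_id": v.snp.snp_id,
                "chrom": v.snp.chrom,
                "pos": v.snp.pos + 1,
                "maf": v.snp.maf,
                "annotation": v.feature_class or ".",
                "index_snp_id": v.index_snp_id,
                "r2": v.r2_to_index,
                "distance_kb": int(round(v.distance_to_index_bp / 1000.0)),
                "motif_flags": ",".join(v.motif_flags) or ".",
            }
        )
    return pd.DataFrame(rows)
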