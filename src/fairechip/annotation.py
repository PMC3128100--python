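"""Peak classification against gene structure and TSS-distance profiling."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .model import GeneModel, GenomicInterval, PeakRecord, PeakSet

__all__ = [
    "FEATURE_CLASSES",
    "PeakAnnotation",
    "classify_peak",
    "tss_distance",
    "annotate_peaks",
    "tss_summary",
    "class_fractions",
    "class_fraction_fold",
]

#: classification precedence, most specific first
FEATURE_CLASSES = ("promoter_5utr", "utr3", "exonic", "intronic", "intergenic")


@dataclass(frozen=True)
class PeakAnnotation:
    peak: PeakRecord
    feature_class: str
    nearest_gene_id: str
    #: signed bp from peak midpoint to the nearest TSS; negative = upstream
    #: of the TSS with respect to the gene's strand
    tss_distance_bp: int


def _promoter_window(gene: GeneModel, promoter_bp: int) -> GenomicInterval:
    """Upstream promoter window of length ``promoter_bp``, strand-aware.

    For a + strand gene this is ``[tss - promoter_bp, tss)``; the mirror
    image for a - strand gene.
    """
    if gene.strand == "+":
        return GenomicInterval(gene.interval.chrom, gene.tss - promoter_bp, gene.tss)
    return GenomicInterval(gene.interval.chrom, gene.tss + 1, gene.tss + 1 + promoter_bp)


def classify_peak(peak: PeakRecord, genes: Sequence[GeneModel],
                  promoter_bp: int = 2_000) -> str:
    """Genomic-location class of a peak, by >= 1 bp overlap with precedence.

    Precedence: promoter/5'-UTR > 3'-UTR > exonic > intronic > intergenic.
    The promoter class is the union of the strand-aware upstream window and
    any annotated 5'-UTR; a peak inside a gene that touches no exon/UTR is
    intronic.
    """
    iv = peak.interval
    best = len(FEATURE_CLASSES) - 1  # intergenic
    for gene in genes:
        if gene.interval.chrom != iv.chrom:
            continue
        if iv.overlaps(_promoter_window(gene, promoter_bp)) or (
            gene.utr5 is not None and iv.overlaps(gene.utr5)
        ):
            return FEATURE_CLASSES[0]
        if gene.utr3 is not None and iv.overlaps(gene.utr3):
            best = min(best, 1)
        elif any(iv.overlaps(exon) for exon in gene.exons):
            best = min(best, 2)
        elif iv.overlaps(gene.interval):
            best = min(best, 3)
    return FEATURE_CLASSES[best]


def tss_distance(peak: PeakRecord, genes: Sequence[GeneModel]) -> tuple[str, int]:
    """Nearest gene and signed midpoint-to-TSS distance.

    The sign is negative when the peak midpoint lies 5' of the TSS in the
    gene's orientation (upstream). Ties in absolute distance are broken
    toward the lexicographically smaller gene id.
    """
    if not genes:
        raise ValueError("tss_distance: no genes")
    mid = peak.interval.midpoint
    best: Optional[tuple[int, str, int]] = None
    for gene in genes:
        if gene.interval.chrom != peak.interval.chrom:
            continue
        signed = mid - gene.tss if gene.strand == "+" else gene.tss - mid
        key = (abs(signed), gene.gene_id, signed)
        if best is None or key < best:
            best = key
    if best is None:
        raise ValueError(f"tss_distance: no gene on {peak.interval.chrom}")
    return best[1], best[2]


def annotate_peaks(peaks: PeakSet, genes: Sequence[GeneModel],
                   promoter_bp: int = 2_000) -> list[PeakAnnotation]:
    out = []
    for rec in peaks:
        gene_id, dist = tss_distance(rec, genes)
        out.append(PeakAnnotation(rec, classify_peak(rec, genes, promoter_bp), gene_id, dist))
    return out


def tss_summary(annotations: Sequence[PeakAnnotation],
                window_bp: int = 20_000) -> tuple[float, float]:
    """(fraction of peaks within ``window_bp`` of a TSS, mean upstream distance).

    The mean is taken over upstream peaks only and reported as a positive
    bp value (mean of ``-distance`` where distance < 0).
    """
    if not annotations:
        raise ValueError("tss_summary: no annotations")
    dists = [a.tss_distance_bp for a in annotations]
    frac = sum(abs(d) <= window_bp for d in dists) / len(dists)
    upstream = [-d for d in dists if d < 0]
    mean_up = sum(upstream) / len(upstream) if upstream else 0.0
    return frac, mean_up


def class_fractions(annotations: Sequence[PeakAnnotation]) -> dict[str, float]:
    """Percentage of peaks per feature class (sums to 100 up to rounding)."""
    if not annotations:
        raise ValueError("class_fractions: no annotations")
    out = {cls: 0 for cls in FEATURE_CLASSES}
    for a in annotations:
        out[a.feature_class] += 1
    return {cls: 100.0 * n / len(annotations) for cls, n in out.items()}


def class_fraction_fold(frac_shared_pct: float, frac_specific_pct: float) -> float:
    """Fold enrichment of a class fraction in shared vs cell-specific peaks."""
    if frac_specific_pct == 0:
        raise ValueError("class_fraction_fold: zero denominator")
    return round(frac_shared_pct / frac_specific_pct, 1)
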