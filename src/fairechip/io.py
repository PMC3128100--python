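"""Readers and writers for every external format the pipeline touches.

Conventions
-----------
* BED: 0-based half-open; peak scores emitted in the BED score column
  scaled to 0-1000 (``score_pct * 10``).
* GFF3: 1-based inclusive; ``score_pct`` carried verbatim as an attribute.
* SNP tables: positions 1-based on disk, 0-based in memory.
* Probe/gene/LD/expression/interaction tables: plain TSV; probe and gene
  coordinates are written in the internal 0-based half-open convention.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Optional, Sequence

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
    "ParseError",
    "interval_length",
    "read_probe_track",
    "write_probe_track",
    "read_intervals_bed",
    "write_intervals_bed",
    "write_peaks_bed",
    "read_peaks_bed",
    "write_peaks_gff3",
    "read_peaks_gff3",
    "read_gene_table",
    "write_gene_table",
    "read_snp_table",
    "write_snp_table",
    "read_ld_table",
    "write_ld_table",
    "read_expression",
    "write_expression",
    "read_interactions",
    "write_interactions",
    "read_ortholog_map",
]


class ParseError(ValueError):
    """Malformed input file; message carries the file and line number."""


def interval_length(start: int, end: int, convention: str) -> int:
    """Length of an interval under a named coordinate convention.

    ``half_open``: ``end - start`` (0-based, end exclusive).
    ``one_based_inclusive``: ``end - start + 1`` (both endpoints counted),
    the convention of printed PCR-product coordinates.
    """
    if convention == "half_open":
        length = end - start
    elif convention == "one_based_inclusive":
        length = end - start + 1
    else:
        raise ValueError(f"unknown convention {convention!r}")
    if length < 0:
        raise ValueError(f"negative length for ({start}, {end}) under {convention}")
    return length


# ---------------------------------------------------------------------------
# probe tracks
# ---------------------------------------------------------------------------

PROBE_COLUMNS = ("chrom", "start", "length", "log2_ratio")


def read_probe_track(path: str | Path, condition_label: str) -> list[ProbeTrack]:
    """Read a per-condition probe table (TSV: chrom, start, length, log2_ratio).

    Returns one :class:`ProbeTrack` per chromosome, sorted by probe start.
    Unsorted input is sorted with a warning; a duplicated probe start on a
    chromosome is an error naming the position.
    """
    path = Path(path)
    rows: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != PROBE_COLUMNS:
            raise ParseError(f"{path}:1: expected header {PROBE_COLUMNS}, got {tuple(header)}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 fields, got {len(fields)}")
            try:
                chrom = fields[0]
                start = int(fields[1])
                length = int(fields[2])
                ratio = float(fields[3])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            rows.setdefault(chrom, []).append((start, length, ratio))

    tracks: list[ProbeTrack] = []
    for chrom in sorted(rows):
        recs = rows[chrom]
        starts = [r[0] for r in recs]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            if len(set(starts)) != len(starts):
                dup = next(s for i, s in enumerate(starts) if s in starts[:i])
                raise ParseError(f"{path}: duplicate probe start {chrom}:{dup}")
            warnings.warn(f"{path}: probes on {chrom} were unsorted; sorting", stacklevel=2)
            recs = sorted(recs)
        else:
            seen = set(starts)
            if len(seen) != len(starts):  # pragma: no cover - caught above
                raise ParseError(f"{path}: duplicate probe start on {chrom}")
        tracks.append(
            ProbeTrack(
                chrom,
                np.array([r[0] for r in recs], dtype=np.int64),
                np.array([r[1] for r in recs], dtype=np.int64),
                {condition_label: np.array([r[2] for r in recs], dtype=float)},
            )
        )
    return tracks


def write_probe_track(tracks: Sequence[ProbeTrack], path: str | Path, condition: str) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(PROBE_COLUMNS) + "\n")
        for track in tracks:
            ratios = track.ratios[condition]
            for start, length, ratio in zip(track.starts, track.lengths, ratios):
                fh.write(f"{track.chrom}\t{start}\t{length}\t{float(ratio)!r}\n")


# ---------------------------------------------------------------------------
# intervals / peaks: BED and GFF3
# ---------------------------------------------------------------------------


def read_intervals_bed(path: str | Path) -> list[GenomicInterval]:
    """Read plain intervals from BED (first 3 columns; optional strand in col 6)."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: BED needs >= 3 columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise ParseError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "."
            out.append(GenomicInterval(chrom, start, end, strand))
    return out


def write_intervals_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def write_peaks_bed(peaks: PeakSet, path: str | Path, name_prefix: str = "peak") -> None:
    """Write peaks as BED6; score column = ``score_pct`` scaled to 0-1000."""
    with open(path, "w") as fh:
        for i, rec in enumerate(peaks, start=1):
            iv = rec.interval
            bed_score = int(round(rec.score_pct * 10))
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name_prefix}_{i}\t{bed_score}\t.\n"
            )


def read_peaks_bed(path: str | Path, source: str = "") -> PeakSet:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: BED needs >= 3 columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise ParseError(f"{path}:{lineno}: start >= end")
            score_pct = float(fields[4]) / 10.0 if len(fields) >= 5 else 100.0
            records.append(
                PeakRecord(GenomicInterval(chrom, start, end), score_pct, 1, source)
            )
    return PeakSet(records)


def write_peaks_gff3(peaks: PeakSet, path: str | Path, source: str = "fairechip") -> None:
    """Write peaks as GFF3 (1-based inclusive); score_pct carried verbatim."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, rec in enumerate(peaks, start=1):
            iv = rec.interval
            attrs = f"ID=peak_{i};score_pct={rec.score_pct!r};n_probes={rec.n_probes}"
            fh.write(
                f"{iv.chrom}\t{source}\topen_chromatin_region\t{iv.start + 1}\t{iv.end}\t"
                f"{rec.score_pct}\t.\t.\t{attrs}\n"
            )


def read_peaks_gff3(path: str | Path, source: str = "") -> PeakSet:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: GFF3 needs 9 columns")
            chrom, start1, end1 = fields[0], int(fields[3]), int(fields[4])
            if start1 > end1:
                raise ParseError(f"{path}:{lineno}: start > end")
            attrs = dict(kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv)
            score_pct = float(attrs.get("score_pct", fields[5]))
            n_probes = int(attrs.get("n_probes", 1))
            records.append(
                PeakRecord(GenomicInterval(chrom, start1 - 1, end1), score_pct, n_probes, source)
            )
    return PeakSet(records)


# ---------------------------------------------------------------------------
# genes
# ---------------------------------------------------------------------------

GENE_COLUMNS = (
    "gene_id", "chrom", "start", "end", "strand", "tss",
    "exons", "utr5", "utr3", "lineage",
)


def _fmt_iv(iv: Optional[GenomicInterval]) -> str:
    return f"{iv.start}-{iv.end}" if iv is not None else "."


def _parse_iv(chrom: str, text: str) -> Optional[GenomicInterval]:
    if text == ".":
        return None
    s, e = text.split("-")
    return GenomicInterval(chrom, int(s), int(e))


def write_gene_table(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models as TSV (coordinates 0-based half-open)."""
    with open(path, "w") as fh:
        fh.write("\t".join(GENE_COLUMNS) + "\n")
        for g in genes:
            exons = ",".join(f"{e.start}-{e.end}" for e in g.exons) or "."
            fh.write(
                "\t".join(
                    [
                        g.gene_id, g.interval.chrom, str(g.interval.start),
                        str(g.interval.end), g.strand, str(g.tss), exons,
                        _fmt_iv(g.utr5), _fmt_iv(g.utr3), g.lineage_label or ".",
                    ]
                )
                + "\n"
            )


def read_gene_table(path: str | Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != GENE_COLUMNS:
            raise ParseError(f"{path}:1: expected header {GENE_COLUMNS}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) != len(GENE_COLUMNS):
                raise ParseError(f"{path}:{lineno}: expected {len(GENE_COLUMNS)} fields")
            chrom = f[1]
            exons = tuple(
                _parse_iv(chrom, part) for part in f[6].split(",") if part != "."
            )
            genes.append(
                GeneModel(
                    gene_id=f[0],
                    interval=GenomicInterval(chrom, int(f[2]), int(f[3]), f[4]),
                    strand=f[4],
                    tss=int(f[5]),
                    exons=tuple(e for e in exons if e is not None),
                    utr5=_parse_iv(chrom, f[7]),
                    utr3=_parse_iv(chrom, f[8]),
                    lineage_label=None if f[9] == "." else f[9],
                )
            )
    return genes


# ---------------------------------------------------------------------------
# SNPs and LD
# ---------------------------------------------------------------------------

SNP_COLUMNS = ("snp_id", "chrom", "pos", "ref", "alt", "maf")


def write_snp_table(snps: Sequence[SNPRecord], path: str | Path) -> None:
    """Write SNPs as TSV; positions converted to 1-based."""
    with open(path, "w") as fh:
        fh.write("\t".join(SNP_COLUMNS) + "\n")
        for s in snps:
            fh.write(
                f"{s.snp_id}\t{s.chrom}\t{s.pos + 1}\t{s.alleles[0]}\t{s.alleles[1]}\t{s.maf!r}\n"
            )


def read_snp_table(path: str | Path) -> dict[str, SNPRecord]:
    out: dict[str, SNPRecord] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != SNP_COLUMNS:
            raise ParseError(f"{path}:1: expected header {SNP_COLUMNS}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) != 6:
                raise ParseError(f"{path}:{lineno}: expected 6 fields")
            rec = SNPRecord(f[0], f[1], int(f[2]) - 1, (f[3], f[4]), float(f[5]))
            out[rec.snp_id] = rec
    return out


def write_ld_table(table: LDTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("snp_a\tsnp_b\tr2\n")
        for p in table.pairs():
            fh.write(f"{p.snp_a}\t{p.snp_b}\t{p.r2!r}\n")


def read_ld_table(path: str | Path) -> LDTable:
    """Read LD pairs; order of the two SNP columns is irrelevant (canonicalized)."""
    pairs = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != ("snp_a", "snp_b", "r2"):
            raise ParseError(f"{path}:1: expected header (snp_a, snp_b, r2)")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) != 3:
                raise ParseError(f"{path}:{lineno}: expected 3 fields")
            pairs.append(LDPair(f[0], f[1], float(f[2])))
    return LDTable(pairs)


# ---------------------------------------------------------------------------
# expression, interactions, orthologs
# ---------------------------------------------------------------------------


def write_expression(expr: ExpressionMatrix, values_path: str | Path,
                     detection_path: str | Path, groups_path: str | Path) -> None:
    expr.values.to_csv(values_path, sep="\t", index_label="gene_id")
    expr.detection_p.to_csv(detection_path, sep="\t", index_label="gene_id")
    expr.sample_groups.rename("group").to_csv(groups_path, sep="\t", index_label="sample")


def read_expression(values_path: str | Path, detection_path: str | Path,
                    groups_path: str | Path) -> ExpressionMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col="gene_id")
    detection = pd.read_csv(detection_path, sep="\t", index_col="gene_id")
    groups = pd.read_csv(groups_path, sep="\t", index_col="sample")["group"]
    return ExpressionMatrix(values, detection, groups)


def write_interactions(table: InteractionTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_a\tprotein_b\n")
        for a, b in table:
            fh.write(f"{a}\t{b}\n")


def read_interactions(path: str | Path) -> InteractionTable:
    pairs = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != ("protein_a", "protein_b"):
            raise ParseError(f"{path}:1: expected header (protein_a, protein_b)")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 fields")
            pairs.append((f[0], f[1]))
    return InteractionTable(pairs)


def read_ortholog_map(path: str | Path) -> dict[str, str]:
    """Read a gene -> protein ortholog mapping (TSV: gene_id, protein_id)."""
    out: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != ("gene_id", "protein_id"):
            raise ParseError(f"{path}:1: expected header (gene_id, protein_id)")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            gene, protein = line.split("\t")
            out[gene] = protein
    return out
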