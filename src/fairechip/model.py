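"""Domain types for tiling-array open-chromatin analysis.

All genomic coordinates are stored 0-based half-open internally; conversion
to/from 1-based inclusive happens only at I/O boundaries (see :mod:`fairechip.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "ProbeTrack",
    "PeakRecord",
    "PeakSet",
    "GeneModel",
    "SNPRecord",
    "LDPair",
    "ExpressionMatrix",
    "InteractionTable",
]

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``[start, end)``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not self.start < self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: start must be < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two half-open intervals share >= 1 bp on the same chromosome."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, chrom: str, pos: int) -> bool:
        """Half-open containment: ``start <= pos < end``."""
        return chrom == self.chrom and self.start <= pos < self.end


@dataclass
class ProbeTrack:
    """Probes of one chromosome of a two-channel tiling array.

    ``ratios`` maps a condition label (e.g. a formaldehyde cross-linking
    time such as ``"8min"``) to the per-probe log2(FAIRE/input) values.
    ``scaled`` records which conditions have been centred by the Tukey
    biweight location (a prerequisite for peak calling).
    """

    chrom: str
    starts: np.ndarray
    lengths: np.ndarray
    ratios: dict[str, np.ndarray] = field(default_factory=dict)
    scaled: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.lengths = np.asarray(self.lengths, dtype=np.int64)
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.starts.shape != self.lengths.shape:
            raise ValueError("starts and lengths must have equal length")
        if self.starts.size and not np.all(np.diff(self.starts) > 0):
            raise ValueError(f"probe starts on {self.chrom} must be strictly ascending")
        for label, values in self.ratios.items():
            values = np.asarray(values, dtype=float)
            if values.shape != self.starts.shape:
                raise ValueError(f"ratio array for {label!r} has wrong length")
            if not np.all(np.isfinite(values)):
                raise ValueError(f"non-finite log2 ratio in condition {label!r}")
            self.ratios[label] = values

    @property
    def n_probes(self) -> int:
        return int(self.starts.size)

    @property
    def ends(self) -> np.ndarray:
        return self.starts + self.lengths

    def with_ratios(self, condition: str, values: np.ndarray, scaled: bool = False) -> "ProbeTrack":
        ratios = dict(self.ratios)
        ratios[condition] = np.asarray(values, dtype=float)
        flags = set(self.scaled)
        if scaled:
            flags.add(condition)
        else:
            flags.discard(condition)
        return ProbeTrack(self.chrom, self.starts, self.lengths, ratios, flags)


@dataclass(frozen=True)
class PeakRecord:
    """A called nucleosome-depleted region (NDR).

    ``score_pct`` is the highest percentage of the hypothetical maximum at
    which any part of the peak was detected; ``n_probes`` the above-cutoff
    probe count of that detection.
    """

    interval: GenomicInterval
    score_pct: float
    n_probes: int
    source: str = ""

    def __post_init__(self) -> None:
        if not 0 < self.score_pct <= 100:
            raise ValueError(f"score_pct must be in (0, 100], got {self.score_pct}")
        if self.n_probes < 1:
            raise ValueError("n_probes must be >= 1")


class PeakSet:
    """A sorted collection of :class:`PeakRecord`, BED/GFF3-serializable."""

    def __init__(self, records: Iterable[PeakRecord] = ()):
        self.records: list[PeakRecord] = sorted(
            records, key=lambda r: (r.interval.chrom, r.interval.start, r.interval.end)
        )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PeakRecord]:
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, PeakSet) and self.records == other.records

    def intervals(self) -> list[GenomicInterval]:
        return [r.interval for r in self.records]

    def by_chrom(self) -> dict[str, list[PeakRecord]]:
        out: dict[str, list[PeakRecord]] = {}
        for rec in self.records:
            out.setdefault(rec.interval.chrom, []).append(rec)
        return out

    def total_span_bp(self) -> int:
        return sum(len(r.interval) for r in self.records)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [r.interval.chrom for r in self.records],
                "start": [r.interval.start for r in self.records],
                "end": [r.interval.end for r in self.records],
                "score_pct": [r.score_pct for r in self.records],
                "n_probes": [r.n_probes for r in self.records],
                "source": [r.source for r in self.records],
            }
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene with TSS, exon and UTR structure plus an optional lineage label.

    ``lineage_label`` marks lineage-specific reference genes: MK
    (megakaryocyte), EB (erythroblast) or MONO (monocyte).
    """

    gene_id: str
    interval: GenomicInterval
    strand: str
    tss: int
    exons: tuple[GenomicInterval, ...] = ()
    utr5: Optional[GenomicInterval] = None
    utr3: Optional[GenomicInterval] = None
    lineage_label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("gene strand must be + or -")
        if not self.interval.start <= self.tss <= self.interval.end:
            raise ValueError(f"TSS {self.tss} outside gene interval for {self.gene_id}")
        exons = sorted(self.exons, key=lambda e: e.start)
        for exon in exons:
            if exon.start < self.interval.start or exon.end > self.interval.end:
                raise ValueError(f"exon outside gene interval for {self.gene_id}")
        for a, b in zip(exons, exons[1:]):
            if b.start < a.end:
                raise ValueError(f"overlapping exons in {self.gene_id}")
        object.__setattr__(self, "exons", tuple(exons))
        if self.lineage_label is not None and self.lineage_label not in ("MK", "EB", "MONO"):
            raise ValueError(f"unknown lineage label {self.lineage_label!r}")


@dataclass(frozen=True)
class SNPRecord:
    """A biallelic SNP; position is 0-based internally (1-based in I/O)."""

    snp_id: str
    chrom: str
    pos: int
    alleles: tuple[str, str] = ("A", "G")
    maf: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf <= 0.5:
            raise ValueError(f"MAF must be in [0, 0.5], got {self.maf}")
        if self.pos < 0:
            raise ValueError("position must be non-negative")


@dataclass(frozen=True)
class LDPair:
    """Pairwise linkage disequilibrium between two SNPs, canonical order."""

    snp_a: str
    snp_b: str
    r2: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.r2 <= 1.0:
            raise ValueError(f"r2 must be in [0, 1], got {self.r2}")
        if self.snp_a > self.snp_b:
            a, b = self.snp_b, self.snp_a
            object.__setattr__(self, "snp_a", a)
            object.__setattr__(self, "snp_b", b)


class LDTable:
    """Symmetric lookup of r-squared values, built from canonical pairs."""

    def __init__(self, pairs: Iterable[LDPair] = ()):
        self._r2: dict[tuple[str, str], float] = {}
        for p in pairs:
            self._r2[(p.snp_a, p.snp_b)] = p.r2

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        key = (a, b) if a < b else (b, a)
        return self._r2.get(key, 0.0)

    def partners(self, snp_id: str) -> dict[str, float]:
        out: dict[str, float] = {}
        for (a, b), r2 in self._r2.items():
            if a == snp_id:
                out[b] = r2
            elif b == snp_id:
                out[a] = r2
        return out

    def pairs(self) -> list[LDPair]:
        return [LDPair(a, b, r2) for (a, b), r2 in sorted(self._r2.items())]

    def __len__(self) -> int:
        return len(self._r2)


@dataclass
class ExpressionMatrix:
    """Log2-scale expression values with per-cell detection P-values.

    ``values``: genes x samples DataFrame (assumed normalized, log2 scale).
    ``detection_p``: same shape; probability the probe signal is background.
    ``sample_groups``: group label per sample (e.g. KO / WT, or a cell type).
    """

    values: pd.DataFrame
    detection_p: pd.DataFrame
    sample_groups: pd.Series

    def __post_init__(self) -> None:
        if not self.values.columns.equals(self.detection_p.columns) or not self.values.index.equals(
            self.detection_p.index
        ):
            raise ValueError("values and detection_p must share index and columns")
        if not set(self.values.columns) <= set(self.sample_groups.index):
            raise ValueError("every sample needs a group label")
        if self.sample_groups.loc[list(self.values.columns)].isna().any():
            raise ValueError("missing group labels")
        dp = self.detection_p.to_numpy()
        if np.any((dp < 0) | (dp > 1)):
            raise ValueError("detection_p must lie in [0, 1]")

    def samples_in_group(self, group: str) -> list[str]:
        labels = self.sample_groups.loc[list(self.values.columns)]
        return [s for s in self.values.columns if labels[s] == group]


class InteractionTable:
    """Deduplicated unordered protein-id pairs (no self-interactions)."""

    def __init__(self, pairs: Iterable[tuple[str, str]] = ()):
        seen: set[tuple[str, str]] = set()
        for a, b in pairs:
            if a == b:
                continue
            seen.add((a, b) if a < b else (b, a))
        self.pairs: list[tuple[str, str]] = sorted(seen)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.pairs)

    def proteins(self) -> set[str]:
        out: set[str] = set()
        for a, b in self.pairs:
            out.add(a)
            out.add(b)
        return out
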