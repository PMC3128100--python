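"""Cross-condition merging and cross-cell-type comparison of peak sets.

Two peak sets from the same cell type (different formaldehyde cross-linking
times) are reduced to their concordant regions; two condition-merged sets
from different cell types are classified into shared and cell-specific
open-chromatin regions, counting shared regions as connected components of
the overlap graph so that a single count is valid from either side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import GenomicInterval, PeakRecord, PeakSet

__all__ = [
    "merge_conditions",
    "concordance_rate",
    "ComparisonReport",
    "compare_cell_types",
    "peak_density",
]


def _components(peaks_a: PeakSet, peaks_b: PeakSet):
    """Connected components of the cross-set overlap graph.

    Yields (members_a, members_b) index lists per component. Within-set
    peaks are assumed non-overlapping (caller output), so components can
    be found with a single coordinate sweep per chromosome.
    """
    by_chrom_a = {}
    for i, rec in enumerate(peaks_a):
        by_chrom_a.setdefault(rec.interval.chrom, []).append(i)
    by_chrom_b = {}
    for j, rec in enumerate(peaks_b):
        by_chrom_b.setdefault(rec.interval.chrom, []).append(j)
    for chrom in sorted(set(by_chrom_a) | set(by_chrom_b)):
        events = [
            (peaks_a[i].interval.start, peaks_a[i].interval.end, "a", i)
            for i in by_chrom_a.get(chrom, [])
        ] + [
            (peaks_b[j].interval.start, peaks_b[j].interval.end, "b", j)
            for j in by_chrom_b.get(chrom, [])
        ]
        events.sort()
        comp: list[tuple[str, int]] = []
        comp_end = None
        for start, end, side, idx in events:
            if comp and start < comp_end:
                comp.append((side, idx))
                comp_end = max(comp_end, end)
            else:
                if comp:
                    yield comp
                comp = [(side, idx)]
                comp_end = end
        if comp:
            yield comp


def merge_conditions(peaks_x: PeakSet, peaks_y: PeakSet, source: str = "") -> PeakSet:
    """Concordant regions across two cross-linking conditions.

    One output interval per connected component of cross-set overlaps
    (>= 1 bp) containing at least one peak from EACH condition: the union
    span of the component, scored with the maximum member ``score_pct``.
    Commutative and, applied to its own output on both sides, idempotent.
    """
    records = []
    for comp in _components(peaks_x, peaks_y):
        sides = {side for side, _ in comp}
        if sides != {"a", "b"}:
            continue
        members = [peaks_x[i] if side == "a" else peaks_y[i] for side, i in comp]
        start = min(m.interval.start for m in members)
        end = max(m.interval.end for m in members)
        chrom = members[0].interval.chrom
        score = max(m.score_pct for m in members)
        n_probes = max(m.n_probes for m in members)
        records.append(
            PeakRecord(GenomicInterval(chrom, start, end), score, n_probes, source)
        )
    return PeakSet(records)


def concordance_rate(peaks_a: PeakSet, peaks_b: PeakSet) -> tuple[float, float]:
    """Percentage of peaks in each set overlapping >= 1 peak of the other.

    Returns ``(pct_a, pct_b)``; raises on an empty input set (the rate is
    undefined).
    """
    if len(peaks_a) == 0 or len(peaks_b) == 0:
        raise ValueError("concordance_rate: empty peak set")
    hit_a: set[int] = set()
    hit_b: set[int] = set()
    for comp in _components(peaks_a, peaks_b):
        sides = {side for side, _ in comp}
        if sides == {"a", "b"}:
            for side, idx in comp:
                (hit_a if side == "a" else hit_b).add(idx)
    return (100.0 * len(hit_a) / len(peaks_a), 100.0 * len(hit_b) / len(peaks_b))


@dataclass
class ComparisonReport:
    """Shared / cell-specific classification of two condition-merged peak sets."""

    n_a: int
    n_b: int
    n_shared: int
    frac_a_shared: float
    frac_b_shared: float
    class_a: list[str] = field(default_factory=list)
    class_b: list[str] = field(default_factory=list)


def compare_cell_types(peaks_a: PeakSet, peaks_b: PeakSet) -> ComparisonReport:
    """Classify peaks of two cell types as shared or cell-specific.

    A peak is "shared" iff it overlaps (>= 1 bp) a peak of the other set;
    ``n_shared`` counts shared REGIONS as connected components spanning
    both sets, so a single number is valid from either side. The reported
    fractions are ``100 * n_shared / n_side``, rounded to 1 decimal.
    """
    shared_a: set[int] = set()
    shared_b: set[int] = set()
    n_shared = 0
    for comp in _components(peaks_a, peaks_b):
        sides = {side for side, _ in comp}
        if sides == {"a", "b"}:
            n_shared += 1
            for side, idx in comp:
                (shared_a if side == "a" else shared_b).add(idx)
    class_a = ["shared" if i in shared_a else "a_only" for i in range(len(peaks_a))]
    class_b = ["shared" if j in shared_b else "b_only" for j in range(len(peaks_b))]
    frac_a = round(100.0 * n_shared / len(peaks_a), 1) if len(peaks_a) else 0.0
    frac_b = round(100.0 * n_shared / len(peaks_b), 1) if len(peaks_b) else 0.0
    return ComparisonReport(len(peaks_a), len(peaks_b), n_shared, frac_a, frac_b,
                            class_a, class_b)


def peak_density(peaks: PeakSet, footprint_bp: float) -> float:
    """Peaks per megabase of interrogated sequence."""
    if footprint_bp <= 0:
        raise ValueError("footprint must be positive")
    return len(peaks) / (footprint_bp / 1e6)
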