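"""Channel scaling and sliding-window NDR detection on tiling-array log2 ratios.

The caller mirrors the vendor-style two-step procedure used for FAIRE-chip
data: (1) log2(FAIRE/input) ratios are centred array-wide by subtracting
their Tukey biweight location; (2) per chromosome, a descending series of
cutoffs is taken as percentages of a hypothetical maximum (mean + 6 SD of
the scaled ratios) and, at each cutoff, 300-bp windows anchored at probe
starts qualify when at least ``min_probes`` probes inside exceed the
cutoff. Qualifying windows are merged, runs of more than ``gap_probes``
consecutive below-cutoff probes split a merged region, and the final peak
set is the union over all cutoffs, each peak annotated with the highest
percentage at which any part of it was detected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .config import PeakCallParams
from .model import GenomicInterval, PeakRecord, PeakSet, ProbeTrack

__all__ = [
    "tukey_biweight_location",
    "scale_tracks",
    "CutoffSeries",
    "make_cutoff_series",
    "call_peaks",
]


def tukey_biweight_location(values, c: float = 5.0, tol: float = 1e-6,
                            max_iter: int = 50) -> float:
    """Tukey biweight (bisquare) location estimate.

    Iteratively reweighted mean with weights ``w = (1 - u**2)**2`` for
    ``|u| < 1`` and 0 otherwise, where ``u = (x - m) / (c * MAD)``; started
    at the median and iterated to ``tol`` or ``max_iter``. A zero MAD
    (more than half the data identical) returns the median.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("tukey_biweight_location: empty input")
    if not np.all(np.isfinite(x)):
        raise ValueError("tukey_biweight_location: non-finite values")
    m = float(np.median(x))
    mad = float(np.median(np.abs(x - m)))
    if mad == 0.0:
        return m
    scale = c * mad
    for _ in range(max_iter):
        u = (x - m) / scale
        w = np.zeros_like(x)
        inlier = np.abs(u) < 1.0
        w[inlier] = (1.0 - u[inlier] ** 2) ** 2
        total = w.sum()
        if total == 0.0:  # all points rejected; keep current estimate
            break
        m_new = float((w * x).sum() / total)
        if abs(m_new - m) < tol:
            return m_new
        m = m_new
    return m


def scale_tracks(tracks: Sequence[ProbeTrack], condition: str,
                 c: float = 5.0) -> list[ProbeTrack]:
    """Centre one condition's log2 ratios by their array-wide biweight location.

    The location is estimated over ALL probes of the condition (across
    chromosomes, matching between-channel scaling of a whole array), then
    subtracted from every ratio. Output tracks carry the ``scaled`` flag
    for the condition.
    """
    if not tracks:
        raise ValueError("scale_tracks: no tracks")
    pooled = np.concatenate([t.ratios[condition] for t in tracks])
    if pooled.size == 0:
        raise ValueError("scale_tracks: condition has no probes")
    center = tukey_biweight_location(pooled, c=c)
    return [
        t.with_ratios(condition, t.ratios[condition] - center, scaled=True)
        for t in tracks
    ]


@dataclass(frozen=True)
class CutoffSeries:
    """Descending cutoff series for one chromosome.

    ``percentages`` runs from ``p_start`` down to ``p_end`` in steps of
    ``p_step``; ``absolute_cutoffs[k] = percentages[k] / 100 * hypothetical_max``.
    """

    hypothetical_max: float
    percentages: tuple[float, ...]
    absolute_cutoffs: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.percentages) < 1:
            raise ValueError("cutoff series must be non-empty")
        if any(b >= a for a, b in zip(self.percentages, self.percentages[1:])):
            raise ValueError("percentages must be strictly descending")
        if not np.all(np.isfinite(self.absolute_cutoffs)):
            raise ValueError("non-finite cutoff")

    def __len__(self) -> int:
        return len(self.percentages)


def make_cutoff_series(scaled_values, params: PeakCallParams) -> CutoffSeries:
    """Cutoff series for one chromosome's scaled log2 ratios.

    The hypothetical maximum is ``mean + sd_mult * SD`` (sample SD) of the
    chromosome's scaled ratios. ``params.max_steps``, when set, truncates
    the series to its first ``max_steps`` entries (highest cutoffs kept).
    """
    x = np.asarray(scaled_values, dtype=float)
    if x.size < 2:
        raise ValueError("make_cutoff_series: need >= 2 probes per chromosome")
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        raise ValueError("degenerate chromosome: zero standard deviation")
    hyp_max = float(np.mean(x)) + params.sd_mult * sd
    n_steps = int(np.floor((params.p_start - params.p_end) / params.p_step + 1e-9)) + 1
    pcts = tuple(params.p_start - k * params.p_step for k in range(n_steps))
    if params.max_steps is not None:
        pcts = pcts[: params.max_steps]
    cutoffs = tuple(p / 100.0 * hyp_max for p in pcts)
    return CutoffSeries(hyp_max, pcts, cutoffs)


def _peaks_at_cutoff(starts: np.ndarray, ends: np.ndarray, above: np.ndarray,
                     params: PeakCallParams) -> list[tuple[int, int, int]]:
    """Peaks (start, end, n_above) at a single absolute cutoff.

    A window ``[s_j, s_j + window_bp)`` anchored at probe j qualifies when
    >= ``min_probes`` above-cutoff probes start inside it; overlapping
    qualifying windows merge; inside a merged region more than
    ``gap_probes`` consecutive below-cutoff probes split it; each segment
    is trimmed to its above-cutoff probes and kept if it still holds
    >= ``min_probes`` of them.
    """
    n = starts.size
    if n == 0 or not above.any():
        return []
    win = params.window_bp
    # above-count per window via prefix sums over probes ordered by start
    cum = np.concatenate(([0], np.cumsum(above)))
    hi = np.searchsorted(starts, starts + win, side="left")
    counts = cum[hi] - cum[np.arange(n)]
    qualified = np.flatnonzero(counts >= params.min_probes)
    if qualified.size == 0:
        return []
    # merge overlapping qualifying windows into regions [rs, re)
    q_starts = starts[qualified]
    q_ends = q_starts + win
    breaks = np.flatnonzero(q_starts[1:] >= np.maximum.accumulate(q_ends[:-1]))
    region_bounds = np.concatenate(([0], breaks + 1, [qualified.size]))
    peaks: list[tuple[int, int, int]] = []
    above_idx = np.flatnonzero(above)
    for b0, b1 in zip(region_bounds[:-1], region_bounds[1:]):
        rs = int(q_starts[b0])
        re_ = int(q_ends[b0:b1].max())
        # above-cutoff probes whose start lies in the region (contiguous indices)
        lo = np.searchsorted(above_idx, np.searchsorted(starts, rs, side="left"))
        hi_a = np.searchsorted(above_idx, np.searchsorted(starts, re_, side="left"))
        members = above_idx[lo:hi_a]
        if members.size == 0:
            continue
        # split where more than gap_probes consecutive below-cutoff probes intervene
        gaps = np.diff(members) - 1
        cut_at = np.flatnonzero(gaps > params.gap_probes)
        seg_bounds = np.concatenate(([0], cut_at + 1, [members.size]))
        for s0, s1 in zip(seg_bounds[:-1], seg_bounds[1:]):
            seg = members[s0:s1]
            if seg.size >= params.min_probes:
                peaks.append((int(starts[seg[0]]), int(ends[seg[-1]]), int(seg.size)))
    return peaks


def _union_scored(scored: list[tuple[int, int, float, int]]) -> list[tuple[int, int, float, int]]:
    """Merge overlapping (start, end, pct, n_above) peaks from all cutoffs.

    The merged interval is the union span; its score is the highest
    contributing percentage (ties broken toward the larger probe count).
    """
    if not scored:
        return []
    scored = sorted(scored)
    merged: list[list] = []
    for s, e, pct, n in scored:
        if merged and s < merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
            if (pct, n) > (merged[-1][2], merged[-1][3]):
                merged[-1][2], merged[-1][3] = pct, n
        else:
            merged.append([s, e, pct, n])
    return [tuple(m) for m in merged]


def call_peaks(tracks: Sequence[ProbeTrack], condition: str,
               params: PeakCallParams, source: str = "") -> PeakSet:
    """Call NDRs on scaled tracks using the iterative-threshold sliding window.

    Raises if the condition has not been scaled (``params.require_scaled``).
    Output peaks are sorted and non-overlapping; each carries ``score_pct``
    (highest detection percentage) and the above-cutoff probe count of that
    detection.
    """
    records: list[PeakRecord] = []
    for track in tracks:
        if params.require_scaled and condition not in track.scaled:
            raise ValueError(
                f"track {track.chrom} condition {condition!r} is not scaled; "
                "run scale_tracks first (or set require_scaled=False)"
            )
        ratios = track.ratios[condition]
        series = make_cutoff_series(ratios, params)
        starts, ends = track.starts, track.ends
        scored: list[tuple[int, int, float, int]] = []
        for pct, cut in zip(series.percentages, series.absolute_cutoffs):
            above = ratios > cut
            for s, e, n in _peaks_at_cutoff(starts, ends, above, params):
                scored.append((s, e, pct, n))
        for s, e, pct, n in _union_scored(scored):
            records.append(
                PeakRecord(GenomicInterval(track.chrom, s, e), pct, n, source or condition)
            )
    return PeakSet(records)
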