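"""Independent reference implementations used as test oracles.

These deliberately use brute-force or textbook formulations (exhaustive
enumeration, O(n^2) scans, fixed-point iteration written from the estimator
definition) so that agreement with the package's optimized implementations
is meaningful.
"""

from __future__ import annotations

from itertools import combinations

import networkx as nx
import numpy as np


def biweight_location_fixed_point(values, c=5.0, tol=1e-9, max_iter=500):
    """Tukey biweight location via plain fixed-point iteration on the
    weighted-mean equation, written directly from the estimator definition."""
    x = np.asarray(values, dtype=float)
    m = np.median(x)
    mad = np.median(np.abs(x - np.median(x)))
    if mad == 0:
        return float(np.median(x))
    for _ in range(max_iter):
        u = (x - m) / (c * mad)
        mask = np.abs(u) < 1
        w = np.zeros_like(x)
        w[mask] = (1 - u[mask] ** 2) ** 2
        m_next = np.sum(w * x) / np.sum(w)
        if abs(m_next - m) < tol:
            return float(m_next)
        m = m_next
    return float(m)


def brute_force_call_peaks(starts, lengths, ratios, params, percentages, cutoffs):
    """Exhaustive window/cutoff peak enumeration.

    For each cutoff: test every probe-anchored window by explicit
    membership comparison, merge overlapping qualifying windows by linear
    scan, split merged regions at runs of more than ``gap_probes``
    below-cutoff probes, trim to above-cutoff probes, keep segments with
    >= ``min_probes``. Returns the merged union over all cutoffs as
    (start, end, score_pct, n_probes) tuples.
    """
    starts = np.asarray(starts)
    lengths = np.asarray(lengths)
    ratios = np.asarray(ratios, dtype=float)
    n = starts.size
    win = params.window_bp
    in_window = (
        (starts[None, :] >= starts[:, None]) & (starts[None, :] < starts[:, None] + win)
    ).astype(np.int64)

    all_peaks = []
    for pct, cut in zip(percentages, cutoffs):
        above = ratios > cut
        counts = in_window @ above.astype(np.int64)
        qualified = [j for j in range(n) if counts[j] >= params.min_probes]
        if not qualified:
            continue
        regions = []
        for j in qualified:
            lo, hi = int(starts[j]), int(starts[j]) + win
            if regions and lo < regions[-1][1]:
                regions[-1][1] = max(regions[-1][1], hi)
            else:
                regions.append([lo, hi])
        for rs, re_ in regions:
            members = [i for i in range(n) if rs <= starts[i] < re_]
            above_members = [i for i in members if above[i]]
            if not above_members:
                continue
            groups = [[above_members[0]]]
            for prev, nxt in zip(above_members, above_members[1:]):
                if nxt - prev - 1 <= params.gap_probes:
                    groups[-1].append(nxt)
                else:
                    groups.append([nxt])
            for g in groups:
                if len(g) >= params.min_probes:
                    all_peaks.append(
                        (int(starts[g[0]]), int(starts[g[-1]] + lengths[g[-1]]), pct, len(g))
                    )

    merged = []
    for s, e, pct, cnt in sorted(all_peaks):
        if merged and s < merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
            if (pct, cnt) > (merged[-1][2], merged[-1][3]):
                merged[-1][2], merged[-1][3] = pct, cnt
        else:
            merged.append([s, e, pct, cnt])
    return [tuple(m) for m in merged]


def overlap_components(intervals_a, intervals_b):
    """Connected components of the bipartite-plus overlap graph via networkx.

    Returns a list of (set_of_a_indices, set_of_b_indices).
    """
    g = nx.Graph()
    g.add_nodes_from(("a", i) for i in range(len(intervals_a)))
    g.add_nodes_from(("b", j) for j in range(len(intervals_b)))
    every = [("a", i, iv) for i, iv in enumerate(intervals_a)] + [
        ("b", j, iv) for j, iv in enumerate(intervals_b)
    ]
    for (sa, ia, va), (sb, ib, vb) in combinations(every, 2):
        if va.chrom == vb.chrom and va.start < vb.end and vb.start < va.end:
            g.add_edge((sa, ia), (sb, ib))
    out = []
    for comp in nx.connected_components(g):
        out.append(
            (
                {i for side, i in comp if side == "a"},
                {j for side, j in comp if side == "b"},
            )
        )
    return out


def nearest_tss_exhaustive(peak_mid, chrom, genes):
    """Nearest TSS by scanning all genes; ties to smaller gene id."""
    best = None
    for gene in genes:
        if gene.interval.chrom != chrom:
            continue
        signed = peak_mid - gene.tss if gene.strand == "+" else gene.tss - peak_mid
        key = (abs(signed), gene.gene_id, signed)
        if best is None or key < best:
            best = key
    return (best[1], best[2]) if best else None


def hypergeom_upper_tail_enumeration(n_universe, n_set, n_hits, k_obs):
    """P[X >= k] for the hypergeometric by exhaustive enumeration of draws."""
    from math import comb

    total = comb(n_universe, n_hits)
    count = 0
    for k in range(k_obs, min(n_set, n_hits) + 1):
        count += comb(n_set, k) * comb(n_universe - n_set, n_hits - k)
    return count / total


def bfs_largest_component(nodes, edges):
    """Largest connected component by hand-rolled breadth-first search;
    ties resolved by edge count then lexicographically smallest node set."""
    adj = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    seen = set()
    best = None
    best_key = None
    for start in sorted(nodes):
        if start in seen:
            continue
        comp = {start}
        queue = [start]
        while queue:
            node = queue.pop()
            for nb in adj[node]:
                if nb not in comp:
                    comp.add(nb)
                    queue.append(nb)
        seen |= comp
        n_edges = sum(1 for a, b in edges if a in comp and b in comp)
        key = (len(comp), n_edges)
        if best is None or key > best_key or (key == best_key and sorted(comp) < sorted(best)):
            best, best_key = comp, key
    return best or set()
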