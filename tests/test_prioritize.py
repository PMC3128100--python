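"""LD-proxy expansion, SNP-in-NDR intersection and the exact rank-sum test."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fairechip.model import GenomicInterval, LDPair, LDTable, PeakRecord, PeakSet, SNPRecord
from fairechip.prioritize import (
    annotate_motif_overlap,
    expand_proxies,
    intersect_snps_ndrs,
    lineage_peak_density,
    lineage_enrichment_test,
    report_table,
)
from fairechip.ranktest import rank_sum_test
from fairechip.simulate import simulate_locus_panel


def snp(snp_id, pos, chrom="chr1", maf=0.3):
    return SNPRecord(snp_id, chrom, pos, maf=maf)


class TestExpandProxies:
    def test_lone_index_maps_to_itself_at_r2_one(self):
        snps = {"rs1": snp("rs1", 100)}
        out = expand_proxies(["rs1"], LDTable(), snps)
        assert out == {"rs1": [("rs1", 1.0)]}

    def test_r2_and_maf_boundaries(self):
        snps = {
            "rsI": snp("rsI", 100),
            "rsA": snp("rsA", 500, maf=0.3),
            "rsB": snp("rsB", 900, maf=0.3),
            "rsC": snp("rsC", 1300, maf=0.04),
        }
        ld = LDTable([LDPair("rsI", "rsA", 0.80), LDPair("rsI", "rsB", 0.79),
                      LDPair("rsI", "rsC", 0.95)])
        out = expand_proxies(["rsI"], ld, snps, r2_min=0.8, maf_min=0.05)
        ids = [s for s, _ in out["rsI"]]
        assert ids == ["rsI", "rsA"]  # 0.79 excluded; low-MAF excluded

    def test_unknown_index_is_named_in_error(self):
        with pytest.raises(KeyError, match="rsMissing"):
            expand_proxies(["rsMissing"], LDTable(), {})

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_filter(self, seed):
        rng = np.random.default_rng(seed)
        snps = {f"rs{i}": snp(f"rs{i}", 100 * i, maf=float(rng.uniform(0, 0.5)))
                for i in range(30)}
        pairs = [LDPair("rs0", f"rs{i}", float(rng.uniform(0, 1))) for i in range(1, 30)]
        ld = LDTable(pairs)
        out = expand_proxies(["rs0"], ld, snps)["rs0"]
        expected = [("rs0", 1.0)] + sorted(
            (p.snp_b if p.snp_a == "rs0" else p.snp_a, p.r2)
            for p in pairs
            if p.r2 >= 0.8 and snps[p.snp_b if p.snp_a == "rs0" else p.snp_a].maf >= 0.05
        )
        assert out == expected

    def test_monotone_in_thresholds(self, rng):
        snps = {f"rs{i}": snp(f"rs{i}", 100 * i, maf=float(rng.uniform(0, 0.5)))
                for i in range(40)}
        ld = LDTable([LDPair("rs0", f"rs{i}", float(rng.uniform(0, 1)))
                      for i in range(1, 40)])
        prev = None
        for r2_min in (0.5, 0.7, 0.9):
            ids = {s for s, _ in expand_proxies(["rs0"], ld, snps, r2_min=r2_min)["rs0"]}
            if prev is not None:
                assert ids <= prev
            prev = ids
            assert "rs0" in ids


def table2_fixture():
    """Seven loci mirroring the printed cell-type column: two NDRs open only
    in MK, one only in EB, four in both cell types, each holding one SNP."""
    specs = [  # (locus offset, cell types with an NDR over the SNP)
        (0, ("MK",)), (10_000, ("MK",)), (20_000, ("EB",)),
        (30_000, ("MK", "EB")), (40_000, ("MK", "EB")),
        (50_000, ("MK", "EB")), (60_000, ("MK", "EB")),
    ]
    snps, proxy_map = {}, {}
    peaks = {"MK": [], "EB": []}
    for k, (offset, cells) in enumerate(specs):
        sid = f"rs{k}"
        snps[sid] = snp(sid, offset + 250)
        proxy_map[sid] = [(sid, 1.0)]
        for ct in cells:
            peaks[ct].append(
                PeakRecord(GenomicInterval("chr1", offset + 100, offset + 500), 80.0, 5, ct)
            )
    return proxy_map, snps, {ct: PeakSet(p) for ct, p in peaks.items()}


class TestIntersectSnpsNdrs:
    def test_cell_specificity_counts_match_study_layout(self):
        proxy_map, snps, peaks = table2_fixture()
        variants = intersect_snps_ndrs(proxy_map, snps, peaks)
        by_class = {}
        for v in variants:
            by_class[v.cell_specificity] = by_class.get(v.cell_specificity, 0) + 1
        assert by_class == {"MK_only": 2, "EB_only": 1, "shared": 4}
        assert len(report_table(variants)) == 7

    def test_snp_at_peak_end_is_outside(self):
        peaks = {"MK": PeakSet([PeakRecord(GenomicInterval("chr1", 100, 500), 80.0, 5)])}
        snps = {"rs1": snp("rs1", 500), "rs2": snp("rs2", 499), "rs3": snp("rs3", 100)}
        proxy_map = {"rs1": [("rs1", 1.0), ("rs2", 0.9), ("rs3", 0.85)]}
        variants = intersect_snps_ndrs(proxy_map, snps, peaks)
        assert {v.snp.snp_id for v in variants} == {"rs2", "rs3"}

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_exhaustive_containment_oracle(self, seed):
        rng = np.random.default_rng(seed)
        starts = np.sort(rng.choice(np.arange(0, 100_000, 1_000), 30, replace=False))
        peak_set = PeakSet(
            PeakRecord(GenomicInterval("chr1", int(s), int(s + rng.integers(100, 900))),
                       50.0, 4) for s in starts
        )
        snps = {f"rs{i}": snp(f"rs{i}", int(rng.integers(0, 100_000))) for i in range(100)}
        proxy_map = {"rs0": [(f"rs{i}", 1.0) for i in range(100)]}
        hits = {v.snp.snp_id
                for v in intersect_snps_ndrs(proxy_map, snps, {"MK": peak_set})}
        expected = {
            sid for sid, rec in snps.items()
            if any(p.interval.start <= rec.pos < p.interval.end for p in peak_set)
        }
        assert hits == expected

    def test_every_variant_lies_in_its_harboring_peak(self):
        proxy_map, snps, peaks = table2_fixture()
        for v in intersect_snps_ndrs(proxy_map, snps, peaks):
            for ct, rec in v.harboring_peaks.items():
                assert rec.interval.contains_point(v.snp.chrom, v.snp.pos)


class TestLineagePeakDensity:
    def test_simple_arithmetic_and_empty(self, peaks_factory):
        _, genes = simulate_locus_panel(n_loci=1, locus_length_bp=210_000,
                                        genes_per_locus=1, seed=11)
        gene = genes[0]
        inside = [(gene.interval.chrom, gene.interval.start + 10, gene.interval.start + 200),
                  (gene.interval.chrom, gene.interval.end - 300, gene.interval.end - 50)]
        dens = lineage_peak_density(peaks_factory(inside), [gene])
        assert dens[gene.gene_id] == pytest.approx(2 / (len(gene.interval) / 1e6))
        from fairechip.model import PeakSet
        assert lineage_peak_density(PeakSet(), [gene])[gene.gene_id] == 0.0

    def test_flank_included_and_counts_match_oracle(self, rng, peaks_factory):
        _, genes = simulate_locus_panel(n_loci=3, locus_length_bp=60_000, seed=12)
        spots = sorted(int(s) for s in rng.choice(np.arange(0, 500_000, 700), 80, replace=False))
        peaks = peaks_factory([("chr1", s, s + 300) for s in spots])
        dens = lineage_peak_density(peaks, genes, flank_bp=2_000)
        for gene in genes:
            window = GenomicInterval(gene.interval.chrom, gene.interval.start - 2_000,
                                     gene.interval.end + 2_000)
            count = sum(1 for rec in peaks if rec.interval.overlaps(window))
            assert dens[gene.gene_id] == pytest.approx(count / (len(gene.interval) / 1e6))


class TestRankSumTest:
    def test_identical_samples_give_p_one(self):
        res = rank_sum_test([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert res.p_value == 1.0

    def test_complete_separation_two_vs_two(self):
        res = rank_sum_test([3.0, 4.0], [1.0, 2.0], alternative="greater")
        assert res.p_value == pytest.approx(1 / 6)

    def test_complete_separation_eight_vs_eight(self):
        x = list(range(9, 17))
        y = list(range(1, 9))
        res = rank_sum_test(x, y, alternative="greater")
        assert res.p_value == pytest.approx(1 / 12870)  # 1 / C(16, 8)

    @pytest.mark.parametrize("na,nb", [(2, 3), (4, 4), (5, 3), (6, 6)])
    def test_exact_p_matches_scipy_on_tie_free_data(self, na, nb):
        rng = np.random.default_rng(na * 10 + nb)
        for _ in range(20):
            x = rng.normal(size=na)
            y = rng.normal(0.5, size=nb)
            for alt, scipy_alt in (("two_sided", "two-sided"), ("greater", "greater"),
                                   ("less", "less")):
                ours = rank_sum_test(x, y, alternative=alt)
                ref = stats.mannwhitneyu(x, y, alternative=scipy_alt, method="exact")
                assert ours.method == "exact"
                assert ours.p_value == pytest.approx(ref.pvalue)
                assert ours.u_statistic == pytest.approx(ref.statistic)

    def test_ties_handled_by_midrank_enumeration(self):
        x, y = [1.0, 2.0, 2.0, 5.0], [2.0, 3.0, 3.0, 0.5]
        res = rank_sum_test(x, y, alternative="greater")
        # independent enumeration from the definition
        pooled = np.array(x + y)
        ranks = stats.rankdata(pooled)
        s_obs = ranks[:4].sum()
        sums = [sum(ranks[list(c)]) for c in combinations(range(8), 4)]
        expected = np.mean([s >= s_obs - 1e-9 for s in sums])
        assert res.p_value == pytest.approx(expected)

    def test_large_samples_use_normal_approximation(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(1.0, size=30)
        res = rank_sum_test(x, y, alternative="two_sided")
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert res.method == "normal"
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_lineage_enrichment_wrapper(self):
        dens_a = {f"g{i}": float(i + 10) for i in range(8)}
        dens_b = {f"g{i}": float(i) for i in range(8)}
        res = lineage_enrichment_test(dens_a, dens_b, alternative="greater")
        assert res.p_value < 0.01


class TestMotifOverlap:
    def test_ref_only_motif_flags_variant(self):
        proxy_map, snps, peaks = table2_fixture()
        variants = intersect_snps_ndrs(proxy_map, snps, peaks)
        motifs = pd.DataFrame(
            [
                {"motif_id": "EVI1", "chrom": "chr1", "start": 240, "end": 260,
                 "allele": "ref"},
                {"motif_id": "GATA1", "chrom": "chr1", "start": 0, "end": 1_000,
                 "allele": "ref"},
                {"motif_id": "GATA1", "chrom": "chr1", "start": 0, "end": 1_000,
                 "allele": "alt"},
            ]
        )
        annotate_motif_overlap(variants, motifs)
        flags = {v.snp.snp_id: v.motif_flags for v in variants}
        assert flags["rs0"] == ["EVI1"]  # present for ref allele only: disrupting
        assert all("GATA1" not in f for f in flags.values())  # both alleles: no change

    def test_without_motif_table_flags_stay_empty(self):
        proxy_map, snps, peaks = table2_fixture()
        variants = intersect_snps_ndrs(proxy_map, snps, peaks)
        annotate_motif_overlap(variants, None)
        assert all(v.motif_flags == [] for v in variants)
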