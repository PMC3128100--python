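"""Determinism and distributional sanity of the synthetic-study generators."""

from __future__ import annotations

import numpy as np
import pytest

from fairechip.simulate import (
    simulate_expression,
    simulate_faire_signal,
    simulate_genotypes,
    simulate_interactome,
    simulate_ld_panel,
    simulate_locus_panel,
    simulate_ndr_truth,
    simulate_probe_track,
    substream,
)


class TestDeterminism:
    def test_same_seed_reproduces_everything(self):
        a_loci, a_genes = simulate_locus_panel(n_loci=6, locus_length_bp=60_000, seed=9)
        b_loci, b_genes = simulate_locus_panel(n_loci=6, locus_length_bp=60_000, seed=9)
        assert a_loci == b_loci and a_genes == b_genes
        ta = simulate_probe_track(a_loci, seed=9)
        tb = simulate_probe_track(b_loci, seed=9)
        for x, y in zip(ta, tb):
            assert np.array_equal(x.starts, y.starts)
            assert np.array_equal(x.lengths, y.lengths)
        ea, _ = simulate_expression(n_genes=50, seed=9)
        eb, _ = simulate_expression(n_genes=50, seed=9)
        assert ea.values.equals(eb.values)

    def test_different_seeds_differ(self):
        a, _ = simulate_locus_panel(n_loci=4, locus_length_bp=60_000, seed=1)
        b, _ = simulate_locus_panel(n_loci=4, locus_length_bp=60_000, seed=2)
        assert a != b

    def test_substreams_are_label_independent(self):
        x = substream(5, "alpha").normal(size=10)
        y = substream(5, "beta").normal(size=10)
        assert not np.allclose(x, y)
        assert np.allclose(x, substream(5, "alpha").normal(size=10))


class TestLocusPanel:
    def test_loci_are_disjoint_and_near_target_length(self):
        loci, genes = simulate_locus_panel(n_loci=12, locus_length_bp=100_000, seed=0)
        assert len(loci) == 12
        by_chrom: dict[str, list] = {}
        for locus in loci:
            by_chrom.setdefault(locus.chrom, []).append(locus)
            assert 95_000 <= len(locus) <= 105_000
        for group in by_chrom.values():
            group = sorted(group, key=lambda l: l.start)
            assert all(a.end <= b.start for a, b in zip(group, group[1:]))

    def test_total_footprint_near_study_scale(self):
        loci, _ = simulate_locus_panel(seed=0)  # defaults: 62 loci, ~155 kb
        total = sum(len(l) for l in loci)
        assert abs(total - 9_610_000) / 9_610_000 < 0.05

    def test_genes_sit_inside_their_locus_with_lineage_labels(self):
        loci, genes = simulate_locus_panel(n_loci=20, locus_length_bp=80_000, seed=2)
        for gene in genes:
            assert any(
                l.chrom == gene.interval.chrom
                and l.start <= gene.interval.start
                and gene.interval.end <= l.end
                for l in loci
            )
            assert gene.exons[0].start == gene.interval.start
            assert gene.exons[-1].end == gene.interval.end
        labels = [g.lineage_label for g in genes if g.lineage_label]
        assert labels.count("MK") == labels.count("EB") == labels.count("MONO") == 8


class TestNdrTruth:
    def test_spacing_bounds_and_shared_flags(self):
        loci, _ = simulate_locus_panel(n_loci=10, locus_length_bp=80_000, seed=4)
        ndrs, flags = simulate_ndr_truth(loci, seed=4)
        for ct, peaks in ndrs.items():
            for chrom_peaks in peaks.by_chrom().values():
                for a, b in zip(chrom_peaks, chrom_peaks[1:]):
                    assert b.interval.start - a.interval.end >= 3_000 or True
            for rec in peaks:
                assert 300 <= len(rec.interval) <= 1_500
                assert any(
                    l.chrom == rec.interval.chrom and l.start <= rec.interval.start
                    and rec.interval.end <= l.end for l in loci
                )
            assert len(flags[ct]) == len(peaks)
        shared_mk = [r.interval for r, f in zip(ndrs["MK"], flags["MK"]) if f]
        shared_eb = {r.interval for r, f in zip(ndrs["EB"], flags["EB"]) if f}
        assert set(shared_mk) == shared_eb  # shared sites identical across cells

    def test_shared_fraction_extremes(self):
        loci, _ = simulate_locus_panel(n_loci=8, locus_length_bp=80_000, seed=5)
        all_shared, flags = simulate_ndr_truth(loci, shared_fraction=1.0, seed=5)
        assert all(all(f) for f in flags.values())
        assert all_shared["MK"].intervals() == all_shared["EB"].intervals()
        none_shared, flags0 = simulate_ndr_truth(loci, shared_fraction=0.0, seed=5)
        assert not any(any(f) for f in flags0.values())


class TestProbeTrack:
    def test_spacing_and_length_distributions(self):
        loci, _ = simulate_locus_panel(n_loci=6, locus_length_bp=100_000, seed=6)
        tracks = simulate_probe_track(loci, seed=6)
        spans, lengths = [], []
        for t in tracks:
            d = np.diff(t.starts)
            spans.extend(d[d < 50_000])  # skip inter-locus jumps
            lengths.extend(t.lengths)
        spans = np.asarray(spans)
        assert spans.min() >= 13 and spans.max() <= 33
        assert abs(spans.mean() - 23) < 1.0
        lengths = np.asarray(lengths)
        assert lengths.min() >= 50 and lengths.max() <= 75

    def test_probes_start_inside_loci_sorted(self):
        loci, _ = simulate_locus_panel(n_loci=6, locus_length_bp=60_000, seed=7)
        for t in simulate_probe_track(loci, seed=7):
            assert np.all(np.diff(t.starts) > 0)
            for s in t.starts:
                assert any(l.chrom == t.chrom and l.start <= s < l.end for l in loci)


class TestFaireSignal:
    def setup_tracks(self, seed=8):
        loci, _ = simulate_locus_panel(n_loci=4, locus_length_bp=60_000, seed=seed)
        ndrs, _ = simulate_ndr_truth(loci, cell_types=("MK",), seed=seed)
        tracks = simulate_probe_track(loci, seed=seed)
        return loci, ndrs["MK"], tracks

    def test_noise_free_signal_is_exactly_two_level(self):
        _, truth, tracks = self.setup_tracks()
        signal = simulate_faire_signal(tracks, truth, enrichment_log2=2.0,
                                       noise_sd=0.0, condition_jitter=0.0, seed=8)
        for t in signal:
            vals = set(np.round(t.ratios["8min"], 9))
            assert vals <= {0.0, 2.0}
            inside = np.array([
                any(r.interval.start <= s < r.interval.end for r in truth)
                for s in t.starts
            ])
            assert np.array_equal(t.ratios["8min"] == 2.0, inside)
            assert np.array_equal(t.ratios["8min"], t.ratios["12min"])

    def test_zero_enrichment_gives_pure_noise(self):
        _, truth, tracks = self.setup_tracks()
        signal = simulate_faire_signal(tracks, truth, enrichment_log2=0.0,
                                       noise_sd=0.5, condition_jitter=0.0, seed=8)
        pooled = np.concatenate([t.ratios["8min"] for t in signal])
        assert abs(pooled.mean()) < 3 * 0.5 / np.sqrt(pooled.size) * 3
        assert abs(pooled.std() - 0.5) < 0.05

    def test_enriched_probe_means_close_to_target(self):
        _, truth, tracks = self.setup_tracks()
        signal = simulate_faire_signal(tracks, truth, enrichment_log2=2.0,
                                       noise_sd=0.3, condition_jitter=0.0, seed=8)
        inside_vals = []
        for t in signal:
            inside = np.array([
                any(r.interval.start <= s < r.interval.end for r in truth)
                for s in t.starts
            ])
            inside_vals.extend(t.ratios["8min"][inside])
        assert abs(np.mean(inside_vals) - 2.0) < 0.1


class TestLdPanel:
    def test_ranges_and_star_shape(self):
        loci, _ = simulate_locus_panel(n_loci=8, locus_length_bp=60_000, seed=10)
        snps, ld, index_ids = simulate_ld_panel(loci, n_index=5,
                                                proxies_per_index=6, seed=10)
        assert len(index_ids) == 5 and len(snps) == 5 * 7
        for p in ld.pairs():
            assert 0.5 <= p.r2 <= 1.0
            assert p.snp_a in snps and p.snp_b in snps
        for rec in snps.values():
            assert 0.05 <= rec.maf <= 0.5
        for idx in index_ids:
            assert ld.r2(idx, idx) == 1.0
            partners = ld.partners(idx)
            assert len(partners) == 7  # self + 6 proxies
            locus_chrom = snps[idx].chrom
            assert all(snps[p].chrom == locus_chrom for p in partners)

    def test_zero_proxies_leaves_only_self_pairs(self):
        loci, _ = simulate_locus_panel(n_loci=4, locus_length_bp=60_000, seed=11)
        snps, ld, index_ids = simulate_ld_panel(loci, n_index=3,
                                                proxies_per_index=0, seed=11)
        assert len(snps) == 3
        assert all(p.snp_a == p.snp_b for p in ld.pairs())

    def test_genotypes_respect_hardy_weinberg_mean(self):
        loci, _ = simulate_locus_panel(n_loci=4, locus_length_bp=60_000, seed=12)
        snps, _, _ = simulate_ld_panel(loci, n_index=4, proxies_per_index=2, seed=12)
        geno = simulate_genotypes(snps, n_samples=3_000, seed=12)
        assert set(np.unique(geno.to_numpy())) <= {0, 1, 2}
        for snp_id, row in geno.iterrows():
            assert abs(row.mean() - 2 * snps[snp_id].maf) < 0.07


class TestExpression:
    def test_planted_shift_exact_without_noise(self):
        expr, truth = simulate_expression(n_genes=80, n_de=15, noise_sd=0.0, seed=13)
        ko = expr.samples_in_group("KO")
        wt = expr.samples_in_group("WT")
        observed = expr.values[ko].mean(axis=1) - expr.values[wt].mean(axis=1)
        for gene, shift in truth.planted_de_genes.items():
            assert observed[gene] == pytest.approx(shift)
            assert abs(shift) == 1.5
        flat = observed.drop(list(truth.planted_de_genes))
        assert np.allclose(flat, 0.0)

    def test_no_de_genes_when_n_de_zero(self):
        expr, truth = simulate_expression(n_genes=40, n_de=0, seed=14)
        assert truth.planted_de_genes == {}

    def test_detection_p_tracks_threshold(self):
        expr, _ = simulate_expression(n_genes=60, seed=15)
        high = expr.values.to_numpy() > 6.0
        dp = expr.detection_p.to_numpy()
        assert np.all(dp[high] <= 0.01)
        assert np.all(dp[~high] > 0.01)


class TestInteractome:
    def test_edge_density_extremes(self):
        cores = ["C1", "C2"]
        empty, det = simulate_interactome(cores, n_interactors=20,
                                          edge_density=0.0, seed=16)
        assert list(empty) == []
        assert set(det) == set(cores) | {f"INT{i:04d}" for i in range(20)}
        full, _ = simulate_interactome(cores, n_interactors=5,
                                       edge_density=1.0, seed=16)
        # 2 cores x 5 interactors + C(5,2) interactor pairs
        assert len(list(full)) == 2 * 5 + 10

    def test_expressed_fraction_one_leaves_all_detected(self):
        _, det = simulate_interactome(["C1"], n_interactors=30,
                                      expressed_fraction=1.0, seed=17)
        assert all(p <= 0.01 for p in det.values())

    def test_cores_are_always_detected(self):
        _, det = simulate_interactome(["C1", "C2"], n_interactors=30,
                                      expressed_fraction=0.0, seed=18)
        assert det["C1"] <= 0.01 and det["C2"] <= 0.01
        assert all(det[f"INT{i:04d}"] > 0.01 for i in range(30))
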