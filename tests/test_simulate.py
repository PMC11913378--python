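"""Generator determinism, planted ground truth and the contact-decay law."""

import numpy as np
import pytest

from tadboundary.core import GeneModel, overlaps
from tadboundary.peaks import p300_only_peaks
from tadboundary.simulate import (SimConfig, simulate_all, simulate_contacts,
                                  simulate_expression, simulate_genome,
                                  simulate_loops, simulate_peaks)
from tadboundary.topology import AnchorAnnotator, Tad, classify_loops


class TestDeterminism:
    def test_same_seed_same_bytes(self, tmp_path):
        cfg = SimConfig(seed=9, n_loops=50, n_genes=40)
        f1 = simulate_all(cfg, tmp_path / "a")
        f2 = simulate_all(cfg, tmp_path / "b")
        for name in f1:
            assert open(f1[name], "rb").read() == open(f2[name], "rb").read(), \
                f"{name} differs between identical-seed runs"

    def test_different_seed_differs(self, tmp_path):
        f1 = simulate_all(SimConfig(seed=1, n_loops=50), tmp_path / "a")
        f2 = simulate_all(SimConfig(seed=2, n_loops=50), tmp_path / "b")
        assert open(f1["tads"]).read() != open(f2["tads"]).read()


class TestGenome:
    def test_genes_do_not_overlap(self):
        genome = simulate_genome(SimConfig(seed=4))
        by_chrom: dict[str, list[GeneModel]] = {}
        for g in genome.genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        for genes in by_chrom.values():
            genes.sort(key=lambda g: g.start)
            for a, b in zip(genes, genes[1:]):
                assert a.end <= b.start

    def test_planted_pair_geometry(self):
        genome = simulate_genome(SimConfig(seed=4))
        tad_by_name = {t.name: w for t, w in
                       zip(genome.tads, genome.tad_windows)}
        genes = {g.gene_id: g for g in genome.genes}
        for rec in genome.pair_truth:
            t = tad_by_name[rec["tad"]]
            up, down = genes[rec["upstream_gene"]], genes[rec["downstream_gene"]]
            assert up.strand == down.strand == rec["strand"]
            up_hit = [s for s, w in (("left", t.left_boundary),
                                     ("right", t.right_boundary))
                      if overlaps(up.terminator(5000), w)]
            down_hit = [s for s, w in (("left", t.left_boundary),
                                       ("right", t.right_boundary))
                        if overlaps(down.promoter(1000), w)]
            assert up_hit and down_hit and up_hit[0] != down_hit[0]

    def test_infeasible_packing_rejected(self):
        with pytest.raises(ValueError, match="TAD"):
            simulate_genome(SimConfig(seed=0, n_tads=100,
                                      chrom_length=5_000_000))

    def test_zero_genes_is_valid(self):
        genome = simulate_genome(SimConfig(seed=1, n_genes=0,
                                           planted_pairs=0))
        assert genome.filler_gene_ids == [] and len(genome.tads) == 24


class TestPeaks:
    def test_shared_fraction_construction(self):
        cfg = SimConfig(seed=6, fraction_shared=0.4, n_p300=100)
        genome = simulate_genome(cfg)
        peaks = simulate_peaks(cfg, genome)
        assert len(peaks["p300"]) == 100
        assert len(peaks["truth"]["p300_shared"]) == 40
        assert len(peaks["truth"]["p300_only"]) == 60

    def test_partition_recovers_truth_exactly(self):
        cfg = SimConfig(seed=6)
        genome = simulate_genome(cfg)
        peaks = simulate_peaks(cfg, genome)
        only, shared = p300_only_peaks(peaks["p300"], peaks["h3k27ac"],
                                       chrom_sizes=genome.chrom_sizes)
        assert {p.name for p in only} == set(peaks["truth"]["p300_only"])
        assert {p.name for p in shared} == set(peaks["truth"]["p300_shared"])

    def test_fully_shared_leaves_no_p300_only(self):
        cfg = SimConfig(seed=6, fraction_shared=1.0)
        genome = simulate_genome(cfg)
        peaks = simulate_peaks(cfg, genome)
        only, _ = p300_only_peaks(peaks["p300"], peaks["h3k27ac"],
                                  chrom_sizes=genome.chrom_sizes)
        # only deliberate boundary plants (if any) may remain
        assert len(only) == len(genome.headline_tad_indices)


class TestLoops:
    def test_planted_categories_recovered(self):
        cfg = SimConfig(seed=8, n_loops=600)
        genome = simulate_genome(cfg)
        peaks = simulate_peaks(cfg, genome)
        sim = simulate_loops(cfg, genome, peaks)
        p300_only = [p for p in peaks["p300"]
                     if p.name in set(peaks["truth"]["p300_only"])]
        annot = AnchorAnnotator(genome.genes, p300_only, peaks["h3k27me3"])
        classify_loops(sim["loops"], annot, mode="chromatin")
        recovered = [lp.category for lp in sim["loops"]]
        assert recovered == sim["categories"]

    def test_counts_follow_largest_remainder(self):
        cfg = SimConfig(seed=8, n_loops=100)
        genome = simulate_genome(cfg)
        peaks = simulate_peaks(cfg, genome)
        sim = simulate_loops(cfg, genome, peaks)
        assert sum(sim["planted_counts"].values()) == 100
        for cat, frac in cfg.loop_category_proportions.items():
            assert abs(sim["planted_counts"][cat] - frac * 100) <= 1


class TestContacts:
    def test_distance_decay_matches_expectation(self):
        cfg = SimConfig(seed=3, loop_enrichment=1.0, tad_factor=1.0,
                        n_planted_contact_loops=0, contact_base=500.0,
                        contact_decay=0.8)
        m, planted = simulate_contacts(cfg, "chr1", cfg.chrom_length)
        assert planted == []
        n = m.n_bins
        for d in (1, 5, 10, 40):
            diag = np.diagonal(m.counts, offset=d)
            expected = cfg.contact_base * (d + 1.0) ** -cfg.contact_decay
            se = np.sqrt(expected / len(diag))
            assert abs(diag.mean() - expected) < 5 * se

    def test_planted_pixels_reach_target_enrichment(self):
        cfg = SimConfig(seed=3)
        m, planted = simulate_contacts(cfg, "chr1", cfg.chrom_length)
        ratios = []
        for i, j in planted:
            d = j - i
            background = cfg.contact_base * (d + 1.0) ** -cfg.contact_decay
            ratios.append(m.counts[i, j] / background)
        mean_ratio = np.mean(ratios)
        E = cfg.loop_enrichment
        assert 0.8 * E <= mean_ratio <= 1.2 * E

    def test_symmetry_and_seed_reproducibility(self):
        cfg = SimConfig(seed=11)
        m1, p1 = simulate_contacts(cfg, "chr1", cfg.chrom_length)
        m2, p2 = simulate_contacts(cfg, "chr1", cfg.chrom_length)
        assert np.array_equal(m1.counts, m2.counts) and p1 == p2
        assert np.array_equal(m1.counts, m1.counts.T)


class TestExpressionAndCt:
    @staticmethod
    def stub_genes(n):
        return [GeneModel(f"g{i}", "chr1", "+", i * 1000, i * 1000 + 500)
                for i in range(n)]

    def test_tpm_non_negative_and_shift_recovered(self):
        cfg = SimConfig(seed=5, h3k27me3_shift_log2=1.0)
        genes = self.stub_genes(400)
        marked = [g.gene_id for g in genes[:200]]
        df = simulate_expression(cfg, genes, marked)
        assert (df["TPM"] >= 0).all()
        log2 = np.log2(df["TPM"] + 1)
        shift = np.median(log2[200:]) - np.median(log2[:200])
        assert abs(shift - 1.0) <= 0.15

    def test_no_shift_when_disabled(self):
        cfg = SimConfig(seed=5, h3k27me3_shift_log2=0.0)
        genes = self.stub_genes(400)
        df = simulate_expression(cfg, genes, [g.gene_id for g in genes[:200]])
        log2 = np.log2(df["TPM"] + 1)
        assert abs(np.median(log2[200:]) - np.median(log2[:200])) < 0.3
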