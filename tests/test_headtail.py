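"""Head-to-tail boundary gene-pair detection and cancer-gene summaries."""

import numpy as np
import pytest

from tadboundary.core import GeneModel, GenomicInterval, overlaps
from tadboundary.headtail import (HeadTailPair, MutationRecord,
                                  detect_head_to_tail, oncogene_pair_summary,
                                  promoter_mutation_summary)
from tadboundary.simulate import SimConfig, simulate_genome
from tadboundary.topology import tad_boundary_windows
from conftest import make_gene


def iv(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


def brute_force_pairs(tads, genes, promoter_flank=1000, terminator_flank=5000,
                      boundary_flank=5000):
    """All-combinations oracle applying the definition literally: every
    TAD × ordered gene pair × boundary-side assignment is tested."""
    windows = tad_boundary_windows(tads, boundary_flank)
    elements = [(g, g.terminator(terminator_flank), g.three_prime_half(),
                 g.promoter(promoter_flank)) for g in genes]
    found = set()
    for t in windows:
        sides = [("left", t.left_boundary), ("right", t.right_boundary)]
        on_chrom = [e for e in elements if e[0].chrom == t.interval.chrom]
        for a, aterm, atail, aprom in on_chrom:
            a_sides = [s for s, w in sides
                       if overlaps(aterm, w) or overlaps(atail, w)]
            if not a_sides:
                continue
            for b, bterm, btail, bprom in on_chrom:
                if a.gene_id == b.gene_id or a.strand != b.strand:
                    continue
                ka = (a.start, a.end, a.gene_id)
                kb = (b.start, b.end, b.gene_id)
                if (ka >= kb) if a.strand == "+" else (ka <= kb):
                    continue  # upstream = first in transcription order
                for sa in a_sides:
                    for sb, wb in sides:
                        if sa == sb:
                            continue
                        if overlaps(bprom, wb):
                            found.add((t.interval.start, t.interval.end,
                                       a.gene_id, b.gene_id))
    return found


class TestToyGeometry:
    """Plus-strand upstream gene with its TES in the left boundary window,
    downstream gene with its TSS in the right window — the Dcbld2/Cpox-
    like arrangement."""

    TAD = [iv(1_000_000, 1_400_000)]

    @staticmethod
    def gene(gid, strand, start, end):
        return make_gene(gid, "chr1", strand, [(start, end)])

    def test_plus_strand_pair_detected(self):
        a = self.gene("A", "+", 900_000, 1_002_000)   # TES at 1001999
        b = self.gene("B", "+", 1_401_000, 1_480_000)  # TSS at 1401000
        (pair,) = detect_head_to_tail(self.TAD, [a, b])
        assert pair.upstream_gene.gene_id == "A"
        assert pair.downstream_gene.gene_id == "B"
        assert pair.upstream_element == "terminator"
        assert (pair.boundary_side_up, pair.boundary_side_down) == \
            ("left", "right")

    def test_opposite_strand_pair_rejected(self):
        a = self.gene("A", "+", 900_000, 1_002_000)
        b = self.gene("B", "-", 1_401_000, 1_480_000)
        assert detect_head_to_tail(self.TAD, [a, b]) == []

    def test_minus_strand_mirror_geometry(self):
        # transcription runs right-to-left: the upstream gene sits right
        # of the TAD with its TES (left end) in the right boundary
        # window, the downstream promoter (right end) in the left window
        a = self.gene("A", "-", 1_402_000, 1_480_000)  # TES at right bnd
        b = self.gene("B", "-", 920_000, 1_003_000)    # TSS 1002999, left bnd
        (pair,) = detect_head_to_tail(self.TAD, [a, b])
        assert (pair.upstream_gene.gene_id, pair.downstream_gene.gene_id) == \
            ("A", "B")
        assert (pair.boundary_side_up, pair.boundary_side_down) == \
            ("right", "left")

    def test_gene_body_element_when_terminator_misses(self):
        # upstream gene's 3' half crosses the boundary but its TES is
        # > 5 kb away from the window
        a = self.gene("A", "+", 960_000, 1_020_000)    # TES at 1019999
        b = self.gene("B", "+", 1_401_000, 1_480_000)
        (pair,) = detect_head_to_tail(self.TAD, [a, b])
        assert pair.upstream_element == "gene_body"

    def test_gene_order_invariance(self):
        a = self.gene("A", "+", 900_000, 1_002_000)
        b = self.gene("B", "+", 1_401_000, 1_480_000)
        p1 = detect_head_to_tail(self.TAD, [a, b])
        p2 = detect_head_to_tail(self.TAD, [b, a])
        assert [(p.upstream_gene.gene_id, p.downstream_gene.gene_id)
                for p in p1] == \
            [(p.upstream_gene.gene_id, p.downstream_gene.gene_id) for p in p2]


class TestSyntheticRecovery:
    def test_planted_pairs_recovered_exactly_and_match_oracle(self):
        cfg = SimConfig(seed=5, n_tads=40, planted_pairs=8, n_genes=60,
                        chrom_length=15_000_000)
        genome = simulate_genome(cfg)
        pairs = detect_head_to_tail(genome.tad_windows, genome.genes)
        found = {(p.upstream_gene.gene_id, p.downstream_gene.gene_id)
                 for p in pairs}
        truth = {(p["upstream_gene"], p["downstream_gene"])
                 for p in genome.pair_truth}
        assert found == truth
        oracle = brute_force_pairs(genome.tads, genome.genes)
        assert {(a, b) for *_, a, b in oracle} == found

    def test_mirror_symmetry(self):
        """Mirroring all coordinates (x -> L - x) and flipping strands
        yields the mirror-image pair set with roles swapped."""
        L = 2_500_000
        tads = [iv(1_000_000, 1_400_000)]
        a = make_gene("A", "chr1", "+", [(900_000, 1_002_000)])
        b = make_gene("B", "chr1", "+", [(1_401_000, 1_480_000)])

        def mirror_gene(g, new_id):
            strand = "-" if g.strand == "+" else "+"
            return make_gene(new_id, g.chrom, strand,
                             [(L - e, L - s) for s, e in
                              reversed([(x.start, x.end) for x in g.exons])])

        mirrored_tads = [iv(L - t.end, L - t.start) for t in tads]
        ma, mb = mirror_gene(a, "A'"), mirror_gene(b, "B'")
        orig = detect_head_to_tail(tads, [a, b])
        mirr = detect_head_to_tail(mirrored_tads, [ma, mb])
        assert len(orig) == len(mirr) == 1
        # the mirrored upstream gene is the mirror of the original one
        assert mirr[0].upstream_gene.gene_id == "A'"
        assert mirr[0].boundary_side_up != orig[0].boundary_side_up


class TestCancerGeneSummaries:
    @staticmethod
    def pair(up, down, tss_down=1_401_000):
        tad = iv(1_000_000, 1_400_000)
        a = make_gene(up, "chr1", "+", [(900_000, 1_002_000)])
        b = make_gene(down, "chr1", "+", [(tss_down, tss_down + 50_000)])
        return HeadTailPair(tad, a, b, "terminator", "left", "right")

    def test_oncogene_fractions(self):
        pairs = [self.pair(f"U{i}", f"D{i}") for i in range(10)]
        tab = oncogene_pair_summary(pairs, oncogenes={"U0", "U1"},
                                    tsgs={"D5"})
        up = tab[(tab.role == "3prime_anchored") & (tab.gene_class == "oncogene")]
        assert up["fraction"].item() == pytest.approx(0.2)
        assert (tab["n_pairs"] == 10).all()
        empty = oncogene_pair_summary(pairs, {"ZZZ"}, {"QQQ"})
        assert empty[empty.gene_class != "neither"]["count"].sum() == 0

    def test_sample_counted_once_and_window_boundary(self):
        pairs = [self.pair("U", "D")]
        tss = 1_401_000  # promoter window [tss-1000, tss+1000)
        muts = [MutationRecord("s1", "chr1", tss + 1),
                MutationRecord("s1", "chr1", tss + 2),
                MutationRecord("s1", "chr1", tss + 3),
                MutationRecord("s2", "chr1", tss + 1001),  # 1 bp outside
                MutationRecord("s3", "chr2", tss + 1)]
        per_gene, fraction, incidence = promoter_mutation_summary(
            muts, pairs)
        assert per_gene.set_index("gene_id")["n_samples_mutated"]["D"] == 1
        assert fraction == pytest.approx(1 / 3)
        assert incidence.loc["D", "s1"] == 1 and incidence.loc["D", "s2"] == 0

    def test_oncogene_downstream_excluded(self):
        pairs = [self.pair("U", "D")]
        muts = [MutationRecord("s1", "chr1", 1_401_001)]
        _, fraction, _ = promoter_mutation_summary(muts, pairs,
                                                   oncogenes={"D"})
        assert fraction == 0.0

    def test_random_mutations_match_binomial_expectation(self, rng):
        """Uniform mutation placement: the fraction of samples with >= 1
        promoter hit matches 1 - (1 - w/L)^m within the 95% binomial CI."""
        L, m_per_sample, n_samples = 1_000_000, 40, 400
        tad = iv(400_000, 800_000)
        up = make_gene("U", "chr1", "+", [(300_000, 402_000)])
        down = make_gene("D", "chr1", "+", [(801_000, 851_000)])
        (pair,) = detect_head_to_tail([tad], [up, down])
        muts = [MutationRecord(f"s{k}", "chr1", int(pos) + 1)
                for k in range(n_samples)
                for pos in rng.integers(0, L, m_per_sample)]
        _, fraction, _ = promoter_mutation_summary(muts, [pair])
        w = 2000  # one promoter window
        p = 1 - (1 - w / L) ** m_per_sample
        se = np.sqrt(p * (1 - p) / n_samples)
        assert abs(fraction - p) < 1.96 * se + 1e-9
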