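"""Interval algebra, coordinate conventions and format round trips."""

import numpy as np
import pytest

from tadboundary.core import (GenomicInterval, any_overlap, extend_intervals,
                              overlaps, point_window, read_bed, read_bedpe,
                              read_gtf_genes, write_bed, write_bedpe,
                              write_gtf)


class TestBed:
    def test_bed3_and_bed6_parsing(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\nchr1\t100\t200\tpk1\t7\t-\n")
        ivs = read_bed(p)
        assert (ivs[0].chrom, ivs[0].start, ivs[0].end, ivs[0].strand) == \
            ("chr1", 100, 200, ".")
        assert ivs[1].strand == "-" and ivs[1].name == "pk1" and ivs[1].score == 7

    def test_reversed_coordinates_rejected_with_line_number(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t100\t200\nchr1\t200\t100\n")
        with pytest.raises(ValueError, match=":2"):
            read_bed(p)

    def test_malformed_line_rejected(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t100\n")
        with pytest.raises(ValueError):
            read_bed(p)

    def test_round_trip_preserves_records(self, tmp_path, rng):
        ivs = []
        for i in range(50):
            s = int(rng.integers(0, 10**6))
            ivs.append(GenomicInterval(
                f"chr{rng.integers(1, 4)}", s, s + int(rng.integers(1, 5000)),
                strand=["+", "-", "."][int(rng.integers(3))],
                name=f"iv{i}", score=float(rng.integers(0, 100))))
        p = tmp_path / "rt.bed"
        write_bed(ivs, p)
        back = read_bed(p)
        assert back == ivs
        # writing the re-read records reproduces the file byte-identically
        p2 = tmp_path / "rt2.bed"
        write_bed(back, p2)
        assert p.read_bytes() == p2.read_bytes()


class TestGtf:
    GTF = (
        'chr1\tx\tgene\t1\t100\t.\t+\t.\tgene_id "gp";\n'
        'chr1\tx\texon\t1\t40\t.\t+\t.\tgene_id "gp";\n'
        'chr1\tx\texon\t61\t100\t.\t+\t.\tgene_id "gp";\n'
        'chr1\tx\tgene\t1\t100\t.\t-\t.\tgene_id "gm";\n'
    )

    def test_coordinate_conversion_and_strand_aware_ends(self, tmp_path):
        p = tmp_path / "g.gtf"
        p.write_text(self.GTF)
        genes = {g.gene_id: g for g in read_gtf_genes(p)}
        gp, gm = genes["gp"], genes["gm"]
        assert (gp.start, gp.end) == (0, 100)
        assert (gp.tss, gp.tes) == (0, 99)
        assert (gm.tss, gm.tes) == (99, 0)

    def test_gene_synthesized_from_exon_envelope(self, tmp_path):
        # oracle: min/max over the exon records
        p = tmp_path / "e.gtf"
        p.write_text('chr2\tx\texon\t501\t600\t.\t+\t.\tgene_id "ge";\n'
                     'chr2\tx\texon\t901\t1000\t.\t+\t.\tgene_id "ge";\n')
        (g,) = read_gtf_genes(p)
        assert (g.start, g.end) == (500, 1000)
        assert [(e.start, e.end) for e in g.sorted_exons()] == \
            [(500, 600), (900, 1000)]

    def test_missing_gene_id_and_bad_strand_rejected(self, tmp_path):
        p = tmp_path / "bad.gtf"
        p.write_text('chr1\tx\tgene\t1\t100\t.\t+\t.\tfoo "bar";\n')
        with pytest.raises(ValueError, match="gene_id"):
            read_gtf_genes(p)
        p.write_text('chr1\tx\tgene\t1\t100\t.\t?\t.\tgene_id "g";\n')
        with pytest.raises(ValueError, match="strand"):
            read_gtf_genes(p)

    def test_gtf_round_trip(self, tmp_path, seven_exon_gene, minus_gene):
        p = tmp_path / "rt.gtf"
        write_gtf([seven_exon_gene, minus_gene], p)
        back = {g.gene_id: g for g in read_gtf_genes(p)}
        for g in (seven_exon_gene, minus_gene):
            b = back[g.gene_id]
            assert (b.start, b.end, b.strand) == (g.start, g.end, g.strand)
            assert [(e.start, e.end) for e in b.sorted_exons()] == \
                [(e.start, e.end) for e in g.sorted_exons()]


class TestBedpe:
    def test_anchor_canonicalization(self, tmp_path):
        p = tmp_path / "l.bedpe"
        p.write_text("chr1\t10000\t15000\tchr1\t90000\t95000\n"
                     "chr1\t90000\t95000\tchr1\t10000\t15000\n")
        loops = read_bedpe(p)
        for lp in loops:
            assert lp.anchor1.start == 10000
            assert lp.anchor2.start == 90000

    def test_trans_record_flagged(self, tmp_path):
        p = tmp_path / "t.bedpe"
        p.write_text("chr2\t0\t100\tchr1\t0\t100\n")
        (lp,) = read_bedpe(p)
        assert lp.is_trans and lp.anchor1.chrom == "chr1"

    def test_five_columns_rejected(self, tmp_path):
        p = tmp_path / "bad.bedpe"
        p.write_text("chr1\t0\t100\tchr1\t200\n")
        with pytest.raises(ValueError):
            read_bedpe(p)

    def test_round_trip(self, tmp_path):
        p = tmp_path / "l.bedpe"
        p.write_text("chr1\t0\t100\tchr1\t5000\t5100\tloopA\t3\n")
        q = tmp_path / "l2.bedpe"
        write_bedpe(read_bedpe(p), q)
        assert read_bedpe(q) == read_bedpe(p)


class TestExtend:
    def test_slop_and_clamping(self):
        sizes = {"chr1": 10**6}
        (out,) = extend_intervals([GenomicInterval("chr1", 5000, 5200)],
                                  1000, sizes)
        assert (out.start, out.end) == (4000, 6200)
        (out,) = extend_intervals([GenomicInterval("chr1", 300, 400)],
                                  1000, {"chr1": 10000})
        assert (out.start, out.end) == (0, 1400)
        (out,) = extend_intervals([GenomicInterval("chr1", 9900, 9950)],
                                  1000, {"chr1": 10000})
        assert out.end == 10000

    def test_flank_zero_is_identity(self):
        ivs = [GenomicInterval("chr1", 10, 20, "-", "a", 1.0)]
        assert extend_intervals(ivs, 0, {"chr1": 100}) == ivs

    def test_unknown_chromosome_rejected(self):
        with pytest.raises(KeyError):
            extend_intervals([GenomicInterval("chrZ", 0, 10)], 5, {"chr1": 100})


class TestOverlap:
    def test_half_open_semantics(self):
        a = GenomicInterval("chr1", 0, 10)
        assert not overlaps(a, GenomicInterval("chr1", 10, 20))  # abutting
        assert overlaps(a, GenomicInterval("chr1", 9, 20))
        assert not overlaps(a, GenomicInterval("chr2", 0, 10))

    def test_matches_per_bp_set_intersection_oracle(self, rng):
        for _ in range(1000):
            s1, s2 = rng.integers(0, 200, size=2)
            a = GenomicInterval("c", int(s1), int(s1 + rng.integers(1, 50)))
            b = GenomicInterval("c", int(s2), int(s2 + rng.integers(1, 50)))
            truth = bool(set(range(a.start, a.end)) & set(range(b.start, b.end)))
            assert overlaps(a, b) == truth

    def test_any_overlap_edge_cases(self):
        q = [GenomicInterval("chr1", 0, 10), GenomicInterval("chr2", 5, 15)]
        assert not any_overlap(q, []).any()
        assert any_overlap(q, q).all()

    def test_any_overlap_equals_quadratic_oracle(self, rng):
        def rand_ivs(n):
            out = []
            for _ in range(n):
                s = int(rng.integers(0, 5000))
                out.append(GenomicInterval(f"chr{rng.integers(1, 3)}", s,
                                           s + int(rng.integers(1, 300))))
            return out

        for _ in range(5):
            query, subject = rand_ivs(200), rand_ivs(200)
            mask = any_overlap(query, subject)
            oracle = [any(overlaps(q, s) for s in subject) for q in query]
            assert mask.tolist() == oracle


def test_point_window_clamps_at_zero():
    w = point_window("chr1", 300, 1000)
    assert (w.start, w.end) == (0, 1300)
    with pytest.raises(ValueError):
        point_window("chr1", 300, 0)


def test_invalid_intervals_rejected():
    with pytest.raises(ValueError):
        GenomicInterval("chr1", 200, 100)
    with pytest.raises(ValueError):
        GenomicInterval("", 0, 10)
    with pytest.raises(ValueError):
        GenomicInterval("chr1", -5, 10)
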