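"""Seeded synthetic-data generators with exact ground truth.

Every input the pipeline consumes — gene models, TADs, ChIP-seq peak
sets with controlled co-occurrence, loops with planted interaction
categories, distance-decay contact matrices with planted loop pixels,
log-normal expression tables with a planted H3K27me3 repression shift,
and qPCR Ct tables with planted fold changes — can be generated from a
:class:`SimConfig`, together with the ground truth needed to score every
pipeline stage exactly.  Identical seeds give identical outputs.

Random peaks and filler genes are kept away from TAD-boundary windows so
that planted boundary configurations (head-to-tail pairs, boundary-
anchored p300-only/H3K27me3 marks) are the only ones present and ground
truth is exact rather than approximate.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .core import (GenomicInterval, GeneModel, IntervalIndex, Loop,
                   write_bed, write_bedpe, write_chrom_sizes, write_gtf)
from .hic import ContactMatrix, write_contacts
from .topology import Tad, tad_boundary_windows

__all__ = [
    "SimConfig",
    "SimGenome",
    "simulate_genome",
    "simulate_peaks",
    "simulate_loops",
    "simulate_contacts",
    "simulate_expression",
    "simulate_ct_table",
    "simulate_all",
]


def _default_loop_proportions() -> dict[str, float]:
    # headline repressive class planted at the prevalence reported for
    # chromatin loops (8.33%); the rest spread over gene-element classes
    return {
        "p300only-H3K27me3": 0.0833,
        "PP": 0.12,
        "PT": 0.15,
        "PG": 0.25,
        "GG": 0.1967,
        "intergenic-intergenic": 0.20,
    }


def _default_fold_map() -> dict[str, float]:
    return {"GeneX": 4.0, "GeneY": 0.5}


@dataclass
class SimConfig:
    """All knobs of the synthetic study, with defaults sized so every
    stage runs in seconds (2 chromosomes × 10 Mb at 25 kb bins)."""

    seed: int = 0
    # genome
    n_chroms: int = 2
    chrom_length: int = 10_000_000
    bin_size: int = 25_000
    # genes
    n_genes: int = 160
    gene_length_range: tuple[int, int] = (20_000, 120_000)
    n_exons_range: tuple[int, int] = (2, 6)
    # TADs
    n_tads: int = 24
    tad_size_range: tuple[int, int] = (300_000, 600_000)
    tad_gap_range: tuple[int, int] = (100_000, 200_000)
    boundary_flank: int = 5_000
    planted_pairs: int = 6
    pair_jitter: tuple[int, int] = (1_000, 4_000)
    # headline repressive boundary class, planted at the TAD-boundary
    # prevalence of the reference analysis (1.52%)
    headline_boundary_fraction: float = 0.0152
    # peaks
    n_p300: int = 100
    n_h3k27ac: int = 120
    fraction_shared: float = 0.4
    peak_width: int = 400
    h3k27me3_gene_fraction: float = 0.3
    h3k27me3_block_pad: int = 2_000
    # loops
    n_loops: int = 300
    loop_category_proportions: dict[str, float] = field(
        default_factory=_default_loop_proportions)
    anchor_width: int = 800
    # contacts
    contact_base: float = 2000.0
    contact_decay: float = 0.8
    tad_factor: float = 1.5
    loop_enrichment: float = 5.0
    loop_distance_bins: tuple[int, int] = (80, 150)
    n_planted_contact_loops: int = 50
    contact_chroms: tuple[str, ...] = ("chr1",)
    # expression
    expr_mean_log2: float = 3.0
    expr_sd_log2: float = 1.5
    h3k27me3_shift_log2: float = 1.0
    # qPCR
    qpcr_fold_map: dict[str, float] = field(default_factory=_default_fold_map)
    qpcr_reference: str = "ACT"
    qpcr_control_sample: str = "control"
    qpcr_treated_sample: str = "treated"
    baseline_ct: float = 20.0
    baseline_dct: float = 4.0
    ct_noise_sd: float = 0.1
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be >= 0")
        for name in ("n_chroms", "n_genes", "n_tads", "n_p300", "n_h3k27ac",
                     "n_loops", "n_planted_contact_loops", "planted_pairs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.fraction_shared <= 1.0):
            raise ValueError("fraction_shared must be in [0, 1]")
        if self.loop_enrichment < 1.0:
            raise ValueError("loop_enrichment must be >= 1")
        if self.contact_decay <= 0:
            raise ValueError("contact_decay must be > 0")
        if any(f <= 0 for f in self.qpcr_fold_map.values()):
            raise ValueError("qPCR folds must be positive")
        props = self.loop_category_proportions
        if props and abs(sum(props.values()) - 1.0) > 1e-6:
            raise ValueError("loop_category_proportions must sum to 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("gene_length_range", "n_exons_range", "tad_size_range",
                    "tad_gap_range", "pair_jitter", "loop_distance_bins",
                    "contact_chroms"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SimGenome:
    """Genome-scale outputs of :func:`simulate_genome` plus ground truth."""

    chrom_sizes: dict[str, int]
    genes: list[GeneModel]
    tads: list[GenomicInterval]
    tad_windows: list[Tad]
    pair_truth: list[dict]           # planted head-to-tail pairs
    headline_tad_indices: list[int]  # TADs carrying boundary p300/H3K27me3
    filler_gene_ids: list[str]


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

_EDGE_MARGIN = 200_000  # free bp kept at each chromosome end


def simulate_genome(config: SimConfig,
                    rng: np.random.Generator | None = None) -> SimGenome:
    """Generate chromosome sizes, a TAD tiling and non-overlapping
    multi-exon genes, planting ``config.planted_pairs`` head-to-tail
    boundary gene pairs.

    Planted pairs follow the detection definition exactly: two genes of
    one strand, the upstream gene's TES and the downstream gene's TSS
    placed inside opposite ±5 kb boundary windows of one TAD, with
    1–4 kb jitter so detection is non-trivial.  Filler genes are rejected
    near boundary windows so no unplanned pairs arise.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    sizes = {f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)}

    # --- TAD tiling -------------------------------------------------------
    tads: list[GenomicInterval] = []
    chroms = list(sizes)
    per_chrom = [config.n_tads // config.n_chroms] * config.n_chroms
    for i in range(config.n_tads % config.n_chroms):
        per_chrom[i] += 1
    for chrom, n in zip(chroms, per_chrom):
        pos = _EDGE_MARGIN
        for k in range(n):
            size = int(rng.integers(*config.tad_size_range))
            size = max(config.bin_size, (size // config.bin_size) * config.bin_size)
            if pos + size > sizes[chrom] - _EDGE_MARGIN:
                raise ValueError(
                    f"cannot place {n} TADs of {config.tad_size_range} bp on a "
                    f"{sizes[chrom]} bp chromosome; reduce n_tads or TAD size")
            tads.append(GenomicInterval(chrom, pos, pos + size,
                                        name=f"tad_{len(tads) + 1}"))
            pos += size + int(rng.integers(*config.tad_gap_range))
    windows = tad_boundary_windows(tads, config.boundary_flank, sizes)

    # --- planted head-to-tail pairs and headline-class TADs ---------------
    n_headline = int(round(config.headline_boundary_fraction * len(tads)))
    if config.planted_pairs + n_headline > len(tads):
        raise ValueError("more planted TAD configurations than TADs")
    special = rng.choice(len(tads), size=config.planted_pairs + n_headline,
                         replace=False)
    pair_tads = [int(i) for i in special[:config.planted_pairs]]
    headline_tads = sorted(int(i) for i in special[config.planted_pairs:])

    genes: list[GeneModel] = []
    occupied: list[GenomicInterval] = []
    pair_truth: list[dict] = []
    jit_lo, jit_hi = config.pair_jitter

    def jitter() -> int:
        mag = int(rng.integers(jit_lo, jit_hi + 1))
        return mag if rng.random() < 0.5 else -mag

    def neighbor_gaps(idx: int) -> tuple[int, int]:
        tad = tads[idx]
        prev_end = max((t.end for t in tads
                        if t.chrom == tad.chrom and t.end <= tad.start),
                       default=_EDGE_MARGIN // 2)
        next_start = min((t.start for t in tads
                          if t.chrom == tad.chrom and t.start >= tad.end),
                         default=sizes[tad.chrom] - _EDGE_MARGIN // 2)
        return tad.start - prev_end, next_start - tad.end

    for idx in pair_tads:
        tad = tads[idx]
        strand = "+" if rng.random() < 0.5 else "-"
        # cap gene lengths by the gap to the neighbouring TAD so planted
        # promoters/terminators cannot reach an adjacent boundary window
        # (keeps the planted pair set exactly the detectable set)
        gap_prev, gap_next = neighbor_gaps(idx)
        # half the gap, with margin: two planted genes from adjacent TADs
        # may share one gap without touching
        cap_prev = (gap_prev - 20_000) // 2
        cap_next = (gap_next - 20_000) // 2
        la = int(rng.integers(*config.gene_length_range))
        lb = int(rng.integers(*config.gene_length_range))
        if strand == "+":
            # upstream gene ends at the left boundary, downstream gene
            # starts at the right boundary
            la = max(18_000, min(la, cap_prev))
            lb = max(18_000, min(lb, cap_next))
            a_end = tad.start + jitter()
            a = _make_gene(f"pairA_{idx}", tad.chrom, strand,
                           a_end - la, a_end, config, rng)
            b_start = tad.end + jitter()
            b = _make_gene(f"pairB_{idx}", tad.chrom, strand,
                           b_start, b_start + lb, config, rng)
        else:
            # mirror image: the upstream gene (first in transcription
            # order) sits right of the TAD with its TES at the right
            # boundary; the downstream promoter sits at the left boundary
            la = max(18_000, min(la, cap_next))
            lb = max(18_000, min(lb, cap_prev))
            a_start = tad.end + jitter()
            a = _make_gene(f"pairA_{idx}", tad.chrom, strand,
                           a_start, a_start + la, config, rng)
            b_end = tad.start + jitter()
            b = _make_gene(f"pairB_{idx}", tad.chrom, strand,
                           b_end - lb, b_end, config, rng)
        genes.extend([a, b])
        occupied.extend([a.span, b.span])
        pair_truth.append({
            "tad": tad.name, "chrom": tad.chrom,
            "tad_start": tad.start, "tad_end": tad.end,
            "upstream_gene": a.gene_id, "downstream_gene": b.gene_id,
            "strand": strand,
        })

    # --- filler genes, kept clear of all boundary windows ------------------
    boundary_avoid = IntervalIndex(
        GenomicInterval(w.chrom, max(0, w.start - 7_000), w.end + 7_000)
        for t in windows for w in (t.left_boundary, t.right_boundary))
    filler_ids: list[str] = []
    attempts = 0
    while len(filler_ids) < config.n_genes:
        attempts += 1
        if attempts > config.n_genes * 200:
            raise ValueError("cannot place filler genes; genome too crowded")
        chrom = chroms[int(rng.integers(len(chroms)))]
        length = int(rng.integers(*config.gene_length_range))
        start = int(rng.integers(10_000, sizes[chrom] - length - 10_000))
        cand = GenomicInterval(chrom, max(0, start - 12_000),
                               start + length + 12_000)
        if boundary_avoid.overlaps_interval(cand):
            continue
        if IntervalIndex(occupied).overlaps_interval(cand):
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"gene_{len(filler_ids) + 1:04d}"
        g = _make_gene(gid, chrom, strand, start, start + length, config, rng)
        genes.append(g)
        occupied.append(g.span)
        filler_ids.append(gid)

    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return SimGenome(sizes, genes, tads, windows, pair_truth,
                     headline_tads, filler_ids)


def _make_gene(gene_id: str, chrom: str, strand: str, start: int, end: int,
               config: SimConfig, rng: np.random.Generator) -> GeneModel:
    """Gene with a random multi-exon structure spanning [start, end)."""
    n_exons = int(rng.integers(config.n_exons_range[0],
                               config.n_exons_range[1] + 1))
    inner = np.arange(start + 500, end - 500, 200)
    n_cuts = 2 * (n_exons - 1)
    if n_cuts > 0 and len(inner) > n_cuts:
        cuts = np.sort(rng.choice(inner, size=n_cuts, replace=False))
        bounds = [start] + [int(c) for c in cuts] + [end]
        exons = tuple(GenomicInterval(chrom, bounds[i], bounds[i + 1], strand)
                      for i in range(0, len(bounds) - 1, 2))
    else:
        exons = (GenomicInterval(chrom, start, end, strand),)
    return GeneModel(gene_id, chrom, strand, start, end, gene_name=gene_id,
                     exons=exons)


# ---------------------------------------------------------------------------
# peaks
# ---------------------------------------------------------------------------

def simulate_peaks(config: SimConfig, genome: SimGenome,
                   rng: np.random.Generator | None = None) -> dict:
    """p300 / H3K27ac / H3K27me3 peak sets with controlled co-occurrence.

    ``fraction_shared`` of the p300 peaks are placed within 1 kb of an
    H3K27ac peak (they overlap the ±1 kb extended set); the rest are kept
    >= 2.5 kb from every H3K27ac peak (true p300-only).  H3K27me3 blocks
    cover a known subset of filler genes, and headline TADs additionally
    get a boundary p300-only peak on one window and an H3K27me3 block on
    the other.  Returns peak lists plus the ground-truth assignment.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    sizes = genome.chrom_sizes
    chroms = list(sizes)
    width = config.peak_width
    boundary_avoid = IntervalIndex(
        GenomicInterval(w.chrom, max(0, w.start - 3_000), w.end + 3_000)
        for t in genome.tad_windows
        for w in (t.left_boundary, t.right_boundary))

    def random_position(avoid: IntervalIndex | None, margin: int) -> GenomicInterval:
        for _ in range(10_000):
            chrom = chroms[int(rng.integers(len(chroms)))]
            start = int(rng.integers(10_000, sizes[chrom] - width - 10_000))
            iv = GenomicInterval(chrom, start, start + width)
            probe = GenomicInterval(chrom, max(0, start - margin),
                                    start + width + margin)
            if boundary_avoid.overlaps_interval(probe):
                continue
            if avoid is not None and avoid.overlaps_interval(probe):
                continue
            return iv
        raise ValueError("cannot place peaks; genome too crowded")

    h3k27ac = [dataclasses.replace(random_position(None, 0),
                                   name=f"k27ac_{i + 1:04d}")
               for i in range(config.n_h3k27ac)]
    k27ac_index = IntervalIndex(h3k27ac)

    n_shared = int(round(config.n_p300 * config.fraction_shared))
    n_headline = len(genome.headline_tad_indices)
    n_only_random = config.n_p300 - n_shared - n_headline
    if n_only_random < 0:
        raise ValueError("n_p300 too small for fraction_shared plus "
                         "headline boundary plants")

    p300: list[GenomicInterval] = []
    for i in range(n_shared):
        host = h3k27ac[int(rng.integers(len(h3k27ac)))]
        offset = int(rng.integers(-800, 801))
        start = max(0, host.start + offset)
        p300.append(GenomicInterval(host.chrom, start, start + width,
                                    name=f"p300_shared_{i + 1:04d}"))
    for i in range(n_only_random):
        iv = random_position(k27ac_index, 2_500)
        p300.append(dataclasses.replace(iv, name=f"p300_only_{i + 1:04d}"))

    h3k27me3: list[GenomicInterval] = []
    # gene-level H3K27me3 blocks (filler genes only, so planted boundary
    # classes stay exact)
    gene_by_id = {g.gene_id: g for g in genome.genes}
    n_marked = int(round(config.h3k27me3_gene_fraction * len(genome.filler_gene_ids)))
    marked_ids = sorted(
        rng.choice(genome.filler_gene_ids, size=n_marked, replace=False))
    for gid in marked_ids:
        g = gene_by_id[gid]
        h3k27me3.append(GenomicInterval(
            g.chrom, max(0, g.start - config.h3k27me3_block_pad),
            min(sizes[g.chrom], g.end + config.h3k27me3_block_pad),
            name=f"k27me3_{gid}"))

    # headline boundary plants: p300-only peak in the left window,
    # H3K27me3 block in the right window
    for k, idx in enumerate(genome.headline_tad_indices):
        tad = genome.tads[idx]
        left_c, right_c = tad.start, tad.end
        p300.append(GenomicInterval(
            tad.chrom, left_c - width // 2, left_c + width - width // 2,
            name=f"p300_only_bnd_{k + 1:02d}"))
        h3k27me3.append(GenomicInterval(
            tad.chrom, right_c - 1_500, right_c + 1_500,
            name=f"k27me3_bnd_{k + 1:02d}"))

    truth = {
        "p300_only": sorted(p.name for p in p300 if p.name.startswith("p300_only")),
        "p300_shared": sorted(p.name for p in p300 if p.name.startswith("p300_shared")),
        "h3k27me3_genes": list(marked_ids),
    }
    return {"p300": p300, "h3k27ac": h3k27ac, "h3k27me3": h3k27me3,
            "truth": truth}


# ---------------------------------------------------------------------------
# loops with planted interaction categories
# ---------------------------------------------------------------------------

def _largest_remainder_counts(proportions: Mapping[str, float],
                              total: int) -> dict[str, int]:
    cats = sorted(proportions)
    raw = {c: proportions[c] * total for c in cats}
    counts = {c: int(np.floor(raw[c])) for c in cats}
    rem = total - sum(counts.values())
    order = sorted(cats, key=lambda c: (-(raw[c] - counts[c]), c))
    for c in order[:rem]:
        counts[c] += 1
    return counts


def simulate_loops(config: SimConfig, genome: SimGenome, peaks: dict,
                   rng: np.random.Generator | None = None) -> dict:
    """Loops with planted interaction categories at exact counts.

    Anchor pairs are built on elements that classify unambiguously:
    promoters/terminators/body interiors of "clean" filler genes (no
    H3K27me3, no peaks within 7 kb), true p300-only peaks, H3K27me3 gene
    blocks, and empty intergenic space.  Category counts follow
    ``loop_category_proportions`` by largest remainder, so recovered
    fractions match the plant up to classification itself.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    sizes = genome.chrom_sizes
    chroms = list(sizes)
    half = config.anchor_width // 2

    marked = set(peaks["truth"]["h3k27me3_genes"])
    peak_avoid = IntervalIndex(list(peaks["p300"]) + list(peaks["h3k27me3"]))
    gene_index = IntervalIndex(g.span for g in genome.genes)
    boundary_index = IntervalIndex(
        w for t in genome.tad_windows
        for w in (t.left_boundary, t.right_boundary))
    gene_by_id = {g.gene_id: g for g in genome.genes}

    clean: list[GeneModel] = []
    for gid in genome.filler_gene_ids:
        g = gene_by_id[gid]
        if gid in marked:
            continue
        if g.end - g.start < 16_000:
            continue
        probe = GenomicInterval(g.chrom, max(0, g.start - 7_000), g.end + 7_000)
        if peak_avoid.overlaps_interval(probe):
            continue
        clean.append(g)
    if len(clean) < 4:
        raise ValueError("too few clean genes to plant loop categories")
    marked_genes = [gene_by_id[gid] for gid in sorted(marked)]
    p300_only_peaks = [p for p in peaks["p300"]
                       if p.name and p.name.startswith("p300_only")]

    def promoter_anchor(g: GeneModel) -> GenomicInterval:
        return GenomicInterval(g.chrom, max(0, g.tss - half), g.tss + half)

    def terminator_anchor(g: GeneModel) -> GenomicInterval:
        return GenomicInterval(g.chrom, max(0, g.tes - half), g.tes + half)

    def body_anchor(g: GeneModel) -> GenomicInterval:
        # interior clear of the promoter (±1 kb) and terminator (±5 kb)
        if g.strand == "+":
            lo, hi = g.start + 1_200, g.end - 5_200
        else:
            lo, hi = g.start + 5_200, g.end - 1_200
        c = int(rng.integers(lo + half, hi - half))
        return GenomicInterval(g.chrom, c - half, c + half)

    def intergenic_anchor(chrom: str) -> GenomicInterval:
        for _ in range(10_000):
            start = int(rng.integers(10_000,
                                     sizes[chrom] - config.anchor_width - 10_000))
            iv = GenomicInterval(chrom, start, start + config.anchor_width)
            probe = GenomicInterval(chrom, max(0, start - 7_000),
                                    start + config.anchor_width + 7_000)
            if (gene_index.overlaps_interval(probe)
                    or peak_avoid.overlaps_interval(probe)
                    or boundary_index.overlaps_interval(probe)):
                continue
            return iv
        raise ValueError("cannot place intergenic anchors")

    def pick_gene(pool: Sequence[GeneModel], chrom: str,
                  exclude: str | None = None) -> GeneModel:
        cands = [g for g in pool if g.chrom == chrom and g.gene_id != exclude]
        if not cands:
            raise ValueError(f"no candidate gene on {chrom}")
        return cands[int(rng.integers(len(cands)))]

    headline_chroms = sorted(
        {p.chrom for p in p300_only_peaks} & {g.chrom for g in marked_genes})

    def anchors_for(category: str) -> tuple[GenomicInterval, GenomicInterval]:
        chrom = chroms[int(rng.integers(len(chroms)))]
        if category == "p300only-H3K27me3":
            if not headline_chroms:
                raise ValueError("no chromosome carries both p300-only peaks "
                                 "and H3K27me3 genes")
            chrom = headline_chroms[int(rng.integers(len(headline_chroms)))]
            pk = [p for p in p300_only_peaks if p.chrom == chrom]
            mk = [g for g in marked_genes if g.chrom == chrom]
            p = pk[int(rng.integers(len(pk)))]
            g = mk[int(rng.integers(len(mk)))]
            c = p.midpoint
            gc = (g.start + g.end) // 2
            return (GenomicInterval(chrom, c - half, c + half),
                    GenomicInterval(chrom, gc - half, gc + half))
        if category == "PP":
            g1 = pick_gene(clean, chrom)
            g2 = pick_gene(clean, chrom, exclude=g1.gene_id)
            return promoter_anchor(g1), promoter_anchor(g2)
        if category == "PT":
            g1 = pick_gene(clean, chrom)
            g2 = pick_gene(clean, chrom, exclude=g1.gene_id)
            return promoter_anchor(g1), terminator_anchor(g2)
        if category == "PG":
            g1 = pick_gene(clean, chrom)
            g2 = pick_gene(clean, chrom, exclude=g1.gene_id)
            return promoter_anchor(g1), body_anchor(g2)
        if category == "GG":
            g1 = pick_gene(clean, chrom)
            g2 = pick_gene(clean, chrom, exclude=g1.gene_id)
            return body_anchor(g1), body_anchor(g2)
        if category == "intergenic-intergenic":
            return intergenic_anchor(chrom), intergenic_anchor(chrom)
        raise ValueError(f"cannot plant category {category!r}")

    counts = _largest_remainder_counts(config.loop_category_proportions,
                                       config.n_loops)
    loops: list[Loop] = []
    categories: list[str] = []
    i = 0
    for cat in sorted(counts):
        for _ in range(counts[cat]):
            a1, a2 = anchors_for(cat)
            i += 1
            loops.append(Loop(a1, a2, name=f"loop_{i:05d}"))
            categories.append(cat)
    perm = sorted(range(len(loops)), key=lambda k: loops[k].sort_key())
    loops = [loops[k] for k in perm]
    categories = [categories[k] for k in perm]
    return {"loops": loops, "categories": categories,
            "planted_counts": counts}


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------

def simulate_contacts(config: SimConfig, chrom: str, length: int,
                      tads: Sequence[GenomicInterval] = (),
                      rng: np.random.Generator | None = None,
                      planted_pixels: Sequence[tuple[int, int]] | None = None,
                      ) -> tuple[ContactMatrix, list[tuple[int, int]]]:
    """Poisson contact matrix with power-law distance decay, TAD blocks
    and loop-pixel enrichment.

    Expected count λ(i, j) = base · (|i − j| + 1)^(−α), multiplied by
    ``tad_factor`` when both bins fall in one TAD and by
    ``loop_enrichment`` at planted loop pixels.  Pixels are drawn at
    distances ``loop_distance_bins`` unless given explicitly.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 3)
    n_bins = length // config.bin_size
    idx = np.arange(n_bins)
    dist = np.abs(np.subtract.outer(idx, idx))
    lam = config.contact_base * np.power(dist + 1.0, -config.contact_decay)
    for tad in tads:
        if tad.chrom != chrom:
            continue
        lo = tad.start // config.bin_size
        hi = min(n_bins, -(-tad.end // config.bin_size))
        lam[lo:hi, lo:hi] *= config.tad_factor

    if planted_pixels is None:
        planted: list[tuple[int, int]] = []
        seen = set()
        d_lo, d_hi = config.loop_distance_bins
        guard = 0
        while len(planted) < config.n_planted_contact_loops:
            guard += 1
            if guard > 100_000:
                raise ValueError("cannot place planted loop pixels")
            d = int(rng.integers(d_lo, d_hi + 1))
            if d >= n_bins - 14:
                continue
            i = int(rng.integers(7, n_bins - d - 7))
            if (i, i + d) in seen:
                continue
            seen.add((i, i + d))
            planted.append((i, i + d))
    else:
        planted = [(min(i, j), max(i, j)) for i, j in planted_pixels]
    for i, j in planted:
        lam[i, j] *= config.loop_enrichment
        lam[j, i] *= config.loop_enrichment

    upper = np.triu(rng.poisson(lam)).astype(float)
    counts = upper + np.triu(upper, 1).T
    return ContactMatrix(chrom, config.bin_size, counts), planted


# ---------------------------------------------------------------------------
# expression and qPCR tables
# ---------------------------------------------------------------------------

def simulate_expression(config: SimConfig, genes: Sequence[GeneModel],
                        h3k27me3_gene_ids: Sequence[str],
                        rng: np.random.Generator | None = None):
    """Gene TPM table: log2(TPM+1) ~ Normal(μ, σ), with the planted
    downward shift on H3K27me3-marked genes; clipped so TPM >= 0."""
    import pandas as pd

    rng = rng if rng is not None else np.random.default_rng(config.seed + 4)
    marked = set(h3k27me3_gene_ids)
    log2tpm = rng.normal(config.expr_mean_log2, config.expr_sd_log2,
                         size=len(genes))
    for k, g in enumerate(genes):
        if g.gene_id in marked:
            log2tpm[k] -= config.h3k27me3_shift_log2
    log2tpm = np.clip(log2tpm, 0.0, None)
    tpm = np.power(2.0, log2tpm) - 1.0
    return pd.DataFrame({"gene_id": [g.gene_id for g in genes],
                         "TPM": np.round(tpm, 6)})


def simulate_ct_table(config: SimConfig,
                      rng: np.random.Generator | None = None):
    """qPCR Ct table with planted fold changes.

    Control-condition target genes sit at ``baseline_ct + baseline_dct``;
    the treated condition shifts each target by −log2(fold); the internal
    control gene stays at ``baseline_ct``; Gaussian noise (σ =
    ``ct_noise_sd``) is added per replicate.
    """
    import pandas as pd

    rng = rng if rng is not None else np.random.default_rng(config.seed + 5)
    rows = []
    sd = config.ct_noise_sd

    def noise() -> float:
        return float(rng.normal(0.0, sd)) if sd > 0 else 0.0

    for sample in (config.qpcr_control_sample, config.qpcr_treated_sample):
        for rep in range(1, config.n_replicates + 1):
            rows.append((sample, config.qpcr_reference, rep,
                         config.baseline_ct + noise()))
            for gene, fold in config.qpcr_fold_map.items():
                ct = config.baseline_ct + config.baseline_dct
                if sample == config.qpcr_treated_sample:
                    ct -= float(np.log2(fold))
                rows.append((sample, gene, rep, ct + noise()))
    return pd.DataFrame(rows, columns=["sample", "gene", "replicate", "ct"])


# ---------------------------------------------------------------------------
# one-call driver
# ---------------------------------------------------------------------------

def simulate_all(config: SimConfig, outdir: str | Path) -> dict:
    """Generate and write every synthetic input plus ground_truth.json.

    Returns a manifest mapping logical names to file paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    genome = simulate_genome(config, rng)
    peaks = simulate_peaks(config, genome, rng)
    loops = simulate_loops(config, genome, peaks, rng)

    files: dict[str, Path] = {}

    def put(name: str, fname: str) -> Path:
        files[name] = outdir / fname
        return files[name]

    write_chrom_sizes(genome.chrom_sizes, put("chrom_sizes", "chrom.sizes"))
    write_gtf(genome.genes, put("genes", "genes.gtf"))
    write_bed(genome.tads, put("tads", "tads.bed"))
    write_bedpe(loops["loops"], put("loops", "loops.bedpe"))
    write_bed(peaks["p300"], put("p300", "p300.bed"))
    write_bed(peaks["h3k27ac"], put("h3k27ac", "h3k27ac.bed"))
    write_bed(peaks["h3k27me3"], put("h3k27me3", "h3k27me3.bed"))

    planted_pixels: dict[str, list[tuple[int, int]]] = {}
    for chrom in config.contact_chroms:
        m, pixels = simulate_contacts(config, chrom,
                                      genome.chrom_sizes[chrom],
                                      genome.tads, rng)
        write_contacts(m, put(f"contacts_{chrom}", f"contacts_{chrom}.tsv"))
        planted_pixels[chrom] = pixels

    expr = simulate_expression(config, genome.genes,
                               peaks["truth"]["h3k27me3_genes"], rng)
    expr.to_csv(put("expression", "expression.tsv"), sep="\t", index=False)
    ct = simulate_ct_table(config, rng)
    ct.to_csv(put("ct", "ct.tsv"), sep="\t", index=False)

    truth = {
        "pairs": genome.pair_truth,
        "headline_tads": [genome.tads[i].name
                          for i in genome.headline_tad_indices],
        "p300_only": peaks["truth"]["p300_only"],
        "p300_shared": peaks["truth"]["p300_shared"],
        "h3k27me3_genes": peaks["truth"]["h3k27me3_genes"],
        "loop_categories": loops["categories"],
        "loop_planted_counts": loops["planted_counts"],
        "contact_planted_pixels": planted_pixels,
        "expression_shift_log2": config.h3k27me3_shift_log2,
        "qpcr_fold_map": config.qpcr_fold_map,
    }
    gt_path = put("ground_truth", "ground_truth.json")
    gt_path.write_text(json.dumps(truth, indent=1, sort_keys=True) + "\n")
    return {name: str(path) for name, path in files.items()}
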