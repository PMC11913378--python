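"""Head-to-tail TAD-boundary gene-pair detection and cancer-gene
cross-referencing.

A head-to-tail pair is two genes on the same strand at opposite
boundaries of one TAD: the upstream gene's 3' region (terminator window
or 3'-half gene body) overlaps one ±5 kb boundary window and the
downstream gene's promoter overlaps the other.  Upstream/downstream is
meant in the transcription sense — the upstream gene comes first along
the direction of transcription (smaller coordinates on ``+``, larger on
``-``), which makes the detection symmetric under genome mirroring.
The geometry is that of the Dcbld2/Cpox and CDK12/PSMD3 loci, where
repression of the promoter-anchored gene can restrain its 3'-anchored
partner.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core import GenomicInterval, GeneModel, overlaps, point_window
from .topology import Tad, tad_boundary_windows

__all__ = [
    "HeadTailPair",
    "MutationRecord",
    "read_gene_list",
    "read_mutations",
    "detect_head_to_tail",
    "pairs_to_frame",
    "oncogene_pair_summary",
    "promoter_mutation_summary",
]


@dataclass(frozen=True)
class HeadTailPair:
    """One detected head-to-tail boundary gene pair."""

    tad: GenomicInterval
    upstream_gene: GeneModel
    downstream_gene: GeneModel
    upstream_element: str        # "terminator" or "gene_body"
    boundary_side_up: str        # "left" / "right"
    boundary_side_down: str


@dataclass(frozen=True)
class MutationRecord:
    """A single somatic mutation call (1-based position, MAF-like)."""

    sample_id: str
    chrom: str
    position: int
    gene: str | None = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("mutation position must be >= 1 (1-based)")


def read_gene_list(path: str | Path, column: int = 0) -> set[str]:
    """Read a one-gene-per-row TSV (header line starting with '#' or
    'gene' is skipped)."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        sym = line.split("\t")[column]
        if sym.lower() in ("gene", "gene_id", "gene_name", "symbol"):
            continue
        out.add(sym)
    return out


def read_mutations(path: str | Path) -> list[MutationRecord]:
    """Read a MAF-like TSV with columns sample_id, chrom, pos[, gene]."""
    recs = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if parts[0].lower() in ("sample", "sample_id"):
            continue
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: need sample_id, chrom, pos")
        gene = parts[3] if len(parts) > 3 and parts[3] != "." else None
        recs.append(MutationRecord(parts[0], parts[1], int(parts[2]), gene))
    return recs


def detect_head_to_tail(tads: Sequence[GenomicInterval] | Sequence[Tad],
                        genes: Sequence[GeneModel],
                        promoter_flank: int = 1000,
                        terminator_flank: int = 5000,
                        boundary_flank: int = 5000,
                        chrom_sizes: Mapping[str, int] | None = None,
                        ) -> list[HeadTailPair]:
    """Enumerate head-to-tail gene pairs over all TADs.

    For each TAD and each same-strand gene pair (A, B) with A preceding B
    in the direction of transcription, a pair is reported when A's
    terminator window or 3'-half gene body overlaps one boundary window
    and B's promoter overlaps the *other* boundary window.  All
    qualifying pairs are reported (one record per TAD × A × B), in
    deterministic order.  Genes may extend outside the TAD.
    """
    if tads and isinstance(tads[0], Tad):
        windows = list(tads)  # type: ignore[arg-type]
    else:
        windows = tad_boundary_windows(tads, boundary_flank, chrom_sizes)

    by_chrom: dict[str, list[GeneModel]] = {}
    for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.end, g.gene_id)):
        by_chrom.setdefault(g.chrom, []).append(g)

    pairs: list[HeadTailPair] = []
    for tad in sorted(windows, key=lambda t: (t.interval.chrom,
                                              t.interval.start,
                                              t.interval.end)):
        chrom_genes = by_chrom.get(tad.interval.chrom, [])
        sides = {"left": tad.left_boundary, "right": tad.right_boundary}
        # genes anchored by their 3' region / their promoter, per side
        up_candidates: list[tuple[GeneModel, str, str]] = []
        down_candidates: list[tuple[GeneModel, str]] = []
        for g in chrom_genes:
            term = g.terminator(terminator_flank)
            tail = g.three_prime_half()
            prom = g.promoter(promoter_flank)
            for side, win in sides.items():
                if overlaps(term, win):
                    up_candidates.append((g, side, "terminator"))
                elif overlaps(tail, win):
                    up_candidates.append((g, side, "gene_body"))
                if overlaps(prom, win):
                    down_candidates.append((g, side))
        for a, side_a, element in up_candidates:
            for b, side_b in down_candidates:
                if a.gene_id == b.gene_id or side_a == side_b:
                    continue
                if a.strand != b.strand:
                    continue
                # A must precede B in transcription order
                ka = (a.start, a.end, a.gene_id)
                kb = (b.start, b.end, b.gene_id)
                if (ka >= kb) if a.strand == "+" else (ka <= kb):
                    continue
                pairs.append(HeadTailPair(tad.interval, a, b, element,
                                          side_a, side_b))
    pairs.sort(key=lambda p: (p.tad.chrom, p.tad.start, p.tad.end,
                              p.upstream_gene.gene_id,
                              p.downstream_gene.gene_id))
    return pairs


def pairs_to_frame(pairs: Sequence[HeadTailPair]) -> pd.DataFrame:
    rows = [{
        "chrom": p.tad.chrom,
        "tad_start": p.tad.start,
        "tad_end": p.tad.end,
        "upstream_gene": p.upstream_gene.gene_id,
        "downstream_gene": p.downstream_gene.gene_id,
        "strand": p.upstream_gene.strand,
        "upstream_element": p.upstream_element,
        "boundary_side_up": p.boundary_side_up,
        "boundary_side_down": p.boundary_side_down,
    } for p in pairs]
    return pd.DataFrame(rows, columns=[
        "chrom", "tad_start", "tad_end", "upstream_gene", "downstream_gene",
        "strand", "upstream_element", "boundary_side_up", "boundary_side_down"])


def _gene_symbol(g: GeneModel) -> str:
    return g.gene_name or g.gene_id


def oncogene_pair_summary(pairs: Sequence[HeadTailPair],
                          oncogenes: Iterable[str],
                          tsgs: Iterable[str]) -> pd.DataFrame:
    """Cross-reference pair members with oncogene / tumour-suppressor
    lists.

    Rows: (role in the pair) × (gene class), with counts, fractions and
    the explicit denominator (number of pairs).  The 3'-anchored role is
    the upstream gene (gene body/terminator on a boundary); the
    promoter-anchored role is the downstream gene.
    """
    onco, tsg = set(oncogenes), set(tsgs)
    n = len(pairs)
    rows = []
    for role, getter in (("3prime_anchored", lambda p: p.upstream_gene),
                         ("promoter_anchored", lambda p: p.downstream_gene)):
        syms = [_gene_symbol(getter(p)) for p in pairs]
        n_onco = sum(s in onco for s in syms)
        n_tsg = sum(s in tsg for s in syms)
        n_neither = n - sum((s in onco) or (s in tsg) for s in syms)
        for klass, cnt in (("oncogene", n_onco), ("tsg", n_tsg),
                           ("neither", n_neither)):
            rows.append((role, klass, cnt, cnt / n if n else 0.0, n))
    return pd.DataFrame(rows, columns=["role", "gene_class", "count",
                                       "fraction", "n_pairs"])


def promoter_mutation_summary(mutations: Sequence[MutationRecord],
                              pairs: Sequence[HeadTailPair],
                              promoter_flank: int = 1000,
                              oncogenes: Iterable[str] = (),
                              ) -> tuple[pd.DataFrame, float, pd.DataFrame]:
    """Per-gene promoter-mutation sample counts for the promoter-anchored
    non-oncogenes of a pair set.

    A sample counts at most once per gene regardless of how many of its
    mutations fall in that promoter.  Returns (per-gene table, fraction of
    all distinct samples with >= 1 promoter hit, gene × sample incidence
    matrix).  Mutation positions are 1-based and converted internally.
    """
    onco = set(oncogenes)
    targets: dict[str, GenomicInterval] = {}
    for p in pairs:
        g = p.downstream_gene
        if _gene_symbol(g) in onco:
            continue
        targets[g.gene_id] = point_window(g.chrom, g.tss, promoter_flank)

    hits: dict[str, set[str]] = {gid: set() for gid in targets}
    all_samples = {m.sample_id for m in mutations}
    for m in mutations:
        pos0 = m.position - 1
        for gid, win in targets.items():
            if win.chrom == m.chrom and win.start <= pos0 < win.end:
                hits[gid].add(m.sample_id)

    per_gene = pd.DataFrame(
        [(gid, len(samples)) for gid, samples in sorted(hits.items())],
        columns=["gene_id", "n_samples_mutated"])
    samples_hit = set().union(*hits.values()) if hits else set()
    fraction = len(samples_hit) / len(all_samples) if all_samples else 0.0

    incidence = pd.DataFrame(0, index=sorted(hits),
                             columns=sorted(all_samples), dtype=int)
    for gid, samples in hits.items():
        for s in samples:
            incidence.loc[gid, s] = 1
    return per_gene, fraction, incidence
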