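"""Genomic coordinate conventions, interval algebra and standard-format I/O.

Every coordinate in this package is 0-based half-open (``[start, end)``),
the native BED convention; GTF (1-based closed) is converted on read.
Overlap always means at least one shared base pair and never consults
strand — strand matters only when deriving promoter, terminator and
head-to-tail geometry from gene models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "Loop",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_bed",
    "write_bed",
    "read_bedpe",
    "write_bedpe",
    "read_gtf_genes",
    "write_gtf",
    "read_bedgraph",
    "extend_intervals",
    "overlaps",
    "any_overlap",
    "point_window",
]

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``chrom:[start, end)``.

    The unit of all overlap algebra: ChIP-seq peaks, TAD spans, boundary
    windows, promoters and terminators are all plain intervals.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be a non-empty string")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return overlaps(self, other)

    def __str__(self) -> str:  # pragma: no cover - debugging aid
        return f"{self.chrom}:{self.start}-{self.end}({self.strand})"


def point_window(chrom: str, point: int, flank: int) -> GenomicInterval:
    """Symmetric window ``[point - flank, point + flank)`` clamped at 0.

    This is the "±flank around a position" rule used for promoters
    (TSS ± 1 kb), terminators (TES ± 5 kb) and TAD-boundary windows
    (edge ± 5 kb).
    """
    if flank < 1:
        raise ValueError("flank must be >= 1 for a point window")
    return GenomicInterval(chrom, max(0, point - flank), point + flank)


@dataclass(frozen=True)
class GeneModel:
    """A gene collapsed to a single model per gene_id.

    ``tss``/``tes`` are strand-aware: the TSS is the 5' end of the span
    (``start`` on ``+``, ``end - 1`` on ``-``) and the TES the 3' end.
    Multi-isoform genes are collapsed to the union span, so "the end of
    the annotated transcript" is the outermost 3' position.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    gene_name: str | None = None
    exons: tuple[GenomicInterval, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not (0 <= self.start < self.end):
            raise ValueError(f"gene {self.gene_id}: need 0 <= start < end")
        for ex in self.exons:
            if ex.start < self.start or ex.end > self.end:
                raise ValueError(
                    f"gene {self.gene_id}: exon {ex} outside span "
                    f"[{self.start}, {self.end})"
                )

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end,
                               self.strand, name=self.gene_id)

    def promoter(self, flank: int = 1000) -> GenomicInterval:
        """TSS ± flank window."""
        return point_window(self.chrom, self.tss, flank)

    def terminator(self, flank: int = 5000) -> GenomicInterval:
        """TES ± flank window (the transcript-end region)."""
        return point_window(self.chrom, self.tes, flank)

    def three_prime_half(self) -> GenomicInterval:
        """The 3' half of the gene body (strand-aware)."""
        mid = (self.start + self.end) // 2
        if self.strand == "+":
            return GenomicInterval(self.chrom, mid, self.end, self.strand)
        return GenomicInterval(self.chrom, self.start, max(mid, self.start + 1),
                               self.strand)

    def sorted_exons(self) -> list[GenomicInterval]:
        """Exons in genomic order, overlapping ones merged."""
        merged: list[list[int]] = []
        for ex in sorted(self.exons, key=lambda e: (e.start, e.end)):
            if merged and ex.start <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], ex.end)
            else:
                merged.append([ex.start, ex.end])
        return [GenomicInterval(self.chrom, s, e, self.strand) for s, e in merged]

    def introns(self) -> list[GenomicInterval]:
        """Introns in *transcription* order (first intron first)."""
        exons = self.sorted_exons()
        out = []
        for a, b in zip(exons, exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.chrom, a.end, b.start, self.strand))
        if self.strand == "-":
            out.reverse()
        return out


@dataclass
class Loop:
    """A paired-anchor chromatin interaction (one BEDPE row).

    Anchors are stored in canonical order (anchor1 <= anchor2 by
    chrom, start, end); trans records are kept but flagged.
    ``labels1``/``labels2`` and ``category`` are filled in by the
    topology stage.
    """

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    name: str | None = None
    score: float | None = None
    labels1: frozenset[str] = frozenset()
    labels2: frozenset[str] = frozenset()
    category: str | None = None

    def __post_init__(self) -> None:
        k1 = (self.anchor1.chrom, self.anchor1.start, self.anchor1.end)
        k2 = (self.anchor2.chrom, self.anchor2.start, self.anchor2.end)
        if k2 < k1:
            self.anchor1, self.anchor2 = self.anchor2, self.anchor1
            self.labels1, self.labels2 = self.labels2, self.labels1

    @property
    def is_trans(self) -> bool:
        return self.anchor1.chrom != self.anchor2.chrom

    def sort_key(self):
        a, b = self.anchor1, self.anchor2
        return (a.chrom, a.start, a.end, b.chrom, b.start, b.end)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a 2-column ``chrom<TAB>length`` file."""
    sizes: dict[str, int] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: expected 2 columns")
        length = int(parts[1])
        if length <= 0:
            raise ValueError(f"{path}:{lineno}: chromosome length must be > 0")
        sizes[parts[0]] = length
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, length in sizes.items():
            fh.write(f"{chrom}\t{length}\n")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6; coordinates are kept as-is (BED is already 0-based
    half-open).  Strand comes from column 6 when present, else ``.``."""
    out: list[GenomicInterval] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: BED needs >= 3 tab-separated columns")
        try:
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed BED line: {exc}") from None
        if start >= end:
            raise ValueError(f"{path}:{lineno}: start >= end ({start} >= {end})")
        name = parts[3] if len(parts) > 3 and parts[3] != "." else None
        score = None
        if len(parts) > 4 and parts[4] not in (".", ""):
            score = float(parts[4])
        strand = parts[5] if len(parts) > 5 else "."
        out.append(GenomicInterval(chrom, start, end, strand, name, score))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path,
              ncols: int = 6) -> None:
    """Write BED; ``ncols`` 3 or 6.  Missing name/score become ``.``/0."""
    if ncols not in (3, 6):
        raise ValueError("ncols must be 3 or 6")
    with open(path, "w") as fh:
        for iv in intervals:
            if ncols == 3:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                name = iv.name if iv.name is not None else "."
                score = _fmt_num(iv.score) if iv.score is not None else "0"
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")


def _fmt_num(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def read_bedpe(path: str | Path) -> list[Loop]:
    """Read BEDPE loop anchors; anchors canonicalized to genomic order."""
    loops: list[Loop] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 6:
            raise ValueError(f"{path}:{lineno}: BEDPE needs >= 6 columns")
        try:
            a = GenomicInterval(parts[0], int(parts[1]), int(parts[2]))
            b = GenomicInterval(parts[3], int(parts[4]), int(parts[5]))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed BEDPE line: {exc}") from None
        name = parts[6] if len(parts) > 6 and parts[6] != "." else None
        score = None
        if len(parts) > 7 and parts[7] not in (".", ""):
            score = float(parts[7])
        loops.append(Loop(a, b, name=name, score=score))
    return loops


def write_bedpe(loops: Iterable[Loop], path: str | Path,
                with_category: bool = False) -> None:
    with open(path, "w") as fh:
        for lp in loops:
            a, b = lp.anchor1, lp.anchor2
            cols = [a.chrom, a.start, a.end, b.chrom, b.start, b.end,
                    lp.name if lp.name is not None else ".",
                    _fmt_num(lp.score) if lp.score is not None else "."]
            if with_category:
                cols.append(lp.category if lp.category is not None else ".")
            fh.write("\t".join(str(c) for c in cols) + "\n")


def _parse_gtf_attributes(attr: str) -> dict[str, str]:
    out = {}
    for chunk in attr.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if " " not in chunk:
            continue
        key, val = chunk.split(" ", 1)
        out[key] = val.strip().strip('"')
    return out


def read_gtf_genes(path: str | Path) -> list[GeneModel]:
    """Read a GTF into one :class:`GeneModel` per ``gene_id``.

    GTF is 1-based closed; converted to 0-based half-open on read
    (``start - 1``, ``end``).  If a gene has exon records but no ``gene``
    feature line, the gene span is synthesized as the exon envelope.
    Multiple transcripts collapse into one model (union span, merged
    exons).
    """
    spans: dict[str, list] = {}  # gene_id -> [chrom, strand, start, end, name, exons]
    order: list[str] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 9:
            raise ValueError(f"{path}:{lineno}: GTF needs 9 columns")
        chrom, _src, feature, start1, end1, _score, strand, _frame, attr = parts[:9]
        if feature not in ("gene", "exon", "transcript"):
            continue
        if strand not in ("+", "-"):
            raise ValueError(f"{path}:{lineno}: unknown strand {strand!r}")
        attrs = _parse_gtf_attributes(attr)
        gene_id = attrs.get("gene_id")
        if not gene_id:
            raise ValueError(f"{path}:{lineno}: missing gene_id attribute")
        start, end = int(start1) - 1, int(end1)
        if gene_id not in spans:
            spans[gene_id] = [chrom, strand, None, None, attrs.get("gene_name"), []]
            order.append(gene_id)
        rec = spans[gene_id]
        if rec[0] != chrom or rec[1] != strand:
            raise ValueError(f"{path}:{lineno}: inconsistent chrom/strand for {gene_id}")
        if feature == "gene":
            rec[2] = start if rec[2] is None else min(rec[2], start)
            rec[3] = end if rec[3] is None else max(rec[3], end)
            if rec[4] is None:
                rec[4] = attrs.get("gene_name")
        elif feature == "exon":
            rec[5].append((start, end))

    genes: list[GeneModel] = []
    for gid in order:
        chrom, strand, gstart, gend, gname, exon_coords = spans[gid]
        if gstart is None:
            if not exon_coords:
                raise ValueError(f"gene {gid}: no gene feature and no exons")
            gstart = min(s for s, _ in exon_coords)
            gend = max(e for _, e in exon_coords)
        else:
            # widen to the exon envelope if exons spill past the gene line
            if exon_coords:
                gstart = min(gstart, min(s for s, _ in exon_coords))
                gend = max(gend, max(e for _, e in exon_coords))
        exons = tuple(GenomicInterval(chrom, s, e, strand) for s, e in
                      sorted(exon_coords))
        genes.append(GeneModel(gid, chrom, strand, gstart, gend,
                               gene_name=gname, exons=exons))
    return genes


def write_gtf(genes: Iterable[GeneModel], path: str | Path,
              source: str = "tadboundary") -> None:
    """Write gene + exon features, converting back to 1-based closed."""
    with open(path, "w") as fh:
        for g in genes:
            attr = f'gene_id "{g.gene_id}";'
            if g.gene_name:
                attr += f' gene_name "{g.gene_name}";'
            fh.write("\t".join([g.chrom, source, "gene", str(g.start + 1),
                                str(g.end), ".", g.strand, ".", attr]) + "\n")
            for ex in g.sorted_exons():
                fh.write("\t".join([g.chrom, source, "exon", str(ex.start + 1),
                                    str(ex.end), ".", g.strand, ".", attr]) + "\n")


def read_bedgraph(path: str | Path) -> list[GenomicInterval]:
    """Read a bedGraph coverage track; the 4th column is the value,
    stored in ``score``."""
    out: list[GenomicInterval] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track")):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 4:
            raise ValueError(f"{path}:{lineno}: bedGraph needs 4 columns")
        out.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2]),
                                   score=float(parts[3])))
    return out


# ---------------------------------------------------------------------------
# interval algebra
# ---------------------------------------------------------------------------

def extend_intervals(intervals: Sequence[GenomicInterval], flank: int,
                     chrom_sizes: Mapping[str, int]) -> list[GenomicInterval]:
    """Extend each interval by ``flank`` bp on both sides (bedtools slop),
    clamping to ``[0, chrom length)``.  Order preserved."""
    if flank < 0:
        raise ValueError("flank must be >= 0")
    out = []
    for iv in intervals:
        if iv.chrom not in chrom_sizes:
            raise KeyError(f"chromosome {iv.chrom!r} absent from chrom_sizes")
        L = chrom_sizes[iv.chrom]
        out.append(GenomicInterval(iv.chrom, max(0, iv.start - flank),
                                   min(L, iv.end + flank), iv.strand,
                                   iv.name, iv.score))
    return out


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff a and b share >= 1 bp (half-open; strand ignored)."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


class IntervalIndex:
    """Merged-interval lookup structure for fast any-overlap queries.

    Per chromosome, the subject intervals are merged into disjoint sorted
    blocks; a query overlaps some subject interval iff it overlaps a block.
    """

    def __init__(self, intervals: Iterable[GenomicInterval]):
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            per_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for chrom, pairs in per_chrom.items():
            pairs.sort()
            merged: list[list[int]] = []
            for s, e in pairs:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            self._starts[chrom] = np.array([m[0] for m in merged], dtype=np.int64)
            self._ends[chrom] = np.array([m[1] for m in merged], dtype=np.int64)

    def overlaps_point(self, chrom: str, pos: int) -> bool:
        return self.overlaps_interval(GenomicInterval(chrom, pos, pos + 1))

    def overlaps_interval(self, iv: GenomicInterval) -> bool:
        starts = self._starts.get(iv.chrom)
        if starts is None or len(starts) == 0:
            return False
        idx = int(np.searchsorted(starts, iv.end, side="left"))
        return idx > 0 and int(self._ends[iv.chrom][idx - 1]) > iv.start


def any_overlap(query: Sequence[GenomicInterval],
                subject: Iterable[GenomicInterval]) -> np.ndarray:
    """Boolean mask over ``query``: True where the query interval overlaps
    at least one subject interval.  Equivalent to the all-pairs check."""
    index = IntervalIndex(subject)
    return np.array([index.overlaps_interval(q) for q in query], dtype=bool)
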