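"""TAD-boundary windows, loop merging and interaction-category classification.

Each TAD contributes one "boundary interaction": the pair of ±5 kb
windows around its two edges.  Loops and boundary pairs are classified
by the chromatin / gene elements their anchors overlap; the headline
class is a loop anchored by a p300-only peak on one side and H3K27me3
on the other (a candidate repressive p300–PRC2 loop).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core import GenomicInterval, GeneModel, IntervalIndex, Loop, point_window

__all__ = [
    "Tad",
    "tad_boundary_windows",
    "merge_loops",
    "AnchorAnnotator",
    "annotate_anchor",
    "classify_interaction",
    "classify_loops",
    "classify_tad_boundaries",
    "count_interaction_categories",
    "CHROMATIN_PRECEDENCE",
    "GENE_PRECEDENCE",
]


@dataclass(frozen=True)
class Tad:
    """A topologically associating domain with derived boundary windows."""

    interval: GenomicInterval
    left_boundary: GenomicInterval
    right_boundary: GenomicInterval


def tad_boundary_windows(tads: Sequence[GenomicInterval], flank: int = 5000,
                         chrom_sizes: Mapping[str, int] | None = None) -> list[Tad]:
    """±``flank`` windows around each TAD edge.

    TADs shorter than twice the flank (whose windows would overlap) are
    skipped with a warning.
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    out: list[Tad] = []
    skipped = 0
    for tad in tads:
        if tad.length <= 2 * flank:
            skipped += 1
            continue
        left = point_window(tad.chrom, tad.start, flank)
        right = point_window(tad.chrom, tad.end, flank)
        if chrom_sizes is not None and tad.chrom in chrom_sizes:
            L = chrom_sizes[tad.chrom]
            left = GenomicInterval(tad.chrom, left.start, min(left.end, L))
            right = GenomicInterval(tad.chrom, right.start, min(right.end, L))
        out.append(Tad(tad, left, right))
    if skipped:
        warnings.warn(f"skipped {skipped} TAD(s) shorter than 2*flank={2*flank} bp")
    return out


# ---------------------------------------------------------------------------
# loop merging
# ---------------------------------------------------------------------------

def merge_loops(loop_sets: Sequence[Sequence[Loop]] | Sequence[Loop],
                tolerance: int = 25000) -> list[Loop]:
    """Merge near-duplicate loops across call sets.

    Two loops are duplicates when both anchor pairs match by chromosome
    and their anchor centers lie within ``tolerance`` bp; duplicate
    groups (transitive closure) collapse to their genomically first
    member.  Output sorted by (anchor1, anchor2); idempotent.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    flat: list[Loop] = []
    for item in loop_sets:
        if isinstance(item, Loop):
            flat.append(item)
        else:
            flat.extend(item)
    if not flat:
        return []
    flat = sorted(flat, key=lambda lp: lp.sort_key())
    parent = list(range(len(flat)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    centers1 = [lp.anchor1.midpoint for lp in flat]
    centers2 = [lp.anchor2.midpoint for lp in flat]
    # sorted by anchor1 start, so a sliding window bounds the candidates;
    # the slack accounts for midpoints of anchors of differing widths
    slack = tolerance + max(lp.anchor1.length for lp in flat)
    for i in range(len(flat)):
        for j in range(i + 1, len(flat)):
            if flat[j].anchor1.chrom != flat[i].anchor1.chrom:
                break
            if flat[j].anchor1.start - flat[i].anchor1.start > slack:
                break
            if (abs(centers1[i] - centers1[j]) <= tolerance
                    and flat[i].anchor2.chrom == flat[j].anchor2.chrom
                    and abs(centers2[i] - centers2[j]) <= tolerance):
                union(i, j)
    keep = [flat[i] for i in range(len(flat)) if find(i) == i]
    return sorted(keep, key=lambda lp: lp.sort_key())


# ---------------------------------------------------------------------------
# anchor annotation
# ---------------------------------------------------------------------------

class AnchorAnnotator:
    """Assign chromatin/gene labels to interaction anchors.

    Labels: ``p300_only``, ``H3K27me3``, ``promoter`` (TSS ± 1 kb),
    ``terminator`` (TES ± 5 kb), ``gene_body`` (full gene span), plus the
    exclusion labels ``gene`` (overlaps a gene but neither mark) and
    ``intergenic`` (overlaps nothing of the above).
    """

    def __init__(self, genes: Sequence[GeneModel],
                 p300_only: Sequence[GenomicInterval] = (),
                 h3k27me3: Sequence[GenomicInterval] = (),
                 promoter_flank: int = 1000,
                 terminator_flank: int = 5000):
        self._p300 = IntervalIndex(p300_only)
        self._k27me3 = IntervalIndex(h3k27me3)
        self._promoters = IntervalIndex(g.promoter(promoter_flank) for g in genes)
        self._terminators = IntervalIndex(g.terminator(terminator_flank) for g in genes)
        self._bodies = IntervalIndex(g.span for g in genes)

    def __call__(self, anchor: GenomicInterval) -> frozenset[str]:
        labels = set()
        if self._p300.overlaps_interval(anchor):
            labels.add("p300_only")
        if self._k27me3.overlaps_interval(anchor):
            labels.add("H3K27me3")
        if self._promoters.overlaps_interval(anchor):
            labels.add("promoter")
        if self._terminators.overlaps_interval(anchor):
            labels.add("terminator")
        has_gene = self._bodies.overlaps_interval(anchor)
        if has_gene:
            labels.add("gene_body")
        marked = "p300_only" in labels or "H3K27me3" in labels
        if has_gene and not marked:
            labels.add("gene")
        if not has_gene and not marked and not labels:
            labels.add("intergenic")
        return frozenset(labels)


def annotate_anchor(anchor: GenomicInterval, genes: Sequence[GeneModel],
                    p300_only: Sequence[GenomicInterval] = (),
                    h3k27me3: Sequence[GenomicInterval] = (),
                    promoter_flank: int = 1000,
                    terminator_flank: int = 5000) -> frozenset[str]:
    """One-shot :class:`AnchorAnnotator` call (build the annotator once
    when labelling many anchors)."""
    ann = AnchorAnnotator(genes, p300_only, h3k27me3,
                          promoter_flank, terminator_flank)
    return ann(anchor)


# ---------------------------------------------------------------------------
# interaction categories
# ---------------------------------------------------------------------------

#: (label on one anchor, label on the other anchor, category) in
#: precedence order — the first matching pattern wins, so the headline
#: p300only-H3K27me3 class is never absorbed by a broader one.
CHROMATIN_PRECEDENCE: tuple[tuple[str, str, str], ...] = (
    ("p300_only", "H3K27me3", "p300only-H3K27me3"),
    ("H3K27me3", "H3K27me3", "H3K27me3-H3K27me3"),
    ("p300_only", "p300_only", "p300only-p300only"),
    ("promoter", "promoter", "PP"),
    ("promoter", "terminator", "PT"),
    ("promoter", "gene_body", "PG"),
    ("gene_body", "gene_body", "GG"),
    ("gene", "gene", "gene-gene"),
    ("gene", "intergenic", "gene-intergenic"),
    ("intergenic", "intergenic", "intergenic-intergenic"),
)

#: gene-element-only universe (promoter/terminator/gene-body pair types).
GENE_PRECEDENCE: tuple[tuple[str, str, str], ...] = (
    ("promoter", "promoter", "PP"),
    ("promoter", "terminator", "PT"),
    ("promoter", "gene_body", "PG"),
    ("terminator", "terminator", "TT"),
    ("terminator", "gene_body", "TG"),
    ("gene_body", "gene_body", "GG"),
)


def classify_interaction(labels1: Iterable[str], labels2: Iterable[str],
                         precedence: Sequence[tuple[str, str, str]] | None = None,
                         ) -> str:
    """Category of an anchor pair: the first precedence pattern matched
    in either orientation; symmetric in anchor order; ``"other"`` when
    nothing matches."""
    if precedence is None:
        precedence = CHROMATIN_PRECEDENCE
    s1, s2 = set(labels1), set(labels2)
    for x, y, cat in precedence:
        if (x in s1 and y in s2) or (y in s1 and x in s2):
            return cat
    return "other"


def _precedence_for_mode(mode: str):
    if mode == "chromatin":
        return CHROMATIN_PRECEDENCE
    if mode == "genes":
        return GENE_PRECEDENCE
    raise ValueError(f"unknown mode {mode!r} (expected 'chromatin' or 'genes')")


def classify_loops(loops: Sequence[Loop], annotator: AnchorAnnotator,
                   mode: str = "chromatin",
                   precedence: Sequence[tuple[str, str, str]] | None = None,
                   ) -> list[Loop]:
    """Annotate both anchors of each loop and assign its category
    (in place; the list is returned for chaining)."""
    prec = precedence if precedence is not None else _precedence_for_mode(mode)
    for lp in loops:
        lp.labels1 = annotator(lp.anchor1)
        lp.labels2 = annotator(lp.anchor2)
        lp.category = classify_interaction(lp.labels1, lp.labels2, prec)
    return loops


def classify_tad_boundaries(tads: Sequence[Tad], annotator: AnchorAnnotator,
                            mode: str = "chromatin",
                            precedence: Sequence[tuple[str, str, str]] | None = None,
                            ) -> list[str]:
    """Category of each TAD's (left window, right window) boundary pair."""
    prec = precedence if precedence is not None else _precedence_for_mode(mode)
    return [classify_interaction(annotator(t.left_boundary),
                                 annotator(t.right_boundary), prec)
            for t in tads]


def count_interaction_categories(categories: Iterable[str]) -> pd.DataFrame:
    """Count/fraction table over category strings; fractions sum to 1."""
    cats = list(categories)
    counts = pd.Series(cats).value_counts() if cats else pd.Series(dtype=int)
    rows = [(cat, int(n), n / len(cats)) for cat, n in counts.items()]
    df = pd.DataFrame(rows, columns=["category", "count", "fraction"])
    return df.sort_values(["count", "category"],
                          ascending=[False, True]).reset_index(drop=True)
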