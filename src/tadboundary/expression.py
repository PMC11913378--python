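"""Expression comparisons between interaction classes.

Genes looped to p300-only anchors are split by H3K27me3 overlap and their
log2(TPM+1) distributions compared with a two-sample rank-sum test
(ECDF view); boundary-pair classes (PT/PG/PP) are compared with the
Kruskal-Wallis test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import GenomicInterval, GeneModel, IntervalIndex, Loop, overlaps

__all__ = [
    "GroupedExpression",
    "read_expression",
    "log_expr",
    "assign_loop_gene_groups",
    "Ecdf",
    "ecdf",
    "rank_sum_test",
    "kruskal_wallis",
    "boundary_pair_expression",
]

logger = logging.getLogger(__name__)


@dataclass
class GroupedExpression:
    """log2(TPM+1) values of one comparison group."""

    label: str
    gene_ids: list[str]
    values: np.ndarray

    @property
    def n(self) -> int:
        return len(self.values)


def read_expression(path: str | Path, gene_id_col: str = "gene_id",
                    tpm_col: str = "TPM") -> pd.Series:
    """Read a gene-quantification TSV into a gene_id -> TPM series."""
    df = pd.read_csv(path, sep="\t")
    if gene_id_col not in df.columns or tpm_col not in df.columns:
        raise ValueError(f"expected columns {gene_id_col!r} and {tpm_col!r}, "
                         f"found {list(df.columns)}")
    tpm = df.set_index(gene_id_col)[tpm_col].astype(float)
    if (tpm < 0).any():
        raise ValueError("TPM values must be >= 0")
    return tpm


def log_expr(tpm) -> np.ndarray:
    """log2(TPM + 1)."""
    return np.log2(np.asarray(tpm, dtype=float) + 1.0)


def assign_loop_gene_groups(loops: Sequence[Loop],
                            genes: Sequence[GeneModel],
                            h3k27me3: Sequence[GenomicInterval],
                            expression: Mapping[str, float] | pd.Series,
                            ) -> tuple[GroupedExpression, GroupedExpression]:
    """Split genes looped to a p300-only anchor by H3K27me3 overlap.

    Loops must already carry anchor labels.  For every loop with a
    ``p300_only`` label on one anchor, genes whose span overlaps the
    *other* anchor enter the comparison; each gene counts once even if it
    appears in several qualifying loops.  Genes without an expression
    record are skipped (logged).
    Returns (H3K27me3 group, non-H3K27me3 group) of log2(TPM+1) values.
    """
    k27 = IntervalIndex(h3k27me3)
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    selected: dict[str, GeneModel] = {}
    for lp in loops:
        partners = []
        if "p300_only" in lp.labels1:
            partners.append(lp.anchor2)
        if "p300_only" in lp.labels2:
            partners.append(lp.anchor1)
        for anchor in partners:
            for g in by_chrom.get(anchor.chrom, []):
                if overlaps(g.span, anchor):
                    selected[g.gene_id] = g

    expr = expression if isinstance(expression, pd.Series) else pd.Series(expression)
    with_mark, without = [], []
    n_missing = 0
    for gid in sorted(selected):
        g = selected[gid]
        if gid not in expr.index:
            n_missing += 1
            continue
        val = float(log_expr(expr[gid]))
        (with_mark if k27.overlaps_interval(g.span) else without).append((gid, val))
    if n_missing:
        logger.warning("%d looped gene(s) had no expression record", n_missing)
    return (
        GroupedExpression("H3K27me3", [g for g, _ in with_mark],
                          np.array([v for _, v in with_mark])),
        GroupedExpression("non-H3K27me3", [g for g, _ in without],
                          np.array([v for _, v in without])),
    )


class Ecdf:
    """Right-continuous empirical CDF: F(x) = #{values <= x} / n."""

    def __init__(self, values):
        values = np.asarray(values, dtype=float)
        if values.size == 0:
            raise ValueError("ECDF needs at least one value")
        self.sorted = np.sort(values)
        self.n = values.size

    def __call__(self, x) -> np.ndarray | float:
        res = np.searchsorted(self.sorted, np.asarray(x, dtype=float),
                              side="right") / self.n
        return float(res) if np.isscalar(x) else res

    @property
    def steps(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, F(x)) at the observed points (plot-ready)."""
        return self.sorted, np.arange(1, self.n + 1) / self.n


def ecdf(values) -> Ecdf:
    return Ecdf(values)


def rank_sum_test(group_a, group_b, alternative: str = "two-sided",
                  method: str = "auto") -> tuple[float, float]:
    """Two-sample Wilcoxon rank-sum (Mann-Whitney U) test.

    Exact enumeration for small untied samples, tie-corrected normal
    approximation otherwise (scipy's ``auto`` policy).  Returns (U of the
    first group, p-value).
    """
    a, b = np.asarray(group_a, float), np.asarray(group_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with chi-square p (k-1 df)."""
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    res = stats.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)


def boundary_pair_expression(categories: Sequence[str],
                             tads, genes: Sequence[GeneModel],
                             expression: Mapping[str, float] | pd.Series,
                             which: Iterable[str] = ("PT", "PG", "PP"),
                             boundary_flank: int = 5000,
                             dedupe: bool = True) -> list[GroupedExpression]:
    """Group boundary-gene expression by boundary-pair category.

    Each TAD of a selected category contributes the log2(TPM+1) of the
    genes overlapping its boundary windows, labelled by the category.
    With ``dedupe`` a gene counts once per category.
    """
    expr = expression if isinstance(expression, pd.Series) else pd.Series(expression)
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    buckets: dict[str, dict[str, float]] = {c: {} for c in which}
    for tad, cat in zip(tads, categories):
        if cat not in buckets:
            continue
        for win in (tad.left_boundary, tad.right_boundary):
            for g in by_chrom.get(win.chrom, []):
                if overlaps(g.span, win) and g.gene_id in expr.index:
                    buckets[cat][g.gene_id] = float(log_expr(expr[g.gene_id]))
    out = []
    for cat in which:
        ids = sorted(buckets[cat])
        out.append(GroupedExpression(cat, ids,
                                     np.array([buckets[cat][i] for i in ids])))
    return out
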