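"""p300-only peak discovery, peak feature annotation and signal matrices.

A "p300-only" peak is a p300 ChIP-seq peak that overlaps none of the
H3K27ac peaks after the H3K27ac set has been extended by ±1 kb — the
operational definition of a candidate H3K27ac-independent (potentially
repressive) p300 site.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import GenomicInterval, GeneModel, IntervalIndex, any_overlap, point_window

__all__ = [
    "PeakClassParams",
    "SignalMatrix",
    "p300_only_peaks",
    "annotate_feature",
    "annotate_features",
    "feature_distribution",
    "signal_matrix",
    "FEATURE_LABELS",
]

#: feature labels in priority order (first match wins for a midpoint
#: satisfying several); "3'-end" covers the TES-proximal region including
#: <1 kb downstream of the TES.
FEATURE_LABELS = (
    "promoter",
    "first intron",
    "other intron",
    "exon",
    "3'-end",
    "distal intergenic",
)


@dataclass
class PeakClassParams:
    """Parameters of the peak classification stage.

    ``k27ac_flank``: bp added to each side of every H3K27ac peak before
    the p300 overlap test (±1 kb in the reference analysis).
    ``promoter_flank``: half-width of the TSS promoter window.
    ``tes_flank``: half-width of the 3'-end window around the TES.
    """

    k27ac_flank: int = 1000
    promoter_flank: int = 1000
    tes_flank: int = 1000
    feature_priority: tuple[str, ...] = FEATURE_LABELS

    def __post_init__(self) -> None:
        if self.k27ac_flank < 0 or self.promoter_flank < 0 or self.tes_flank < 0:
            raise ValueError("flanks must be >= 0")
        missing = set(FEATURE_LABELS) - set(self.feature_priority)
        if missing:
            raise ValueError(f"feature_priority missing labels: {sorted(missing)}")


def p300_only_peaks(
    p300: Sequence[GenomicInterval],
    h3k27ac: Sequence[GenomicInterval],
    params: PeakClassParams | None = None,
    chrom_sizes: Mapping[str, int] | None = None,
) -> tuple[list[GenomicInterval], list[GenomicInterval]]:
    """Partition p300 peaks into (p300_only, p300_shared).

    H3K27ac peaks are extended by ``params.k27ac_flank`` on both sides
    (clamped to the chromosome when sizes are given); p300 peaks touching
    none of the extended set are "p300 only", the rest are shared.  The
    two lists are a disjoint partition of the input, order preserved.
    """
    params = params or PeakClassParams()
    flank = params.k27ac_flank
    extended = []
    for iv in h3k27ac:
        hi = iv.end + flank
        if chrom_sizes is not None and iv.chrom in chrom_sizes:
            hi = min(hi, chrom_sizes[iv.chrom])
        extended.append(GenomicInterval(iv.chrom, max(0, iv.start - flank), hi))
    mask = any_overlap(p300, extended)
    only = [p for p, hit in zip(p300, mask) if not hit]
    shared = [p for p, hit in zip(p300, mask) if hit]
    return only, shared


class _FeatureIndex:
    """Per-label merged interval indexes for midpoint feature lookup."""

    def __init__(self, genes: Sequence[GeneModel], params: PeakClassParams):
        promoters, first_introns, other_introns, exons, tes_windows, bodies = \
            [], [], [], [], [], []
        for g in genes:
            promoters.append(g.promoter(params.promoter_flank))
            tes_windows.append(g.terminator(params.tes_flank))
            exons.extend(g.sorted_exons())
            intr = g.introns()
            if intr:
                first_introns.append(intr[0])
                other_introns.extend(intr[1:])
            bodies.append(g.span)
        self.index = {
            "promoter": IntervalIndex(promoters),
            "first intron": IntervalIndex(first_introns),
            "other intron": IntervalIndex(other_introns),
            "exon": IntervalIndex(exons),
            "3'-end": IntervalIndex(tes_windows),
        }
        self.priority = [l for l in params.feature_priority
                         if l != "distal intergenic"]

    def label(self, chrom: str, pos: int) -> str:
        for lab in self.priority:
            if self.index[lab].overlaps_point(chrom, pos):
                return lab
        return "distal intergenic"


def annotate_feature(peak: GenomicInterval, genes: Sequence[GeneModel],
                     params: PeakClassParams | None = None) -> str:
    """Genomic-feature label of one peak, assigned by its midpoint."""
    params = params or PeakClassParams()
    return _FeatureIndex(genes, params).label(peak.chrom, peak.midpoint)


def annotate_features(peaks: Sequence[GenomicInterval],
                      genes: Sequence[GeneModel],
                      params: PeakClassParams | None = None) -> list[str]:
    """Vectorized :func:`annotate_feature` over a peak list."""
    params = params or PeakClassParams()
    idx = _FeatureIndex(genes, params)
    return [idx.label(p.chrom, p.midpoint) for p in peaks]


def feature_distribution(peaks: Sequence[GenomicInterval],
                         genes: Sequence[GeneModel],
                         params: PeakClassParams | None = None) -> pd.DataFrame:
    """Counts and proportions of feature labels over a peak set
    (the pie-chart input).  Proportions sum to 1 for non-empty input."""
    params = params or PeakClassParams()
    if len(peaks) == 0:
        warnings.warn("feature_distribution called with an empty peak set")
        return pd.DataFrame(columns=["feature", "count", "proportion"])
    labels = annotate_features(peaks, genes, params)
    counts = pd.Series(labels).value_counts()
    rows = [(lab, int(counts.get(lab, 0)), counts.get(lab, 0) / len(peaks))
            for lab in params.feature_priority]
    return pd.DataFrame(rows, columns=["feature", "count", "proportion"])


# ---------------------------------------------------------------------------
# signal matrices
# ---------------------------------------------------------------------------

@dataclass
class SignalMatrix:
    """Per-site, per-bin mean coverage around site centers.

    ``values[i, b]`` is the length-weighted mean of the coverage track
    over bin ``b`` of the ``[center - flank, center + flank)`` window of
    site ``i``; uncovered bp count as 0.
    """

    sites: list[GenomicInterval]
    flank: int
    n_bins: int
    values: np.ndarray

    def profile(self) -> np.ndarray:
        """Aggregate (column-mean) binding profile across sites."""
        return self.values.mean(axis=0)


class _StepTrack:
    """Cumulative integral of a non-overlapping step-function track,
    enabling exact O(log n) window averages."""

    def __init__(self, records: Sequence[GenomicInterval]):
        recs = sorted(records, key=lambda r: r.start)
        for a, b in zip(recs, recs[1:]):
            if b.start < a.end:
                raise ValueError("coverage records overlap within a chromosome")
        xs, Fs = [0.0], [0.0]
        acc = 0.0
        for r in recs:
            if r.start > xs[-1]:
                xs.append(float(r.start))
                Fs.append(acc)
            acc += (r.score or 0.0) * (r.end - r.start)
            xs.append(float(r.end))
            Fs.append(acc)
        self.xs = np.asarray(xs)
        self.Fs = np.asarray(Fs)
        self.total = acc

    def integral(self, lo: float, hi: float) -> float:
        if hi <= lo:
            return 0.0
        a, b = np.interp([lo, hi], self.xs, self.Fs,
                         left=0.0, right=self.total)
        return float(b - a)


def signal_matrix(sites: Sequence[GenomicInterval],
                  coverage: Iterable[GenomicInterval],
                  flank: int = 5000,
                  n_bins: int = 100,
                  chrom_sizes: Mapping[str, int] | None = None) -> SignalMatrix:
    """Mean per-bin coverage in ± ``flank`` windows around site midpoints.

    Bins tile ``[center - flank, center + flank)`` uniformly; each value
    is the exact length-weighted average of the step-function coverage
    over the bin (0 where uncovered).  Bins running past the chromosome
    end average only the available bp.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if flank < 1:
        raise ValueError("flank must be >= 1")
    per_chrom: dict[str, list[GenomicInterval]] = {}
    for rec in coverage:
        per_chrom.setdefault(rec.chrom, []).append(rec)
    tracks = {chrom: _StepTrack(recs) for chrom, recs in per_chrom.items()}
    empty = _StepTrack([])

    values = np.zeros((len(sites), n_bins))
    edges = np.linspace(-flank, flank, n_bins + 1)
    for i, site in enumerate(sites):
        track = tracks.get(site.chrom, empty)
        center = site.midpoint
        L = chrom_sizes.get(site.chrom) if chrom_sizes else None
        for b in range(n_bins):
            lo, hi = center + edges[b], center + edges[b + 1]
            clo = max(lo, 0.0)
            chi = min(hi, L) if L is not None else hi
            width = chi - clo
            if width <= 0:
                continue
            values[i, b] = track.integral(clo, chi) / width
    return SignalMatrix(list(sites), flank, n_bins, values)
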