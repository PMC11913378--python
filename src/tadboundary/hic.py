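"""Binned Hi-C contact matrices: loading, VC_SQRT balancing, virtual 4C
and aggregate peak analysis (APA).

The native on-disk format is a plain-text triplet file::

    #chrom=chr1 bin_size=25000 n_bins=400
    i<TAB>j<TAB>count

with bin ``b`` covering ``[b * bin_size, (b + 1) * bin_size)``.  Triplets
are mirrored on read so the in-memory matrix is always symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import GenomicInterval, Loop

__all__ = [
    "ContactMatrix",
    "ApaResult",
    "load_contacts",
    "write_contacts",
    "vc_normalize",
    "vc_sqrt_normalize",
    "virtual_4c",
    "apa",
]


@dataclass
class ContactMatrix:
    """Symmetric per-chromosome binned contact-count matrix."""

    chrom: str
    bin_size: int
    counts: np.ndarray
    norm: str = "RAW"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("counts must be a square matrix")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be > 0")
        if not np.allclose(self.counts, self.counts.T):
            raise ValueError("counts must be symmetric")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.norm not in ("RAW", "VC", "VC_SQRT"):
            raise ValueError(f"unknown norm {self.norm!r}")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    def bin_of(self, pos: int) -> int:
        b = pos // self.bin_size
        if not (0 <= b < self.n_bins):
            raise ValueError(f"position {pos} outside matrix "
                             f"({self.n_bins} bins of {self.bin_size} bp)")
        return int(b)

    def anchor_bins(self, anchor: GenomicInterval) -> list[int]:
        """Bins overlapped by ``anchor`` (its midpoint bin when the anchor
        fits inside one bin)."""
        if anchor.chrom != self.chrom:
            raise ValueError(f"anchor on {anchor.chrom}, matrix is {self.chrom}")
        lo = anchor.start // self.bin_size
        hi = (anchor.end - 1) // self.bin_size
        if hi < 0 or lo >= self.n_bins:
            raise ValueError("anchor outside matrix")
        return list(range(max(0, lo), min(self.n_bins - 1, hi) + 1))


def load_contacts(path: str | Path) -> ContactMatrix:
    """Read a triplet contact file (header gives chrom/bin_size/n_bins);
    each triplet is mirrored across the diagonal, duplicates summed."""
    path = Path(path)
    lines = path.read_text().splitlines()
    header = None
    for line in lines:
        if line.startswith("#"):
            header = line
            break
        if line.strip():
            break
    if header is None:
        raise ValueError(f"{path}: missing '#chrom=... bin_size=... n_bins=...' header")
    fields = dict(kv.split("=") for kv in header.lstrip("#").split())
    chrom = fields["chrom"]
    bin_size = int(fields["bin_size"])
    n_bins = int(fields["n_bins"])
    counts = np.zeros((n_bins, n_bins))
    for lineno, line in enumerate(lines, 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: triplet needs 3 columns")
        i, j, c = int(parts[0]), int(parts[1]), float(parts[2])
        if i >= n_bins or j >= n_bins or i < 0 or j < 0:
            raise ValueError(f"{path}:{lineno}: bin index out of range")
        if c < 0:
            raise ValueError(f"{path}:{lineno}: negative count")
        counts[i, j] += c
        if i != j:
            counts[j, i] += c
    return ContactMatrix(chrom, bin_size, counts)


def write_contacts(m: ContactMatrix, path: str | Path) -> None:
    """Write the upper triangle (incl. diagonal) as triplets."""
    with open(path, "w") as fh:
        fh.write(f"#chrom={m.chrom} bin_size={m.bin_size} n_bins={m.n_bins}\n")
        ii, jj = np.nonzero(np.triu(m.counts))
        for i, j in zip(ii, jj):
            c = m.counts[i, j]
            cs = str(int(c)) if float(c).is_integer() else repr(float(c))
            fh.write(f"{i}\t{j}\t{cs}\n")


def _coverage_normalize(m: ContactMatrix, sqrt: bool) -> ContactMatrix:
    if m.norm != "RAW":
        raise ValueError(f"matrix already normalized ({m.norm})")
    r = m.counts.sum(axis=1)
    denom = np.sqrt(r) if sqrt else r
    with np.errstate(divide="ignore", invalid="ignore"):
        out = m.counts / np.outer(denom, denom)
    out[~np.isfinite(out)] = 0.0
    total_in, total_out = m.counts.sum(), out.sum()
    if total_out > 0:
        out *= total_in / total_out
    return ContactMatrix(m.chrom, m.bin_size, out,
                         norm="VC_SQRT" if sqrt else "VC")


def vc_normalize(m: ContactMatrix) -> ContactMatrix:
    """Vanilla-coverage balancing: c_ij / (r_i * r_j), rescaled to the
    input grand sum."""
    return _coverage_normalize(m, sqrt=False)


def vc_sqrt_normalize(m: ContactMatrix) -> ContactMatrix:
    """Square-root vanilla-coverage balancing: c_ij / (sqrt(r_i) * sqrt(r_j)).

    Zero-coverage rows stay zero; the result is rescaled by one scalar so
    the grand sum matches the input (symmetry preserved; the transform is
    not idempotent).
    """
    return _coverage_normalize(m, sqrt=True)


def virtual_4c(m: ContactMatrix, anchor: GenomicInterval,
               region: GenomicInterval | None = None) -> "pd.DataFrame":
    """One-anchor interaction profile: the matrix row(s) of the anchor.

    The anchor maps to its bin(s); when it spans several bins the rows
    are averaged.  Returns a DataFrame (bin, start, end, value) over the
    bins covering ``region`` (whole chromosome by default).
    """
    import pandas as pd

    rows = m.anchor_bins(anchor)
    prof = m.counts[rows, :].mean(axis=0)
    if region is not None:
        if region.chrom != m.chrom:
            raise ValueError("region on a different chromosome")
        lo = max(0, region.start // m.bin_size)
        hi = min(m.n_bins - 1, (region.end - 1) // m.bin_size)
    else:
        lo, hi = 0, m.n_bins - 1
    bins = np.arange(lo, hi + 1)
    return pd.DataFrame({
        "bin": bins,
        "start": bins * m.bin_size,
        "end": (bins + 1) * m.bin_size,
        "value": prof[lo:hi + 1],
    })


@dataclass
class ApaResult:
    """Aggregate peak analysis output.

    ``aggregate`` is the element-wise mean of the (2w+1)×(2w+1)
    neighborhoods centered on each usable loop pixel; ``score_p2ll`` is
    the center pixel over the mean of the lower-left corner block
    (rows toward larger anchor1 coordinates, columns toward smaller
    anchor2 coordinates), corner size ``ceil(w / 2)``.
    """

    window: int
    resolution: int
    aggregate: np.ndarray
    n_loops_used: int
    n_loops_skipped: int
    score_p2ll: float


def apa(m: ContactMatrix, loops: Sequence[Loop], window: int = 6,
        require_norm: bool = True) -> ApaResult:
    """Aggregate peak analysis over a loop list on one chromosome.

    Cis loops map to pixel (i, j) by anchor-midpoint bins (i < j).  Loops
    failing the diagonal guard ``j - i > 2 * window`` or whose
    neighborhood would leave the matrix are skipped.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if require_norm and m.norm != "VC_SQRT":
        raise ValueError("matrix must be VC_SQRT-normalized (or pass "
                         "require_norm=False)")
    w = window
    size = 2 * w + 1
    acc = np.zeros((size, size))
    used = skipped = 0
    for lp in loops:
        if lp.is_trans or lp.anchor1.chrom != m.chrom:
            skipped += 1
            continue
        i = lp.anchor1.midpoint // m.bin_size
        j = lp.anchor2.midpoint // m.bin_size
        if i > j:
            i, j = j, i
        if j - i <= 2 * w:          # neighborhood would cross the diagonal
            skipped += 1
            continue
        if i - w < 0 or j + w >= m.n_bins or i + w >= m.n_bins or j - w < 0:
            skipped += 1
            continue
        acc += m.counts[i - w:i + w + 1, j - w:j + w + 1]
        used += 1
    if used == 0:
        raise ValueError("no usable loops for APA (diagonal guard / edges)")
    aggregate = acc / used
    corner = max(1, -(-w // 2))     # ceil(w/2); 3 for the standard window 6
    ll = aggregate[-corner:, :corner]
    ll_mean = ll.mean()
    center = aggregate[w, w]
    score = float(center / ll_mean) if ll_mean > 0 else float("inf")
    return ApaResult(window=w, resolution=m.bin_size, aggregate=aggregate,
                     n_loops_used=used, n_loops_skipped=skipped,
                     score_p2ll=score)
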