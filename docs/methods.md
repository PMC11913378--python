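# Methods

This note documents the models, conventions and numerical choices behind
`tadboundary`, and what the synthetic-data generator does and does not
emulate.

## Coordinate and overlap conventions

All internal coordinates are 0-based half-open (`[start, end)`), the BED
convention; GTF input (1-based closed) is converted on read
(`start - 1`, `end`). Overlap means at least one shared base pair —
there is no minimum-fraction option. Strand never affects an overlap
test; it only enters the derivation of promoters, terminators and
head-to-tail geometry. Chromosome names are taken literally (no
`chr`-prefix normalization).

Point-centred windows follow the "± flank" rule `[p - flank, p + flank)`
with clamping at 0 and, where chromosome sizes are supplied, at the
chromosome end. The defaults are the analysis parameters used
throughout: promoter = TSS ± 1 kb, terminator = TES ± 5 kb,
H3K27ac extension ± 1 kb, TAD-boundary window ± 5 kb, contact matrices
at 25 kb bins, APA window 6 with VC_SQRT balancing.

Multi-isoform genes are collapsed to one model per `gene_id` (union
span, merged exons), so "the end of the annotated transcript" is the
outermost 3' position. This is a package decision: the upstream
analyses this mirrors do not state which isoform's 3' end they used.

## p300-only peaks and feature annotation

A p300 peak is *p300-only* when it overlaps none of the H3K27ac peaks
after those are extended ± 1 kb; the rest are *shared*. The two sets
always partition the input, and enlarging the extension can only shrink
the p300-only set (both properties are tested).

Peak-to-feature assignment uses the **peak midpoint**. The label set is
promoter, first intron, other intron, exon, 3'-end, distal intergenic;
when a midpoint satisfies several, priority is promoter > first intron >
other intron > exon > 3'-end. The first intron is first in
*transcription* order (rightmost gap on the minus strand). The 3'-end
label is a TES ± 1 kb window, folding the "downstream < 1 kb" category
into the transcript end. The midpoint rule and this priority are the
simplest reproducible stand-in for annotation packages whose internal
tie-breaks are not published; both are configurable
(`PeakClassParams`).

Signal matrices average a bedGraph step-function track over uniform
bins in ± 5 kb windows around site midpoints, computed exactly via a
cumulative integral (uncovered bp count as 0; bins past the chromosome
end average only the available bp). Coverage input is bedGraph rather
than bigWig to keep the core dependency-free.

## Interaction categories

A TAD-boundary "interaction" is the pair of ± 5 kb windows around the
two edges of one TAD; inter-TAD boundary pairs are not formed. Loop
anchors and boundary windows receive labels by overlap: `p300_only`,
`H3K27me3`, `promoter`, `terminator`, `gene_body` (the full gene span —
promoter/terminator windows are not subtracted), plus two exclusion
labels: `gene` (overlaps a gene but neither chromatin mark) and
`intergenic` (overlaps none of the above). Gene bodies are not trimmed
because the upstream definition does not trim them.

Classification matches an ordered list of label-pair patterns, first
match wins, symmetric in anchor order:

```
p300only-H3K27me3 > H3K27me3-H3K27me3 > p300only-p300only >
PP > PT > PG > GG > gene-gene > gene-intergenic >
intergenic-intergenic > other
```

The headline repressive class (p300-only on one anchor, H3K27me3 on the
other) is first so its count is never absorbed by a broader class. By
default the two marks must sit on *opposite* anchors — a single anchor
carrying both marks does not qualify on its own. A second, gene-only
precedence (PP/PT/PG/TT/TG/GG) serves boundary-pair typing; a mode flag
selects the universe. The precedence list is a plain tuple and can be
replaced by the caller.

Loop merging collapses loops whose anchor centres both lie within a
tolerance (default one bin, 25 kb) of an already-kept loop, using the
transitive closure (union-find) of the tolerance graph; the
genomically first member represents each group, making the operation
idempotent and order-independent.

## Hi-C operations

Contact matrices live in a plain-text triplet format (header
`#chrom=<name> bin_size=<bp> n_bins=<n>`, then `i<TAB>j<TAB>count`);
triplets are mirrored on read so the in-memory matrix is always
symmetric. VC_SQRT balancing divides `c_ij` by `sqrt(r_i) * sqrt(r_j)`
(row sums `r`), leaves zero-coverage rows at zero, and rescales by a
single scalar so the grand sum is preserved; the transform is not
idempotent and the implementation refuses to re-normalize.

Virtual 4C is exactly matrix-row extraction: the anchor maps to its
bin(s) — rows are averaged when an anchor spans several bins — and the
profile is the normalized row over the requested region. No smoothing
is applied; that is left to plotting.

APA extracts the `(2w+1)²` neighbourhood (window `w = 6` → 13 × 13)
around each cis loop pixel (anchor-midpoint bins), averages them
element-wise, and scores P2LL = centre pixel / mean of the
`ceil(w/2)`-sized (3 × 3 at window 6) lower-left corner block (rows
toward larger anchor1 coordinate, columns toward smaller anchor2
coordinate). Loops whose neighbourhood would cross the diagonal
(`j - i <= 2w`) or leave the matrix are skipped and counted; zero usable
loops is an error.

## Head-to-tail boundary gene pairs

A head-to-tail pair is two same-strand genes at opposite boundary
windows of one TAD: the upstream gene's 3' region overlaps one window
and the downstream gene's promoter the other. Upstream/downstream is
meant in the *transcription* sense (smaller coordinate on `+`, larger on
`-`); this is the only reading under which the screen is symmetric when
the genome is mirrored and strands flipped, a property the tests check.
"3' region" accepts either the terminator window (TES ± 5 kb) or the
3'-half of the gene body, and the matched element is recorded per pair.
Genes may extend outside the TAD; all qualifying pairs are reported (no
best-pair selection).

Oncogene/tumour-suppressor cross-referencing is a plain set lookup on
user-supplied symbol lists (list provenance is the caller's
responsibility). In the promoter-mutation summary a sample counts at
most once per gene regardless of mutation multiplicity, and the overall
fraction is distinct samples with ≥ 1 promoter hit over all distinct
samples in the table; positions are 1-based on input, converted
internally.

## Expression comparisons and qPCR

Expression enters as TPM and is compared on the `log2(TPM + 1)` scale;
zero-TPM genes are retained (no filter is applied). Genes looped to a
p300-only anchor are split by H3K27me3 overlap of the gene span and
compared with the two-sample Wilcoxon rank-sum (Mann-Whitney) test —
the two-sample variant because the groups are independent gene sets —
exact for small untied samples, tie-corrected normal approximation
otherwise (scipy). A gene appearing in several qualifying loops counts
once. Boundary-pair classes (PT/PG/PP) are compared with the
tie-corrected Kruskal-Wallis test; each boundary contributes the
expression of its overlapping gene, labelled by the pair's type, and
genes are deduplicated per (gene, category).

qPCR relative quantification computes ΔCt per replicate against the
internal control gene, then ΔΔCt against the *mean* control-condition
ΔCt (the common convention); fold = 2^−ΔΔCt and log2 fold change =
−ΔΔCt hold exactly by construction. Error is reported both as the sd of
replicate folds and as the ΔCt-propagated range 2^−(ΔΔCt ± sd), since
figure-legend conventions differ. Replicate-level comparisons use the
unpaired Welch t-test by default (Student's available via a flag);
amplification-efficiency correction is out of scope.

## Synthetic data: what it emulates, and what it does not

The generator produces every input type from one seeded configuration,
with exact ground truth. Defaults define one study: 2 chromosomes of
10 Mb, 25 kb bins, 160 filler genes of 20–120 kb with 2–6 exons on both
strands, 24 TADs of 300–600 kb separated by 100–200 kb gaps, 120
H3K27ac and 100 p300 peaks of 400 bp with a 40% planted shared
fraction, H3K27me3 blocks over 30% of filler genes, 300 loops with
planted category proportions (the repressive class at 8.33%, the rate
reported for chromatin loops; boundary plants at 1.52% of TADs), 6
planted head-to-tail pairs, contact matrices with power-law decay
(base 2000, exponent 0.8), a 1.5× TAD block factor and 50 loop pixels
at 5× enrichment spanning 2–3.75 Mb, log-normal expression
(log2 scale: mean 3, sd 1.5) with a 1.0-log2 repression shift on
H3K27me3 genes, and Ct tables at 0.1-cycle noise with planted 4× and
0.5× folds. Everything runs in seconds at these sizes; larger instances
(e.g. 300 TADs on 100 Mb chromosomes for the pair screen) are plain
configuration changes.

Design points worth knowing:

- **Exactness by construction.** Randomly placed peaks and filler genes
  are rejected near TAD-boundary windows, and planted pair-gene lengths
  are capped at half the gap to the neighbouring TAD, so the planted
  configurations are the *only* boundary configurations present and
  ground truth is exact, not approximate. Planted pair TES/TSS
  positions carry 1–4 kb jitter inside the windows so detection is
  non-trivial.
- **Counts are Poisson.** Contact counts are Poisson draws of
  `base · (d+1)^-α` (times TAD/loop factors); overdispersion
  (negative-binomial) is not modelled and is unnecessary at these
  scales.
- **Loop anchors classify unambiguously.** Category plants use
  promoters/terminators/body interiors of "clean" genes (no marks or
  peaks within 7 kb), true p300-only peaks, H3K27me3 blocks and empty
  intergenic space, with per-category counts fixed by largest
  remainder.
- **Expression clipping.** log2(TPM+1) draws are clipped at 0 before
  inverting to TPM, so TPM is always non-negative; the clip slightly
  compresses the realized shift of strongly repressed genes.

What passing tests on this data do **not** show: real peak sets have
width and co-occurrence structure far richer than fixed-width
non-colliding intervals; real TADs are nested and their boundaries
fuzzy; real contact maps have domain-level structure beyond one block
factor; real expression is not a single log-normal; and the genome here
has no sequence content at all. The generator validates the *logic* of
every stage against a known truth — it does not validate biological
discovery power on real data.

## Problem sizes and numerical choices

The test suite and the acceptance script run the screens at the sizes
above (the pair screen at 300 TADs / 12 planted pairs, category
recovery at 5 000 loops, rank-sum calibration at 500 replicates of
200 + 200 genes), chosen so each stage's property is measured with
comfortable statistical margin while the whole suite stays fast.
Floating-point comparisons in oracles use absolute tolerances of 1e-9
or tighter; the ΔΔCt identities are asserted exactly. Degenerate inputs
(empty peak sets, TADs shorter than two boundary windows, replicates
missing a reference Ct) warn and skip rather than fail, and every
malformed-file error names the offending line.

## Known limitations

- bigWig and `.hic`/`.cool` binary formats are not parsed; coverage is
  bedGraph and contacts are text triplets (adapters can be layered on).
- KR/ICE balancing and insulation scores are out of scope; only
  VC/VC_SQRT are implemented.
- The H3K27me3 input is any BED; if a study only provides a signal
  track, thresholding it into intervals is the caller's choice.
- Trans-chromosomal loops are carried through I/O and merging but are
  skipped by APA and virtual 4C.
- The rank-sum null-calibration check inherits binomial noise
  (sd ≈ 0.01 at 500 replicates); its 0.03–0.07 acceptance band is a
  ±2 sd envelope.
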