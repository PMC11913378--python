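# tadboundary

Analysis toolkit for gene regulation at TAD boundaries and chromatin
loops: discovery of H3K27ac-independent ("p300-only") p300 peaks,
classification of loop and TAD-boundary interactions — including the
repressive class anchored by a p300-only peak on one side and H3K27me3
on the other — virtual 4C and aggregate peak analysis (APA) on binned
Hi-C contact matrices, a genome-wide screen for *head-to-tail*
TAD-boundary gene pairs with oncogene cross-referencing and
promoter-mutation summaries, expression comparisons between interaction
classes, and ΔΔCt quantification for qRT-PCR.

It is written for regulatory-genomics analysts who have peak calls
(BED), loops (BEDPE), TADs (BED), gene models (GTF), contact matrices
(text triplets), expression tables (TSV) and qPCR Ct tables (TSV), and
want the complete pipeline between those files and the summary
statistics — plus a seeded synthetic-data generator that produces every
input type with exact ground truth, so each stage is testable without
any downloads.

## The core definitions

- **p300-only peak** — a p300 ChIP-seq peak overlapping none of the
  H3K27ac peaks after each is extended ± 1 kb. These sites, lacking the
  active-enhancer mark, are candidates for a repressive role.
- **Interaction categories** — each loop anchor (or ± 5 kb TAD-boundary
  window) is labelled by overlap with p300-only peaks, H3K27me3,
  promoters (TSS ± 1 kb), terminators (TES ± 5 kb) and gene bodies; the
  pair is classified by a first-match precedence in which
  `p300only-H3K27me3` outranks all gene-element classes (PP, PT, PG,
  GG, …).
- **Virtual 4C** — the contact-matrix row of an anchor bin, after
  VC_SQRT balancing (`c_ij / √(r_i r_j)`, grand sum preserved).
- **APA** — the element-wise mean of the 13 × 13 (window 6)
  neighbourhoods around loop pixels; P2LL = centre pixel over the mean
  of the 3 × 3 lower-left corner.
- **Head-to-tail pair** — two same-strand genes at opposite boundaries
  of one TAD: the upstream gene's 3' region (terminator or 3'-half gene
  body) on one ± 5 kb boundary window, the downstream gene's promoter
  on the other. Repression of the promoter-anchored gene can restrain
  its 3'-anchored partner (oncogene screening follows from this).
- **ΔΔCt** — per-replicate ΔCt against an internal control gene, then
  ΔΔCt against the mean control-condition ΔCt; fold change = 2^−ΔΔCt,
  log2 fold change = −ΔΔCt.

See `docs/methods.md` for conventions, tie-breaks and the synthetic
model.

## Worked example

Run the whole pipeline on a synthetic study (2 × 10 Mb genome, 24 TADs,
300 loops, 25 kb contact matrix — seconds end to end):

```sh
tadboundary reproduce-synthetic --seed 1 --outdir run1
```

This simulates all inputs into `run1/inputs/`, re-reads them through the
package's own parsers, runs every stage, and writes per-stage tables
plus `summary.json` and `manifest.json` (sha256 of every file — two runs
with one seed are byte-identical). Selected `summary.json` content from
seed 1:

```json
"p300_only":        {"n_true": 60, "n_recovered": 60, "exact_match": true},
"loop_categories":  {"headline_fraction_pct": 8.3333,
                     "max_abs_fraction_error": 0.0, "n_loops": 300},
"head_to_tail":     {"n_planted": 6, "n_recovered": 6, "n_false_positive": 0},
"hic": {"chr1":     {"apa_p2ll_planted": 4.5396, "apa_p2ll_random": 0.9324,
                     "virtual4c_peak_at_planted_partner": true}},
"expression":       {"median_shift_log2": 0.6919, "rank_sum_p": 0.021},
"qpcr":             {"recovered_folds": {"GeneX": 4.5316, "GeneY": 0.5266},
                     "planted_folds":   {"GeneX": 4.0,    "GeneY": 0.5}}
```

Reading: the p300-only partition recovered the planted 60-peak set
exactly; loop-category fractions match the plant (the repressive
`p300only-H3K27me3` class at its planted 8.33% rate); all 6 planted
head-to-tail pairs were found with no false positives; loops planted at
5× enrichment score APA P2LL ≈ 4.5 while random pixel pairs sit near 1;
the planted 1-log2 repression shift is visible (rank-sum p = 0.021 at
this small n); and the planted 4× / 0.5× qPCR folds are recovered
within replicate noise.

Individual stages are also library calls, e.g.:

```python
from tadboundary import read_bed, p300_only_peaks
only, shared = p300_only_peaks(read_bed("p300.bed"), read_bed("h3k27ac.bed"))
```

or subcommands: `simulate`, `p300only`, `annotate-peaks`,
`signal-matrix`, `boundaries`, `merge-loops`, `classify`, `virtual4c`,
`apa`, `headtail`, `promoter-mutations`, `expr-compare`, `qpcr`,
`reproduce-synthetic` (`tadboundary <cmd> --help`).

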