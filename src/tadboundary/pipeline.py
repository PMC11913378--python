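"""End-to-end synthetic reproduction pipeline.

``reproduce_synthetic`` generates a full synthetic study from one seed,
re-reads every file through the package's own readers, runs all analysis
stages, and writes per-stage tables plus ``summary.json`` (recovered
ground truth) and ``manifest.json`` (sha256 of every output, for
determinism audits).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from . import expression as expr_mod
from . import headtail as ht_mod
from . import hic as hic_mod
from . import peaks as peaks_mod
from . import qpcr as qpcr_mod
from . import topology as topo_mod
from .core import (GenomicInterval, read_bed, read_bedpe, read_chrom_sizes,
                   read_gtf_genes, write_bed, write_bedpe, Loop)
from .simulate import SimConfig, simulate_all

__all__ = ["reproduce_synthetic", "random_loop_pixels"]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def random_loop_pixels(n: int, n_bins: int, distance_range: tuple[int, int],
                       rng: np.random.Generator,
                       exclude: set[tuple[int, int]] = frozenset(),
                       ) -> list[tuple[int, int]]:
    """Random distinct (i, j) pixel pairs at loop-like distances, for the
    APA negative control."""
    out: list[tuple[int, int]] = []
    seen = set(exclude)
    guard = 0
    while len(out) < n:
        guard += 1
        if guard > 100_000:
            raise ValueError("cannot sample random pixels")
        d = int(rng.integers(distance_range[0], distance_range[1] + 1))
        if d >= n_bins - 14:
            continue
        i = int(rng.integers(7, n_bins - d - 7))
        if (i, i + d) in seen:
            continue
        seen.add((i, i + d))
        out.append((i, i + d))
    return out


def _pixel_loops(pixels, m: hic_mod.ContactMatrix) -> list[Loop]:
    bs = m.bin_size
    return [Loop(GenomicInterval(m.chrom, i * bs, (i + 1) * bs),
                 GenomicInterval(m.chrom, j * bs, (j + 1) * bs))
            for i, j in pixels]


def reproduce_synthetic(config: SimConfig, outdir: str | Path) -> dict:
    """Run the full pipeline on freshly simulated data.

    Returns the manifest dict (also written to ``manifest.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs_dir = outdir / "inputs"
    files = simulate_all(config, inputs_dir)
    truth = json.loads(Path(files["ground_truth"]).read_text())

    # ---- re-read everything through the package's readers ---------------
    chrom_sizes = read_chrom_sizes(files["chrom_sizes"])
    genes = read_gtf_genes(files["genes"])
    tads = read_bed(files["tads"])
    loops = read_bedpe(files["loops"])
    p300 = read_bed(files["p300"])
    h3k27ac = read_bed(files["h3k27ac"])
    h3k27me3 = read_bed(files["h3k27me3"])
    expression = expr_mod.read_expression(files["expression"])
    ct = qpcr_mod.read_ct_table(files["ct"])

    summary: dict = {"seed": config.seed}
    out_files: dict[str, Path] = {}

    def put(name: str, fname: str) -> Path:
        out_files[name] = outdir / fname
        return out_files[name]

    # ---- stage 1: p300-only partition ------------------------------------
    params = peaks_mod.PeakClassParams()
    only, shared = peaks_mod.p300_only_peaks(p300, h3k27ac, params, chrom_sizes)
    write_bed(only, put("p300_only", "p300_only.bed"))
    write_bed(shared, put("p300_shared", "p300_shared.bed"))
    rec = {p.name for p in only}
    tru = set(truth["p300_only"])
    summary["p300_only"] = {
        "n_true": len(tru), "n_recovered": len(rec),
        "exact_match": rec == tru,
        "jaccard": (len(rec & tru) / len(rec | tru)) if (rec | tru) else 1.0,
    }

    # ---- stage 2: feature distribution of p300-only peaks ----------------
    dist = peaks_mod.feature_distribution(only, genes, params)
    dist.to_csv(put("feature_distribution", "feature_distribution.tsv"),
                sep="\t", index=False)
    summary["feature_distribution"] = {
        row.feature: round(float(row.proportion), 6)
        for row in dist.itertuples()}

    # ---- stage 3: loop interaction categories ----------------------------
    annot = topo_mod.AnchorAnnotator(genes, only, h3k27me3)
    topo_mod.classify_loops(loops, annot, mode="chromatin")
    write_bedpe(loops, put("loops_classified", "loops_classified.bedpe"),
                with_category=True)
    counts = topo_mod.count_interaction_categories(
        [lp.category for lp in loops])
    counts.to_csv(put("loop_categories", "loop_category_counts.tsv"),
                  sep="\t", index=False)
    planted = truth["loop_planted_counts"]
    n_loops = len(loops)
    observed = {row.category: row.fraction for row in counts.itertuples()}
    max_err = max(abs(observed.get(cat, 0.0) - planted[cat] / n_loops)
                  for cat in planted)
    summary["loop_categories"] = {
        "n_loops": n_loops,
        "fractions": {k: round(float(v), 6) for k, v in observed.items()},
        "headline_fraction_pct": round(
            100.0 * observed.get("p300only-H3K27me3", 0.0), 4),
        "max_abs_fraction_error": round(float(max_err), 6),
    }

    # ---- stage 4: TAD boundary categories --------------------------------
    tad_windows = topo_mod.tad_boundary_windows(tads, config.boundary_flank,
                                                chrom_sizes)
    bnd_cats = topo_mod.classify_tad_boundaries(tad_windows, annot,
                                                mode="chromatin")
    bnd_counts = topo_mod.count_interaction_categories(bnd_cats)
    bnd_counts.to_csv(put("tad_boundary_categories",
                          "tad_boundary_category_counts.tsv"),
                      sep="\t", index=False)
    frac = {row.category: row.fraction for row in bnd_counts.itertuples()}
    summary["tad_boundary_categories"] = {
        "n_tads": len(tad_windows),
        "headline_fraction_pct": round(
            100.0 * frac.get("p300only-H3K27me3", 0.0), 4),
        "n_headline_planted": len(truth["headline_tads"]),
    }

    # ---- stage 5: head-to-tail screen ------------------------------------
    pairs = ht_mod.detect_head_to_tail(tad_windows, genes)
    ht_mod.pairs_to_frame(pairs).to_csv(
        put("headtail_pairs", "headtail_pairs.tsv"), sep="\t", index=False)
    found = {(p.upstream_gene.gene_id, p.downstream_gene.gene_id)
             for p in pairs}
    truth_pairs = {(p["upstream_gene"], p["downstream_gene"])
                   for p in truth["pairs"]}
    summary["head_to_tail"] = {
        "n_planted": len(truth_pairs),
        "n_recovered": len(found & truth_pairs),
        "n_false_positive": len(found - truth_pairs),
    }

    # ---- stage 6: virtual 4C and APA on the contact matrix ---------------
    rng = np.random.default_rng(config.seed + 10)
    hic_summary = {}
    for chrom in config.contact_chroms:
        m = hic_mod.load_contacts(files[f"contacts_{chrom}"])
        norm = hic_mod.vc_sqrt_normalize(m)
        pixels = [tuple(px) for px in truth["contact_planted_pixels"][chrom]]

        i0, j0 = pixels[0]
        anchor = GenomicInterval(chrom, i0 * m.bin_size, (i0 + 1) * m.bin_size)
        prof = hic_mod.virtual_4c(norm, anchor)
        prof.to_csv(put(f"virtual4c_{chrom}", f"virtual4c_{chrom}.tsv"),
                    sep="\t", index=False)
        # planted partners of this anchor row, searched within the
        # loop-distance band (outside it distance decay dominates)
        partners = {j for i, j in pixels if i == i0} | \
                   {i for i, j in pixels if j == i0}
        d_lo, d_hi = config.loop_distance_bins
        band = prof[(np.abs(prof["bin"] - i0) >= d_lo)
                    & (np.abs(prof["bin"] - i0) <= d_hi)]
        v4c_hits_plant = bool(
            int(band.loc[band["value"].idxmax(), "bin"]) in partners)

        apa_planted = hic_mod.apa(norm, _pixel_loops(pixels, norm), window=6)
        rand_pixels = random_loop_pixels(len(pixels), m.n_bins,
                                         config.loop_distance_bins, rng,
                                         exclude=set(pixels))
        apa_random = hic_mod.apa(norm, _pixel_loops(rand_pixels, norm),
                                 window=6)
        np.savetxt(put(f"apa_{chrom}", f"apa_aggregate_{chrom}.tsv"),
                   apa_planted.aggregate, delimiter="\t", fmt="%.6f")
        hic_summary[chrom] = {
            "virtual4c_peak_at_planted_partner": v4c_hits_plant,
            "apa_p2ll_planted": round(apa_planted.score_p2ll, 4),
            "apa_p2ll_random": round(apa_random.score_p2ll, 4),
            "n_loops_used": apa_planted.n_loops_used,
        }
    summary["hic"] = hic_summary

    # ---- stage 7: expression comparison (H3K27me3 vs not) ----------------
    marked = set(truth["h3k27me3_genes"])
    k27_idx = expr_mod.IntervalIndex(h3k27me3)
    g_marked, g_clear = [], []
    for g in genes:
        (g_marked if k27_idx.overlaps_interval(g.span) else g_clear).append(g)
    vals_m = expr_mod.log_expr([expression[g.gene_id] for g in g_marked
                                if g.gene_id in expression.index])
    vals_c = expr_mod.log_expr([expression[g.gene_id] for g in g_clear
                                if g.gene_id in expression.index])
    stat, pval = expr_mod.rank_sum_test(vals_m, vals_c)
    summary["expression"] = {
        "n_h3k27me3": int(len(vals_m)),
        "n_other": int(len(vals_c)),
        "median_shift_log2": round(
            float(np.median(vals_c) - np.median(vals_m)), 4),
        "rank_sum_p": float(pval),
        "planted_shift_log2": truth["expression_shift_log2"],
    }

    # ---- stage 8: qPCR ΔΔCt ----------------------------------------------
    dct = qpcr_mod.delta_ct(ct, config.qpcr_reference)
    dd = qpcr_mod.ddct(dct, config.qpcr_control_sample)
    dd.to_csv(put("qpcr", "qpcr_ddct.tsv"), sep="\t", index=False)
    treated = dd[dd["sample"] == config.qpcr_treated_sample]
    summary["qpcr"] = {
        "recovered_folds": {row.gene: round(float(row.fold), 4)
                            for row in treated.itertuples()},
        "planted_folds": truth["qpcr_fold_map"],
    }

    # ---- summary + manifest ----------------------------------------------
    summary_path = outdir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=1, sort_keys=True) + "\n")

    all_files = dict(files)
    all_files.update({k: str(v) for k, v in out_files.items()})
    all_files["summary"] = str(summary_path)
    manifest = {
        "config": config.to_dict(),
        "checksums": {name: _sha256(Path(p))
                      for name, p in sorted(all_files.items())},
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest
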