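"""Relative quantification for qRT-PCR: ΔCt, 2^-ΔCt and the 2^-ΔΔCt method.

ΔCt is computed per replicate against an internal control gene (ACT in
the reference experiments); ΔΔCt subtracts the mean control-condition
ΔCt, so fold change = 2^-ΔΔCt and log2 fold change = -ΔΔCt exactly.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "read_ct_table",
    "delta_ct",
    "relative_expression",
    "ddct",
    "replicate_test",
]

CT_COLUMNS = ["sample", "gene", "replicate", "ct"]


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV with columns sample, gene, replicate, ct."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"Ct table missing columns {missing}")
    df = df[CT_COLUMNS].copy()
    df["ct"] = df["ct"].astype(float)
    if (df["ct"] <= 0).any():
        raise ValueError("Ct values must be > 0")
    dup = df.duplicated(["sample", "gene", "replicate"])
    if dup.any():
        raise ValueError("duplicate (sample, gene, replicate) rows")
    return df


def delta_ct(ct: pd.DataFrame, reference_gene: str) -> pd.DataFrame:
    """Per-replicate ΔCt = Ct(target) - Ct(reference), same sample and
    replicate.  Replicates lacking a reference measurement are dropped
    with a warning.  Returns long-format rows (sample, gene, replicate,
    dct) for every non-reference gene.
    """
    ref = ct[ct["gene"] == reference_gene].set_index(["sample", "replicate"])["ct"]
    if ref.empty:
        raise ValueError(f"no rows for reference gene {reference_gene!r}")
    targets = ct[ct["gene"] != reference_gene].copy()
    key = list(zip(targets["sample"], targets["replicate"]))
    ref_ct = [ref.get(k, np.nan) for k in key]
    targets["dct"] = targets["ct"].to_numpy() - np.asarray(ref_ct, float)
    n_drop = int(targets["dct"].isna().sum())
    if n_drop:
        warnings.warn(f"dropped {n_drop} replicate(s) without a reference Ct")
    return targets.dropna(subset=["dct"])[["sample", "gene", "replicate", "dct"]]


def relative_expression(dct) -> np.ndarray:
    """2^-ΔCt."""
    return np.power(2.0, -np.asarray(dct, dtype=float))


def summarize_dct(dct: pd.DataFrame) -> pd.DataFrame:
    """Mean ± sd of ΔCt and mean 2^-ΔCt per (sample, gene)."""
    g = dct.groupby(["sample", "gene"])["dct"]
    out = g.agg(dct_mean="mean", dct_sd="std", n="count").reset_index()
    out["rel_expr_2^-dct"] = relative_expression(out["dct_mean"])
    return out


def ddct(dct: pd.DataFrame, control_sample: str) -> pd.DataFrame:
    """ΔΔCt per (sample, gene) against the control condition.

    ΔΔCt = mean ΔCt(sample) - mean ΔCt(control); per-replicate ΔΔCt
    values (replicate ΔCt minus the mean control ΔCt) give the sd of the
    fold.  Reports ddct, log2fc = -ΔΔCt, fold = 2^-ΔΔCt, and both error
    conventions (sd of replicate folds, and the ΔCt-propagated fold
    range 2^-(ΔΔCt ± sd)).
    """
    if control_sample not in set(dct["sample"]):
        raise ValueError(f"control sample {control_sample!r} absent from table")
    ctrl_mean = (dct[dct["sample"] == control_sample]
                 .groupby("gene")["dct"].mean())
    rows = []
    for (sample, gene), grp in dct.groupby(["sample", "gene"]):
        if gene not in ctrl_mean.index:
            warnings.warn(f"gene {gene!r} has no control ΔCt; skipped")
            continue
        rep_ddct = grp["dct"].to_numpy() - ctrl_mean[gene]
        d = float(rep_ddct.mean())
        sd = float(rep_ddct.std(ddof=1)) if len(rep_ddct) > 1 else 0.0
        folds = np.power(2.0, -rep_ddct)
        rows.append({
            "sample": sample,
            "gene": gene,
            "n": len(rep_ddct),
            "ddct": d,
            "ddct_sd": sd,
            "log2fc": -d,
            "fold": float(2.0 ** -d),
            "fold_sd": float(folds.std(ddof=1)) if len(folds) > 1 else 0.0,
            "fold_lo": float(2.0 ** -(d + sd)),
            "fold_hi": float(2.0 ** -(d - sd)),
        })
    return pd.DataFrame(rows)


def replicate_test(group_a, group_b, tail: str = "two",
                   welch: bool = True) -> tuple[float, float]:
    """Unpaired t-test between replicate-level values (Welch by default).

    ``tail``: "two", "greater" (A > B) or "less".
    """
    a, b = np.asarray(group_a, float), np.asarray(group_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 replicates")
    alternative = {"two": "two-sided", "two-sided": "two-sided",
                   "greater": "greater", "less": "less"}.get(tail)
    if alternative is None:
        raise ValueError(f"unknown tail {tail!r}")
    res = stats.ttest_ind(a, b, equal_var=not welch, alternative=alternative)
    return float(res.statistic), float(res.pvalue)
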