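"""Promoter probe-sign homogeneity ("cluster phenomenon") analysis.

A gene whose significant promoter probes all carry the same methyl-score
sign is called a cluster: category ``neg`` (all less methylated in
disease), ``pos`` (all more methylated) or ``negpos`` (mixed). The
promoter is the inclusive interval [−1,700, 0] relative to the TSS, and
only genes with at least ``min_probes`` (default 3, i.e. "more than
two") significant signed probes there are categorised.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .groups import SignContingency
from .windows import make_windows

logger = logging.getLogger("methylprofile")

PROMOTER = (-1700, 0)

CATEGORIES = ("neg", "pos", "negpos")


def classify_promoter_clusters(
    stats: pd.DataFrame,
    promoter: tuple[int, int] = PROMOTER,
    min_probes: int = 3,
    include_zero: bool = False,
) -> pd.DataFrame:
    """Categorise genes by the sign homogeneity of their promoter probes.

    ``stats`` must be significance-filtered. Zero-sign probes are
    excluded from the sign set before classification unless
    ``include_zero`` (in which case a zero breaks homogeneity). Genes
    with fewer than ``min_probes`` qualifying probes are omitted with a
    logged count. Returns columns (gene_id, group, n_sig_probes, n_neg,
    n_pos, category).
    """
    lo, hi = min(promoter), max(promoter)
    sel = stats[stats["tss_offset"].between(lo, hi)]
    if not include_zero:
        sel = sel[sel["sign"] != "zero"]
    if sel.empty:
        return pd.DataFrame(columns=["gene_id", "group", "n_sig_probes", "n_neg", "n_pos",
                                     "category"])
    agg = sel.groupby(["gene_id", "group"], observed=True)["sign"].agg(
        n_sig_probes="count",
        n_neg=lambda s: int((s == "negative").sum()),
        n_pos=lambda s: int((s == "positive").sum()),
    ).reset_index()
    below = agg["n_sig_probes"] < min_probes
    if below.any():
        logger.info("classify_promoter_clusters: %d genes below %d-probe threshold omitted",
                    below.sum(), min_probes)
    agg = agg.loc[~below].reset_index(drop=True)
    homogeneous_neg = (agg["n_pos"] == 0) & (agg["n_neg"] == agg["n_sig_probes"])
    homogeneous_pos = (agg["n_neg"] == 0) & (agg["n_pos"] == agg["n_sig_probes"])
    agg["category"] = np.where(homogeneous_neg, "neg",
                               np.where(homogeneous_pos, "pos", "negpos"))
    return agg


def cluster_frequency(calls: pd.DataFrame) -> tuple[float, dict]:
    """Fraction of categorised genes that are homogeneous: (neg+pos)/total."""
    if calls.empty:
        raise ValueError("no cluster calls")
    counts = calls["category"].value_counts().reindex(CATEGORIES, fill_value=0).to_dict()
    total = sum(counts.values())
    frac = (counts["neg"] + counts["pos"]) / total
    return float(frac), {**counts, "total": total}


def neg_enrichment_test(calls: pd.DataFrame) -> SignContingency:
    """Chi-squared test of the all-negative fraction across gene groups.

    Builds the groups x {neg, not-neg} table from the cluster calls and
    applies Pearson's chi-squared without continuity correction.
    """
    if calls["group"].nunique() < 2:
        raise ValueError("need >=2 groups")
    tab = pd.DataFrame({
        "n_negative": calls.groupby("group", observed=True)["category"]
        .apply(lambda s: int((s == "neg").sum())),
        "n_positive": calls.groupby("group", observed=True)["category"]
        .apply(lambda s: int((s != "neg").sum())),
    })
    # reuse the sign-contingency machinery: columns are {neg, not-neg} here
    from .groups import sign_contingency_test

    return sign_contingency_test(tab)


def scan_cluster_windows(
    stats: pd.DataFrame,
    start: int = 750,
    end: int = -1500,
    width: int = 800,
    step: int = 50,
    min_probes: int = 4,
) -> pd.DataFrame:
    """Positional cluster scan: per-window all-neg / all-pos gene fractions.

    Slides an 800-bp window (50-bp shift by default) over [end, start];
    in each window, genes with at least ``min_probes`` (default 4, i.e.
    "more than three") significant signed probes inside the window are
    classified as all-negative, all-positive or mixed, and the fractions
    are reported. Windows with no qualifying gene carry NaN fractions.
    """
    windows = make_windows(start=start, end=end, width=width, step=step)
    signed = stats[stats["sign"] != "zero"]
    rows = []
    for w, lo, hi in windows.itertuples(index=False):
        sel = signed[signed["tss_offset"].between(lo, hi)]
        if sel.empty:
            rows.append({"w": w, "lo": lo, "hi": hi, "n_genes": 0,
                         "frac_all_neg": np.nan, "frac_all_pos": np.nan})
            continue
        agg = sel.groupby("gene_id", observed=True)["sign"].agg(
            n="count", n_neg=lambda s: int((s == "negative").sum())
        )
        agg = agg[agg["n"] >= min_probes]
        n_genes = len(agg)
        if n_genes == 0:
            rows.append({"w": w, "lo": lo, "hi": hi, "n_genes": 0,
                         "frac_all_neg": np.nan, "frac_all_pos": np.nan})
            continue
        all_neg = (agg["n_neg"] == agg["n"]).sum()
        all_pos = (agg["n_neg"] == 0).sum()
        rows.append({"w": w, "lo": lo, "hi": hi, "n_genes": n_genes,
                     "frac_all_neg": all_neg / n_genes, "frac_all_pos": all_pos / n_genes})
    return pd.DataFrame(rows)
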