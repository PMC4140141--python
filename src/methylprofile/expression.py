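"""Linking methylation variation to differential mRNA expression.

Two complementary analyses:

* :func:`split_by_expression_sign` — genes are split by the sign of
  their differential expression (up vs down in disease) and the per-gene
  methylation summaries (mean methyl score, negative-probe frequency)
  are compared between the two sides with Mann-Whitney tests;
* :func:`windowed_correlation` — a 140-bp sliding window is moved along
  the TSS axis and, per window, a Spearman rank correlation is computed
  across genes between delta mRNA and a window-local methylation
  parameter (freq_neg, mean_score, or their product, the *interaction*).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .probes import mannwhitney_probe
from .windows import make_windows

logger = logging.getLogger("methylprofile")

PARAMETERS = ("freq_neg", "mean_score", "interaction")

DEFAULT_SCOPE = (-2000, 2000)


def spearman_rho_p(x, y) -> tuple[float, float]:
    """Spearman rank correlation with two-sided p.

    Uses the t-approximation for n ≥ 10 and the exact permutation null
    (full enumeration over the n! orderings, vectorised) for n < 10.
    Returns (NaN, NaN) for n < 3 or when either variable is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    if n >= 10:
        rho, p = sps.spearmanr(x, y)
        return float(rho), float(p)
    rx = sps.rankdata(x) - (n + 1) / 2
    ry = sps.rankdata(y) - (n + 1) / 2
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    rho = float((rx * ry).sum() / denom)
    perms = np.array(list(permutations(ry)))
    rho_null = perms @ rx / denom
    p = float((np.abs(rho_null) >= abs(rho) - 1e-12).mean())
    return rho, p


def gene_meth_summary(stats: pd.DataFrame, scope: tuple[int, int] = DEFAULT_SCOPE) -> pd.DataFrame:
    """Per-gene methylation summary over the significant probes in scope.

    freq_neg = n_negative / (n_negative + n_positive) (zero-sign probes
    excluded from the ratio; NaN when a gene has only zero-sign probes);
    mean_score averages over all significant probes in scope;
    interaction = freq_neg × mean_score. Only genes with at least one
    significant probe in scope appear.
    """
    lo, hi = min(scope), max(scope)
    sel = stats[stats["tss_offset"].between(lo, hi)]
    if sel.empty:
        return pd.DataFrame(columns=["gene_id", "group", "n_probes", "freq_neg",
                                     "mean_score", "interaction"])
    grp = sel.groupby(["gene_id", "group"], observed=True)
    out = grp.agg(
        n_probes=("probe_id", "count"),
        n_neg=("sign", lambda s: int((s == "negative").sum())),
        n_pos=("sign", lambda s: int((s == "positive").sum())),
        mean_score=("methyl_score", "mean"),
    ).reset_index()
    signed = out["n_neg"] + out["n_pos"]
    out["freq_neg"] = np.where(signed > 0, out["n_neg"] / signed.where(signed > 0, 1), np.nan)
    out["interaction"] = out["freq_neg"] * out["mean_score"]
    return out[["gene_id", "group", "n_probes", "freq_neg", "mean_score", "interaction"]]


@dataclass
class ExpressionSplit:
    """Up- vs down-regulated comparison of per-gene methylation summaries."""

    summary: pd.DataFrame  # gene-level table with delta_mrna and expr_sign
    n_up: int
    n_down: int
    p_methyl_score: float
    p_freq_neg: float
    median_score_up: float
    median_score_down: float
    median_freq_neg_up: float
    median_freq_neg_down: float


def split_by_expression_sign(
    stats: pd.DataFrame,
    expression: pd.DataFrame,
    scope: tuple[int, int] = DEFAULT_SCOPE,
) -> ExpressionSplit:
    """Compare methylation summaries between up- and down-regulated genes.

    Genes are joined to the expression table on gene_id (unmatched genes
    dropped and counted) and split by the sign of delta_mrna; the mean
    methyl score and the negative-probe frequency are each compared
    between the two sides with a two-sided Mann-Whitney test. Fewer than
    2 genes on either side is an error naming the side.
    """
    summary = gene_meth_summary(stats, scope=scope)
    merged = summary.merge(expression[["gene_id", "delta_mrna"]], on="gene_id", how="inner")
    dropped = len(summary) - len(merged)
    if dropped:
        logger.info("split_by_expression_sign: %d genes absent from expression table", dropped)
    merged["expr_sign"] = np.where(merged["delta_mrna"] > 0, "up", "down")
    up = merged[merged["expr_sign"] == "up"]
    down = merged[merged["expr_sign"] == "down"]
    for side, frame in (("up", up), ("down", down)):
        if len(frame) < 2:
            raise ValueError(f"fewer than 2 genes on the {side}-regulated side")
    p_score = mannwhitney_probe(up["mean_score"], down["mean_score"])
    up_fn = up["freq_neg"].dropna()
    down_fn = down["freq_neg"].dropna()
    p_freq = mannwhitney_probe(up_fn, down_fn)
    return ExpressionSplit(
        summary=merged, n_up=len(up), n_down=len(down),
        p_methyl_score=p_score, p_freq_neg=p_freq,
        median_score_up=float(up["mean_score"].median()),
        median_score_down=float(down["mean_score"].median()),
        median_freq_neg_up=float(up_fn.median()),
        median_freq_neg_down=float(down_fn.median()),
    )


def windowed_correlation(
    stats: pd.DataFrame,
    expression: pd.DataFrame,
    windows: pd.DataFrame | None = None,
    parameter: str = "interaction",
    min_genes: int = 10,
) -> pd.DataFrame:
    """Sliding-window Spearman correlation of methylation with expression.

    Per window, every gene with ≥1 significant probe inside the window
    gets a window-local summary (freq_neg over its signed probes there,
    mean_score over all its probes there, or their product); the chosen
    parameter is rank-correlated with delta_mrna across those genes.
    Windows with fewer than ``min_genes`` genes are masked (NaN rho/p).
    Returns columns (w, lo, hi, n_genes, rho, p_value).
    """
    if parameter not in PARAMETERS:
        raise ValueError(f"parameter must be one of {PARAMETERS}")
    if windows is None:
        windows = make_windows()
    joined = stats.merge(expression[["gene_id", "delta_mrna"]], on="gene_id", how="inner")
    if joined.empty:
        raise ValueError("no overlap between probe stats and expression table")
    codes, gene_index = pd.factorize(joined["gene_id"], sort=True)
    joined = joined.assign(_code=codes)
    delta = joined.drop_duplicates("_code").set_index("_code")["delta_mrna"] \
        .sort_index().to_numpy()
    n_genes_total = len(gene_index)

    order = np.argsort(joined["tss_offset"].to_numpy(), kind="mergesort")
    offs = joined["tss_offset"].to_numpy()[order]
    code = joined["_code"].to_numpy()[order]
    score = joined["methyl_score"].to_numpy(dtype=float)[order]
    sign = joined["sign"].to_numpy()[order]
    is_neg = (sign == "negative").astype(float)
    is_pos = (sign == "positive").astype(float)

    lo_arr = windows["lo"].to_numpy()
    hi_arr = windows["hi"].to_numpy()
    i0 = np.searchsorted(offs, lo_arr, side="left")
    i1 = np.searchsorted(offs, hi_arr, side="right")

    rows = np.full((len(windows), 3), np.nan)  # n, rho, p
    for k in range(len(windows)):
        a, b = i0[k], i1[k]
        if b - a == 0:
            rows[k, 0] = 0
            continue
        c = code[a:b]
        cnt = np.bincount(c, minlength=n_genes_total)
        neg = np.bincount(c, weights=is_neg[a:b], minlength=n_genes_total)
        pos = np.bincount(c, weights=is_pos[a:b], minlength=n_genes_total)
        ssum = np.bincount(c, weights=score[a:b], minlength=n_genes_total)
        present = cnt > 0
        signed = neg + pos
        if parameter == "mean_score":
            use = present
            x = ssum[use] / cnt[use]
        else:
            use = present & (signed > 0)
            fn = neg[use] / signed[use]
            x = fn if parameter == "freq_neg" else fn * (ssum[use] / cnt[use])
        n = int(use.sum())
        rows[k, 0] = n
        if n < min_genes:
            continue
        rho, p = spearman_rho_p(x, delta[use])
        rows[k, 1], rows[k, 2] = rho, p
    return pd.DataFrame({
        "w": windows["w"].to_numpy(), "lo": lo_arr, "hi": hi_arr,
        "n_genes": rows[:, 0].astype(int), "rho": rows[:, 1], "p_value": rows[:, 2],
    })
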