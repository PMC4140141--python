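"""Per-probe differential methylation statistics.

Each array probe is summarised by three quantities:

* a two-sided Mann-Whitney U p-value comparing the disease and healthy
  beta values (rank test — invariant to monotone transforms of beta);
* an FDR q-value (Storey's method by default, Benjamini-Hochberg as an
  alternative), computed over all probes in the initial selection;
* the *methyl score*, mean(disease beta) − mean(healthy beta), whose sign
  classifies the probe as *negative* (less methylated in disease),
  *positive* (more methylated in disease) or *zero*.

Downstream analyses use only the probes that survive
:func:`filter_significant` (q ≤ 0.05 within ±2,000 bp of the TSS by
default).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .io import ANNOTATION_COLUMNS, BetaMatrix

logger = logging.getLogger("methylprofile")

STAT_COLUMNS = ANNOTATION_COLUMNS[:4] + ["p_value", "q_value", "methyl_score", "sign"]

DEFAULT_Q_MAX = 0.05
DEFAULT_WINDOW = (-2000, 2000)


def _clean_pair(disease_values, healthy_values):
    x = np.asarray(disease_values, dtype=float)
    y = np.asarray(healthy_values, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need >=2 non-missing values per condition")
    return x, y


def mannwhitney_probe(disease_values, healthy_values) -> float:
    """Two-sided Mann-Whitney U p-value for one probe.

    Uses the exact null distribution when both groups have n ≤ 10 and the
    data are tie-free; otherwise the tie-corrected normal approximation
    with continuity correction. If every value is identical across both
    groups the test is degenerate and p = 1.0 is returned (logged).
    """
    x, y = _clean_pair(disease_values, healthy_values)
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0.0:
        logger.debug("degenerate probe: all values identical, p = 1.0")
        return 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(x) <= 10 and len(y) <= 10 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def methyl_score(disease_values, healthy_values) -> float:
    """mean(disease) − mean(healthy) beta, over non-missing values."""
    x, y = _clean_pair(disease_values, healthy_values)
    return float(x.mean() - y.mean())


def estimate_pi0(p_values, lambdas=None) -> float:
    """Storey estimate of the null proportion pi0.

    pi0(λ) = #{p > λ} / (m·(1−λ)) is evaluated on a λ-grid
    (0.05, 0.10, …, 0.95 by default), smoothed with a cubic polynomial,
    and read off at the largest λ; the result is clipped into (0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    lambdas = np.asarray(lambdas, dtype=float)
    m = len(p)
    pi0_lambda = np.array([(p > lam).mean() / (1.0 - lam) for lam in lambdas])
    coeffs = np.polyfit(lambdas, pi0_lambda, 3)
    pi0 = float(np.polyval(coeffs, lambdas.max()))
    if pi0 <= 0:
        logger.warning("pi0 smoother gave %.3g <= 0; clipping to 1/m", pi0)
        pi0 = 1.0 / m
    return min(pi0, 1.0)


def compute_qvalues(p_values, method: str = "storey") -> np.ndarray:
    """FDR q-values for a vector of p-values.

    method="storey": q_i = min over p_j ≥ p_i of pi0·m·p_j / rank(p_j),
    with pi0 estimated by :func:`estimate_pi0`.
    method="bh": the same with pi0 fixed at 1, i.e. Benjamini-Hochberg
    adjusted p-values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.isnan(p).any():
        raise ValueError("NaN p-values")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    if method != "storey":
        raise ValueError(f"unknown FDR method {method!r}")
    pi0 = estimate_pi0(p)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def classify_sign(scores) -> np.ndarray:
    """Map methyl scores to 'negative' / 'positive' / 'zero' labels."""
    s = np.asarray(scores, dtype=float)
    return np.where(s < 0, "negative", np.where(s > 0, "positive", "zero"))


def _matrix_pvalues(xd: np.ndarray, xh: np.ndarray) -> np.ndarray:
    """Vectorised asymptotic Mann-Whitney over the rows of two matrices."""
    pooled = np.hstack([xd, xh])
    degenerate = np.ptp(pooled, axis=1) == 0.0
    p = np.ones(xd.shape[0])
    if (~degenerate).any():
        res = sps.mannwhitneyu(
            xd[~degenerate], xh[~degenerate], alternative="two-sided",
            method="asymptotic", axis=1,
        )
        p[~degenerate] = np.minimum(res.pvalue, 1.0)
    if degenerate.any():
        logger.debug("%d degenerate probes set to p = 1.0", degenerate.sum())
    return p


def compute_probe_stats(
    beta: BetaMatrix,
    annotation: pd.DataFrame,
    fdr_method: str = "storey",
) -> pd.DataFrame:
    """Per-probe p, q, methyl score and sign, joined with the annotation.

    Probes with fewer than 2 non-missing values in either condition are
    dropped (logged). p- and q-values are computed once per probe; a
    probe annotated to several genes contributes one row per gene with
    the same statistics. q-values are estimated over all tested probes,
    i.e. the full initial selection, before any positional filtering.
    """
    probes = beta.probe_ids.intersection(pd.Index(annotation["probe_id"].unique()))
    n_unannotated = len(beta.probe_ids) - len(probes)
    if n_unannotated:
        logger.info("compute_probe_stats: %d probes lack annotation, skipped", n_unannotated)
    if len(probes) == 0:
        raise ValueError("no overlap between beta matrix and annotation probes")
    xd = beta.disease.loc[probes].to_numpy()
    xh = beta.healthy.loc[probes].to_numpy()
    enough = (np.sum(~np.isnan(xd), axis=1) >= 2) & (np.sum(~np.isnan(xh), axis=1) >= 2)
    if (~enough).any():
        logger.info(
            "compute_probe_stats: dropped %d probes with <2 values per condition",
            (~enough).sum(),
        )
    probes, xd, xh = probes[enough], xd[enough], xh[enough]

    no_missing = not (np.isnan(xd).any() or np.isnan(xh).any())
    small = xd.shape[1] <= 10 and xh.shape[1] <= 10
    if no_missing and not small:
        p = _matrix_pvalues(xd, xh)
        score = xd.mean(axis=1) - xh.mean(axis=1)
    else:
        p = np.array([mannwhitney_probe(a, b) for a, b in zip(xd, xh)])
        score = np.nanmean(xd, axis=1) - np.nanmean(xh, axis=1)

    q = compute_qvalues(p, method=fdr_method)
    per_probe = pd.DataFrame(
        {"probe_id": probes, "p_value": p, "q_value": q, "methyl_score": score,
         "sign": classify_sign(score)}
    )
    out = annotation.merge(per_probe, on="probe_id", how="inner")
    return out[STAT_COLUMNS].reset_index(drop=True)


def filter_significant(
    stats: pd.DataFrame,
    q_max: float = DEFAULT_Q_MAX,
    window: tuple[int, int] = DEFAULT_WINDOW,
) -> pd.DataFrame:
    """Keep probes with q ≤ q_max inside the TSS window (inclusive ends).

    The default window is [−2,000, +2,000]; a probe with q exactly equal
    to q_max is kept. Per-group survivor counts are logged; an empty
    survivor set is returned as an empty frame with a warning so that
    downstream stages can no-op gracefully.
    """
    lo, hi = min(window), max(window)
    keep = (stats["q_value"] <= q_max) & stats["tss_offset"].between(lo, hi)
    out = stats.loc[keep].reset_index(drop=True)
    if out.empty:
        logger.warning("filter_significant: no probes survive q<=%g in [%d,%d]", q_max, lo, hi)
    else:
        counts = out.groupby("group", observed=True)["probe_id"].count()
        logger.info("significant probes per group: %s", counts.to_dict())
    return out
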