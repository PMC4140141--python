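"""Cross-group comparisons of probe signs and methyl-score dispersion."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger("methylprofile")


@dataclass
class SignContingency:
    """Pearson chi-squared result on the groups x {negative, positive} table."""

    table: pd.DataFrame  # index: group, columns: n_negative, n_positive
    chi2_stat: float
    p_value: float
    dof: int
    low_expected: bool  # any expected cell < 1


def sign_counts(stats: pd.DataFrame) -> pd.DataFrame:
    """Negative/positive counts per gene group (zero-sign probes excluded)."""
    signed = stats[stats["sign"] != "zero"]
    tab = (
        signed.groupby(["group", "sign"], observed=True)["probe_id"].count()
        .unstack("sign", fill_value=0)
        .reindex(columns=["negative", "positive"], fill_value=0)
    )
    tab.columns = ["n_negative", "n_positive"]
    return tab


def sign_contingency_test(counts: pd.DataFrame) -> SignContingency:
    """Pearson chi-squared homogeneity test of sign frequencies across groups.

    ``counts`` has one row per group with columns n_negative and
    n_positive (as produced by :func:`sign_counts` or entered from a
    published table). No continuity correction is applied. An expected
    cell below 1 attaches a warning flag rather than failing.
    """
    if len(counts) < 2:
        raise ValueError("need >=2 groups")
    obs = counts[["n_negative", "n_positive"]].to_numpy()
    if (obs.sum(axis=1) == 0).any():
        raise ValueError("every group needs >=1 signed probe")
    chi2, p, dof, expected = sps.chi2_contingency(obs, correction=False)
    low = bool((expected < 1).any())
    if low:
        logger.warning("sign_contingency_test: expected cell < 1; chi-squared approximation weak")
    return SignContingency(table=counts.copy(), chi2_stat=float(chi2), p_value=float(p),
                           dof=int(dof), low_expected=low)


def score_dispersion_test(scores_a, scores_b) -> tuple[float, float]:
    """Two-sided F test of var(a)/var(b).

    Returns (F ratio, two-sided p) with (n_a−1, n_b−1) degrees of
    freedom. Zero variance on either side is an error.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >=2 values per side")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 or vb == 0:
        raise ValueError("zero variance in F test input")
    f = va / vb
    dist = sps.f(len(a) - 1, len(b) - 1)
    p = 2.0 * min(dist.cdf(f), dist.sf(f))
    return float(f), float(min(p, 1.0))


def dispersion_tests(scores_by_group: dict, mode: str = "pairwise") -> pd.DataFrame:
    """F tests of methyl-score variance between groups.

    mode="pairwise" runs every unordered pair; mode="pooled" tests each
    group against the concatenation of the others.
    """
    rows = []
    if mode == "pairwise":
        for (ga, a), (gb, b) in combinations(scores_by_group.items(), 2):
            f, p = score_dispersion_test(a, b)
            rows.append({"group_a": ga, "group_b": gb, "f_ratio": f, "p_value": p,
                         "n_a": len(a), "n_b": len(b)})
    elif mode == "pooled":
        for ga, a in scores_by_group.items():
            rest = np.concatenate([np.asarray(v, float) for g, v in scores_by_group.items()
                                   if g != ga])
            f, p = score_dispersion_test(a, rest)
            rows.append({"group_a": ga, "group_b": "rest", "f_ratio": f, "p_value": p,
                         "n_a": len(a), "n_b": len(rest)})
    else:
        raise ValueError(f"unknown dispersion mode {mode!r}")
    return pd.DataFrame(rows)


def score_summary(scores_by_group: dict) -> pd.DataFrame:
    """Tukey five-number summary (type-7 quartiles) of scores per group."""
    rows = []
    for group, scores in scores_by_group.items():
        s = np.asarray(scores, dtype=float)
        if s.size == 0:
            raise ValueError(f"group {group!r} has no scores")
        q0, q1, q2, q3, q4 = np.percentile(s, [0, 25, 50, 75, 100])
        rows.append({"group": group, "n": s.size, "min": q0, "q1": q1, "median": q2,
                     "q3": q3, "max": q4, "iqr": q3 - q1})
    return pd.DataFrame(rows)
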