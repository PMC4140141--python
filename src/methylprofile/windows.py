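"""TSS-relative sliding-window profiles and between-group difference tracks.

Windows are inclusive integer intervals [w − width, w] labelled by their
5′ (more positive) offset ``w`` and ordered from the gene-body end of
the scan (+2,000 by default) toward the promoter end (−2,000): the first
default window covers +1,860…+2,000, the last −2,000…−1,860. Inclusive
ends mean a probe sitting exactly on a boundary is counted in both
adjacent windows; with a one-base shift each probe appears in up to
``width + 1`` windows.
"""

from __future__ import annotations

import logging
from functools import lru_cache

import numpy as np
import pandas as pd

from .probes import mannwhitney_probe

logger = logging.getLogger("methylprofile")

DEFAULT_START = 2000
DEFAULT_END = -2000
DEFAULT_WIDTH = 140
DEFAULT_STEP = 1


def make_windows(start: int = DEFAULT_START, end: int = DEFAULT_END,
                 width: int = DEFAULT_WIDTH, step: int = DEFAULT_STEP) -> pd.DataFrame:
    """Ordered sliding windows from ``start`` down to ``end``.

    Returns a frame with columns (w, lo, hi): hi = w, lo = w − width,
    w stepping down by ``step`` while the window still fits inside
    [end, start]. For the defaults there are 3,861 windows.
    """
    if width <= 0 or step <= 0:
        raise ValueError("width and step must be > 0")
    if start <= end:
        raise ValueError("start must exceed end")
    n = (start - end - width) // step + 1
    if n < 1:
        raise ValueError("range shorter than one window")
    w = start - step * np.arange(n)
    return pd.DataFrame({"w": w, "lo": w - width, "hi": w})


class _SortedTrack:
    """Probe arrays sorted by offset, with cumulative sums for O(1) window counts."""

    def __init__(self, stats: pd.DataFrame):
        df = stats.sort_values("tss_offset", kind="mergesort")
        self.offsets = df["tss_offset"].to_numpy()
        self.scores = df["methyl_score"].to_numpy(dtype=float)
        sign = df["sign"].to_numpy()
        self.is_neg = sign == "negative"
        self.is_pos = sign == "positive"
        self.cum_neg = np.concatenate([[0], np.cumsum(self.is_neg)])
        self.cum_pos = np.concatenate([[0], np.cumsum(self.is_pos)])
        self.cum_score = np.concatenate([[0.0], np.cumsum(self.scores)])

    def slice_bounds(self, lo, hi):
        i0 = np.searchsorted(self.offsets, lo, side="left")
        i1 = np.searchsorted(self.offsets, hi, side="right")
        return i0, i1


def profile_group(stats: pd.DataFrame, windows: pd.DataFrame) -> pd.DataFrame:
    """Per-window sign counts, negative-probe frequency and mean methyl score.

    ``stats`` should already be significance-filtered. freq_neg is
    n_negative / (n_negative + n_positive) — zero-sign probes count
    toward n_probes and the mean score but not the frequency — and is
    NaN where no signed probe falls in the window.
    """
    tr = _SortedTrack(stats)
    i0, i1 = tr.slice_bounds(windows["lo"].to_numpy(), windows["hi"].to_numpy())
    n = i1 - i0
    n_neg = tr.cum_neg[i1] - tr.cum_neg[i0]
    n_pos = tr.cum_pos[i1] - tr.cum_pos[i0]
    signed = n_neg + n_pos
    with np.errstate(invalid="ignore", divide="ignore"):
        freq_neg = np.where(signed > 0, n_neg / np.where(signed > 0, signed, 1), np.nan)
        mean_score = np.where(n > 0, (tr.cum_score[i1] - tr.cum_score[i0]) / np.where(n > 0, n, 1),
                              np.nan)
    return pd.DataFrame({
        "w": windows["w"].to_numpy(), "lo": windows["lo"].to_numpy(),
        "hi": windows["hi"].to_numpy(), "n_probes": n, "n_negative": n_neg,
        "n_positive": n_pos, "freq_neg": freq_neg, "mean_score": mean_score,
    })


@lru_cache(maxsize=65536)
def _indicator_mw_p(neg_a: int, pos_a: int, neg_b: int, pos_b: int) -> float:
    """Mann-Whitney p on −1/+1 sign indicators, memoised by the 2x2 counts."""
    a = np.concatenate([-np.ones(neg_a), np.ones(pos_a)])
    b = np.concatenate([-np.ones(neg_b), np.ones(pos_b)])
    return mannwhitney_probe(a, b)


def _proportion_p(neg_a: int, pos_a: int, neg_b: int, pos_b: int) -> float:
    from scipy.stats import chi2_contingency

    table = np.array([[neg_a, pos_a], [neg_b, pos_b]])
    if (table.sum(axis=0) == 0).any():
        return 1.0
    return float(chi2_contingency(table, correction=False)[1])


def difference_track(
    stats_a: pd.DataFrame,
    stats_b: pd.DataFrame,
    windows: pd.DataFrame | None = None,
    mode: str = "freq_neg",
    min_probes: int = 3,
    test: str = "mannwhitney",
) -> pd.DataFrame:
    """Per-window difference (group A − group B) with per-window significance.

    mode="freq_neg": delta is the difference in negative-probe frequency;
    the per-window test is Mann-Whitney on the −1/+1 sign indicators of
    the two groups' probes (or a two-proportion chi-squared with
    test="proportion"). mode="mean_score": delta is the difference of
    mean methyl scores, tested by Mann-Whitney on the per-probe scores.
    Windows where either group has fewer than ``min_probes`` probes of
    the tested kind are masked (delta and p NaN). No correction across
    windows is applied — the track reports raw per-window p-values.
    """
    if windows is None:
        windows = make_windows()
    if mode not in ("freq_neg", "mean_score"):
        raise ValueError(f"unknown mode {mode!r}")
    if test not in ("mannwhitney", "proportion"):
        raise ValueError(f"unknown test {test!r}")
    if test == "proportion" and mode != "freq_neg":
        raise ValueError("the proportion test applies only to freq_neg mode")

    prof_a = profile_group(stats_a, windows)
    prof_b = profile_group(stats_b, windows)
    tr_a, tr_b = _SortedTrack(stats_a), _SortedTrack(stats_b)

    if mode == "freq_neg":
        n_a = (prof_a["n_negative"] + prof_a["n_positive"]).to_numpy()
        n_b = (prof_b["n_negative"] + prof_b["n_positive"]).to_numpy()
        delta = prof_a["freq_neg"].to_numpy() - prof_b["freq_neg"].to_numpy()
    else:
        n_a = prof_a["n_probes"].to_numpy()
        n_b = prof_b["n_probes"].to_numpy()
        delta = prof_a["mean_score"].to_numpy() - prof_b["mean_score"].to_numpy()

    masked = (n_a < min_probes) | (n_b < min_probes)
    p = np.full(len(windows), np.nan)
    lo = windows["lo"].to_numpy()
    hi = windows["hi"].to_numpy()
    for k in np.flatnonzero(~masked):
        if mode == "freq_neg":
            counts = (int(prof_a["n_negative"].iat[k]), int(prof_a["n_positive"].iat[k]),
                      int(prof_b["n_negative"].iat[k]), int(prof_b["n_positive"].iat[k]))
            p[k] = _indicator_mw_p(*counts) if test == "mannwhitney" else _proportion_p(*counts)
        else:
            ia0, ia1 = tr_a.slice_bounds(lo[k], hi[k])
            ib0, ib1 = tr_b.slice_bounds(lo[k], hi[k])
            p[k] = mannwhitney_probe(tr_a.scores[ia0:ia1], tr_b.scores[ib0:ib1])
    delta = np.where(masked, np.nan, delta)
    return pd.DataFrame({
        "w": windows["w"].to_numpy(), "lo": lo, "hi": hi, "delta": delta,
        "p_value": p, "n_a": n_a, "n_b": n_b, "masked": masked,
    })


def significant_runs(track: pd.DataFrame, alpha: float = 0.05,
                     direction: str | None = None) -> pd.DataFrame:
    """Contiguous runs of significant windows in a difference track.

    direction="positive"/"negative" additionally requires the sign of
    delta. Returns one row per run with the 5′/3′ window labels, the
    union genomic span (span_lo..span_hi) and the run length in windows,
    ordered as the track is (5′ first).
    """
    sig = (track["p_value"] < alpha) & ~track["masked"]
    if direction == "positive":
        sig &= track["delta"] > 0
    elif direction == "negative":
        sig &= track["delta"] < 0
    elif direction is not None:
        raise ValueError(f"unknown direction {direction!r}")
    sig = sig.to_numpy()
    rows = []
    k = 0
    while k < len(sig):
        if sig[k]:
            j = k
            while j + 1 < len(sig) and sig[j + 1]:
                j += 1
            rows.append({
                "w_first": int(track["w"].iat[k]), "w_last": int(track["w"].iat[j]),
                "span_lo": int(track["lo"].iat[j]), "span_hi": int(track["hi"].iat[k]),
                "n_windows": j - k + 1,
            })
            k = j + 1
        else:
            k += 1
    return pd.DataFrame(rows, columns=["w_first", "w_last", "span_lo", "span_hi", "n_windows"])
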