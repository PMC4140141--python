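"""Optional matplotlib figures for the window and cluster analyses."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd


def plot_score_boxplot(scores_by_group: dict, path) -> None:
    """Boxplot of methyl scores per gene group."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.boxplot(list(scores_by_group.values()), tick_labels=list(scores_by_group.keys()),
               showfliers=False)
    ax.axhline(0.0, color="grey", lw=0.5)
    ax.set_ylabel("methyl score (disease − healthy beta)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_difference_track(track: pd.DataFrame, path, alpha: float = 0.05,
                          ylabel: str = "delta") -> None:
    """Difference track along the TSS axis, significant windows highlighted."""
    fig, ax = plt.subplots(figsize=(7, 3.5))
    ok = ~track["masked"]
    sig = ok & (track["p_value"] < alpha)
    ax.plot(track.loc[ok, "w"], track.loc[ok, "delta"], ".", ms=2, color="lightgrey")
    ax.plot(track.loc[sig, "w"], track.loc[sig, "delta"], ".", ms=2, color="crimson")
    ax.axhline(0.0, color="grey", lw=0.5)
    ax.axvline(0.0, color="grey", lw=0.5, ls="--")
    ax.set_xlabel("window 5' offset from TSS (bp)")
    ax.set_ylabel(ylabel)
    ax.invert_xaxis()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_correlation_track(corr: pd.DataFrame, path, alpha: float = 0.05) -> None:
    """Windowed Spearman rho with per-window gene counts on a twin axis."""
    fig, ax = plt.subplots(figsize=(7, 3.5))
    ok = corr["rho"].notna()
    sig = ok & (corr["p_value"] < alpha)
    ax.plot(corr.loc[ok, "w"], corr.loc[ok, "rho"], "-", lw=0.8, color="black")
    ax.plot(corr.loc[sig, "w"], corr.loc[sig, "rho"], ".", ms=2, color="crimson")
    ax.axhline(0.0, color="grey", lw=0.5)
    ax.set_xlabel("window 5' offset from TSS (bp)")
    ax.set_ylabel("Spearman rho")
    ax2 = ax.twinx()
    ax2.plot(corr["w"], corr["n_genes"], ":", color="steelblue", lw=0.8)
    ax2.set_ylabel("genes per window", color="steelblue")
    ax.invert_xaxis()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
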