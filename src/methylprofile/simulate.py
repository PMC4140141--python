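"""Synthetic two-condition methylation studies with planted effects.

The generator emulates the design under study: beta values for 12
disease and 11 healthy samples over three gene classes (immune /
cell-cycle / stable, 1,284 / 1,038 / 575 genes), probes scattered from
2,500 bp upstream of the TSS to the gene end, a position-dependent
hypomethylation effect planted in one class, and per-gene mRNA
log-fold changes linearly coupled (with noise) to the planted
methylation change. Beta values are drawn from a Beta distribution
parameterised by (mean, precision), so all values are bounded in (0, 1)
and skewed like array betas.

Besides the planted effect, a sign-balanced *background* of differential
methylation touches a configurable fraction of probes in every group, so
that all groups contribute significant probes the way two-condition
tissue data do; the planted effect is added on top of it.

All randomness flows through one seeded generator in a fixed draw order
(gene lengths → probe counts → probe positions → baseline means →
background flags and shifts → beta values, disease block first →
expression noise), so a config is fully reproducible from its seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import probes as probestats
from .io import ANNOTATION_COLUMNS, BetaMatrix, GeneSet

logger = logging.getLogger("methylprofile")

#: gene-class sizes from the study design (immune, cellcycle, stable)
DEFAULT_GROUP_SIZES = {"immune": 1284, "cellcycle": 1038, "stable": 575}


@dataclass
class SimConfig:
    """Parameters of one synthetic study.

    The defaults reproduce the design conditions: 12 disease vs 11
    healthy samples, class sizes 1,284/1,038/575, probes from −2,500 bp
    to the gene end (Poisson mean 6 per gene), and a −0.3 beta-scale
    hypomethylation effect planted in immune-class genes between −1,500
    and +900 bp of the TSS, anti-correlated with expression
    (expr_slope < 0).
    """

    n_disease: int = 12
    n_healthy: int = 11
    genes_per_group: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    probes_per_gene_mean: float = 6.0
    gene_length_range: tuple[int, int] = (2000, 20000)
    upstream_limit: int = -2500
    baseline_beta_range: tuple[float, float] = (0.1, 0.9)
    beta_precision: float = 50.0
    effect_window: tuple[int, int] = (-1500, 900)
    effect_delta: float = -0.3
    effect_group: str = "immune"
    background_frac: float = 0.25
    background_sd: float = 0.2
    expr_slope: float = -5.0
    expr_noise_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_disease < 2 or self.n_healthy < 2:
            raise ValueError("need >=2 samples per condition")
        if not self.genes_per_group or any(n <= 0 for n in self.genes_per_group.values()):
            raise ValueError("genes_per_group counts must be > 0")
        if self.probes_per_gene_mean <= 0:
            raise ValueError("probes_per_gene_mean must be > 0")
        if abs(self.effect_delta) >= 1:
            raise ValueError("|effect_delta| must be < 1")
        if self.beta_precision <= 0:
            raise ValueError("beta_precision must be > 0")
        lo, hi = self.baseline_beta_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("baseline_beta_range must be inside (0, 1)")
        if self.effect_group not in self.genes_per_group:
            raise ValueError(f"effect_group {self.effect_group!r} not a simulated group")
        if self.gene_length_range[0] < 200 or self.gene_length_range[0] > self.gene_length_range[1]:
            raise ValueError("invalid gene_length_range")
        if self.expr_noise_sd < 0:
            raise ValueError("expr_noise_sd must be >= 0")
        if not (0.0 <= self.background_frac <= 1.0):
            raise ValueError("background_frac must be in [0, 1]")
        if self.background_sd < 0:
            raise ValueError("background_sd must be >= 0")


@dataclass
class GroundTruth:
    """Planted truth of a simulation.

    probe_truth: per probe — affected flag and realised mean shift
    (after clipping) of the disease mean.
    gene_truth: per gene — mean planted shift over its probes inside the
    effect window and the noise-free delta_mrna.
    """

    probe_truth: pd.DataFrame
    gene_truth: pd.DataFrame


class SimulatedStudy(NamedTuple):
    beta: BetaMatrix
    annotation: pd.DataFrame
    gene_sets: list
    expression: pd.DataFrame
    truth: GroundTruth
    config: SimConfig


# keep Beta-distribution means away from the degenerate endpoints
_MEAN_CLIP = (0.01, 0.99)


def simulate(config: SimConfig) -> SimulatedStudy:
    """Draw one synthetic study; bit-reproducible from ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes = []
    for group, n_genes in config.genes_per_group.items():
        lengths = rng.integers(config.gene_length_range[0], config.gene_length_range[1] + 1,
                               size=n_genes)
        for i, length in enumerate(lengths):
            genes.append((f"{group.upper()[:3]}{i + 1:04d}", group, int(length)))
    gene_df = pd.DataFrame(genes, columns=["gene_id", "group", "gene_end_offset"])

    n_probes_per_gene = rng.poisson(config.probes_per_gene_mean, size=len(gene_df))
    rows = []
    for (gene_id, group, length), k in zip(genes, n_probes_per_gene):
        if k == 0:
            continue
        offsets = rng.integers(config.upstream_limit, length + 1, size=k)
        for off in offsets:
            rows.append((gene_id, group, int(off), length))
    annot = pd.DataFrame(rows, columns=["gene_id", "group", "tss_offset", "gene_end_offset"])
    annot.insert(0, "probe_id", [f"cg{i + 1:08d}" for i in range(len(annot))])
    annot = annot[ANNOTATION_COLUMNS]

    n = len(annot)
    lo, hi = config.baseline_beta_range
    base_mean = rng.uniform(lo, hi, size=n)

    # background differential methylation: a sign-balanced random shift on
    # a fraction of probes in every group, so that all groups contribute
    # significant probes (as two-condition tissue data do)
    background = np.zeros(n)
    if config.background_frac > 0 and config.background_sd > 0:
        is_bg = rng.random(n) < config.background_frac
        background[is_bg] = rng.normal(0.0, config.background_sd, size=is_bg.sum())

    wlo, whi = min(config.effect_window), max(config.effect_window)
    affected = (
        (annot["group"] == config.effect_group)
        & annot["tss_offset"].between(wlo, whi)
    ).to_numpy()
    disease_mean = base_mean + background
    disease_mean[affected] += config.effect_delta
    clipped = (disease_mean < _MEAN_CLIP[0]) | (disease_mean > _MEAN_CLIP[1])
    if clipped.any():
        logger.info("simulate: clipped %d shifted disease means into (0.01, 0.99)", clipped.sum())
        disease_mean = np.clip(disease_mean, *_MEAN_CLIP)
    true_shift = disease_mean - base_mean

    k = config.beta_precision

    def draw(means: np.ndarray, n_samples: int) -> np.ndarray:
        a = means[:, None] * k
        b = (1.0 - means[:, None]) * k
        return rng.beta(a, b, size=(len(means), n_samples))

    xd = draw(disease_mean, config.n_disease)
    xh = draw(base_mean, config.n_healthy)
    sample_ids = [f"D{i + 1:02d}" for i in range(config.n_disease)] + [
        f"H{i + 1:02d}" for i in range(config.n_healthy)
    ]
    values = pd.DataFrame(np.hstack([xd, xh]), index=annot["probe_id"], columns=sample_ids)
    condition = pd.Series(
        ["disease"] * config.n_disease + ["healthy"] * config.n_healthy,
        index=sample_ids, name="condition",
    )
    beta = BetaMatrix(values=values, condition=condition)

    in_window = annot["tss_offset"].between(wlo, whi).to_numpy()
    shift_in_window = pd.Series(np.where(in_window, true_shift, np.nan), index=annot.index)
    gene_shift = (
        pd.DataFrame({"gene_id": annot["gene_id"], "shift": shift_in_window})
        .groupby("gene_id")["shift"].mean()
        .reindex(gene_df["gene_id"])
        .fillna(0.0)
    )
    true_delta = config.expr_slope * gene_shift.to_numpy()
    noise = rng.normal(0.0, config.expr_noise_sd, size=len(gene_df)) if config.expr_noise_sd > 0 \
        else np.zeros(len(gene_df))
    delta_mrna = true_delta + noise
    expr = pd.DataFrame({"gene_id": gene_df["gene_id"], "delta_mrna": delta_mrna})
    zero = expr["delta_mrna"] == 0.0
    if zero.any():
        logger.info("simulate: %d genes with delta_mrna == 0 excluded from expression", zero.sum())
        expr = expr.loc[~zero].reset_index(drop=True)

    gene_sets = [
        GeneSet(name=group, members=frozenset(gene_df.loc[gene_df["group"] == group, "gene_id"]))
        for group in config.genes_per_group
    ]
    truth = GroundTruth(
        probe_truth=pd.DataFrame(
            {"probe_id": annot["probe_id"], "gene_id": annot["gene_id"],
             "affected": affected, "true_shift": true_shift}
        ),
        gene_truth=pd.DataFrame(
            {"gene_id": gene_df["gene_id"], "group": gene_df["group"],
             "true_window_shift": gene_shift.to_numpy(), "true_delta_mrna": true_delta}
        ),
    )
    return SimulatedStudy(beta, annot, gene_sets, expr, truth, config)


def null_calibration(config: SimConfig, n_reps: int = 10) -> pd.DataFrame:
    """Empirical p/q behaviour of the testing stack under the global null.

    Re-simulates ``n_reps`` studies with effect_delta and the
    differential background both forced to 0 (seeds config.seed,
    config.seed+1, …), runs the per-probe tests, and
    reports per replicate the Kolmogorov-Smirnov distance of the
    p-values from Uniform(0,1) and the fractions of probes at p ≤ 0.05
    and q ≤ 0.05. With a rank test on small samples the p-value
    distribution is discrete and sub-uniform, so the q ≤ 0.05 fraction
    should be near zero when all nulls are true.
    """
    rows = []
    for rep in range(n_reps):
        cfg = replace(config, effect_delta=0.0, background_frac=0.0, seed=config.seed + rep)
        study = simulate(cfg)
        stats = probestats.compute_probe_stats(study.beta, study.annotation)
        per_probe = stats.drop_duplicates("probe_id")
        p = per_probe["p_value"].to_numpy()
        q = per_probe["q_value"].to_numpy()
        ks = sps.kstest(p, "uniform").statistic
        rows.append(
            {"rep": rep, "seed": cfg.seed, "n_probes": len(p), "ks_stat": float(ks),
             "frac_p05": float((p <= 0.05).mean()), "frac_q05": float((q <= 0.05).mean())}
        )
    return pd.DataFrame(rows)
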