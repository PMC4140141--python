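"""End-to-end orchestration: inputs -> statistics -> report bundle.

``run_all`` executes the stages in a fixed order (probe stats → group
comparison → window scan → cluster analysis → expression link), writes
every intermediate table as TSV, echoes the fully resolved configuration
as YAML, and renders a markdown summary whose every number is
re-derivable from the emitted TSVs. A missing expression table skips
the expression stage with a warning; any other stage error aborts with
the stage name.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import clusters as cl
from . import expression as ex
from . import groups as gr
from . import io as mio
from . import probes as pr
from . import windows as wd
from .simulate import SimConfig, simulate

logger = logging.getLogger("methylprofile")

EXIT_OK = 0
EXIT_CONFIG = 2
EXIT_DATA = 3
EXIT_DEGENERATE = 4


class PipelineError(RuntimeError):
    def __init__(self, stage: str, exit_code: int, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
        self.exit_code = exit_code


@dataclass
class PipelineConfig:
    """Inputs and thresholds for one full run.

    Either ``sim`` (a :class:`~methylprofile.simulate.SimConfig`) or the
    four input paths must be provided. Thresholds default to the values
    used throughout the analysis (q ≤ 0.05 within ±2,000 bp, 140-bp /
    1-base windows, promoter −1,700…0 with ≥3 probes, 800-bp / 50-base
    cluster scan with ≥4 probes, interaction parameter with ≥10 genes).
    """

    outdir: str = "methylprofile_out"
    sim: SimConfig | None = None
    beta_path: str | None = None
    sample_sheet_path: str | None = None
    annotation_path: str | None = None
    expression_path: str | None = None
    q_max: float = pr.DEFAULT_Q_MAX
    fdr_method: str = "storey"
    scope: tuple[int, int] = pr.DEFAULT_WINDOW
    window_width: int = wd.DEFAULT_WIDTH
    window_step: int = wd.DEFAULT_STEP
    min_probes_window: int = 3
    promoter: tuple[int, int] = cl.PROMOTER
    min_probes_promoter: int = 3
    scan_range: tuple[int, int] = (750, -1500)
    scan_width: int = 800
    scan_step: int = 50
    min_probes_scan: int = 4
    correlation_parameter: str = "interaction"
    min_genes: int = 10
    dispersion_mode: str = "pairwise"
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.sim is None and (self.beta_path is None or self.sample_sheet_path is None
                                 or self.annotation_path is None):
            raise PipelineError("config", EXIT_CONFIG,
                                "need either a sim config or beta/sample-sheet/annotation paths")
        if not (0.0 <= self.q_max <= 1.0):
            raise PipelineError("config", EXIT_CONFIG, "q_max must be in [0, 1]")
        if self.fdr_method not in ("storey", "bh"):
            raise PipelineError("config", EXIT_CONFIG, f"unknown fdr_method {self.fdr_method!r}")
        if self.correlation_parameter not in ex.PARAMETERS:
            raise PipelineError("config", EXIT_CONFIG,
                                f"unknown correlation parameter {self.correlation_parameter!r}")


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return list(obj)
    return obj


@dataclass
class PipelineResult:
    stats: pd.DataFrame
    significant: pd.DataFrame
    contingency: gr.SignContingency | None
    dispersion: pd.DataFrame | None
    summary: pd.DataFrame | None
    profiles: dict
    difference_tracks: dict
    cluster_calls: pd.DataFrame
    cluster_freqs: pd.DataFrame
    cluster_enrichment: gr.SignContingency | None
    cluster_scan: pd.DataFrame | None
    expression_splits: dict
    correlations: dict
    outdir: Path


def _stage(name, exit_code=EXIT_DATA):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as err:
                raise PipelineError(name, exit_code, str(err)) from err
        return wrapped
    return deco


def run_all(config: PipelineConfig) -> PipelineResult:
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- inputs -----------------------------------------------------------
    if config.sim is not None:
        sim_cfg = dataclasses.replace(config.sim, seed=config.seed)
        study = simulate(sim_cfg)
        beta, annotation, expression = study.beta, study.annotation, study.expression
        mio.save_beta_matrix(beta, outdir / "beta.tsv", outdir / "samples.tsv")
        mio.save_annotation(annotation, outdir / "annotation.tsv")
        mio.save_expression(expression, outdir / "expression.tsv")
        study.truth.probe_truth.to_csv(outdir / "truth_probes.tsv", sep="\t", index=False)
        study.truth.gene_truth.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
    else:
        beta = _stage("load")(mio.load_beta_matrix)(config.beta_path, config.sample_sheet_path)
        annotation = _stage("load")(mio.load_annotation)(config.annotation_path)
        expression = None
        if config.expression_path is not None:
            expression = _stage("load")(mio.load_expression)(config.expression_path)
        else:
            logger.warning("no expression table given; expression stage will be skipped")

    # --- probe statistics -------------------------------------------------
    stats = _stage("probe_stats")(pr.compute_probe_stats)(
        beta, annotation, fdr_method=config.fdr_method)
    stats.to_csv(outdir / "probe_stats.tsv", sep="\t", index=False, na_rep=mio.MISSING)
    significant = pr.filter_significant(stats, q_max=config.q_max, window=config.scope)
    significant.to_csv(outdir / "significant.tsv", sep="\t", index=False, na_rep=mio.MISSING)

    degenerate = significant.empty
    if degenerate:
        logger.warning("empty survivor set: downstream stages degenerate")

    contingency = dispersion = summary = None
    profiles: dict = {}
    tracks: dict = {}
    calls = pd.DataFrame(columns=["gene_id", "group", "n_sig_probes", "n_neg", "n_pos",
                                  "category"])
    cluster_freqs = pd.DataFrame(columns=["group", "neg", "pos", "negpos", "total",
                                          "cluster_frequency", "frac_neg"])
    enrichment = scan = None
    splits: dict = {}
    corrs: dict = {}

    if not degenerate:
        group_names = [g for g in significant["group"].unique() if g != "other"]

        # --- group comparison --------------------------------------------
        counts = gr.sign_counts(significant.loc[significant["group"] != "other"])
        if len(counts) >= 2:
            contingency = _stage("group_comparison")(gr.sign_contingency_test)(counts)
            counts.to_csv(outdir / "sign_contingency.tsv", sep="\t")
        scores_by_group = {
            g: significant.loc[significant["group"] == g, "methyl_score"].to_numpy()
            for g in group_names
        }
        if len(scores_by_group) >= 2:
            dispersion = _stage("group_comparison")(gr.dispersion_tests)(
                scores_by_group, mode=config.dispersion_mode)
            dispersion.to_csv(outdir / "dispersion.tsv", sep="\t", index=False)
        summary = gr.score_summary(scores_by_group)
        summary.to_csv(outdir / "score_summary.tsv", sep="\t", index=False)

        # --- window scan ---------------------------------------------------
        win = wd.make_windows(start=max(config.scope), end=min(config.scope),
                              width=config.window_width, step=config.window_step)
        for g in group_names:
            prof = wd.profile_group(significant[significant["group"] == g], win)
            profiles[g] = prof
            prof.to_csv(outdir / f"window_profile_{g}.tsv", sep="\t", index=False,
                        na_rep=mio.MISSING)
        for i, ga in enumerate(group_names):
            for gb in group_names[i + 1:]:
                for mode in ("freq_neg", "mean_score"):
                    track = _stage("window_scan")(wd.difference_track)(
                        significant[significant["group"] == ga],
                        significant[significant["group"] == gb],
                        win, mode=mode, min_probes=config.min_probes_window)
                    tracks[(ga, gb, mode)] = track
                    track.to_csv(outdir / f"diff_{ga}_minus_{gb}_{mode}.tsv", sep="\t",
                                 index=False, na_rep=mio.MISSING)

        # --- cluster analysis ---------------------------------------------
        calls = _stage("cluster_analysis")(cl.classify_promoter_clusters)(
            significant, promoter=config.promoter, min_probes=config.min_probes_promoter)
        calls.to_csv(outdir / "cluster_calls.tsv", sep="\t", index=False)
        freq_rows = []
        for g in group_names:
            sub = calls[calls["group"] == g]
            if sub.empty:
                continue
            frac, cnts = cl.cluster_frequency(sub)
            freq_rows.append({"group": g, **cnts, "cluster_frequency": frac,
                              "frac_neg": cnts["neg"] / cnts["total"]})
        cluster_freqs = pd.DataFrame(freq_rows)
        if not cluster_freqs.empty:
            cluster_freqs.to_csv(outdir / "cluster_frequencies.tsv", sep="\t", index=False)
        if calls["group"].nunique() >= 2:
            enrichment = _stage("cluster_analysis")(cl.neg_enrichment_test)(calls)
        scan_group = config.sim.effect_group if config.sim is not None else "immune"
        scan_stats = significant[significant["group"] == scan_group]
        if not scan_stats.empty:
            scan = _stage("cluster_analysis")(cl.scan_cluster_windows)(
                scan_stats, start=max(config.scan_range), end=min(config.scan_range),
                width=config.scan_width, step=config.scan_step,
                min_probes=config.min_probes_scan)
            scan.to_csv(outdir / f"cluster_scan_{scan_group}.tsv", sep="\t", index=False,
                        na_rep=mio.MISSING)

        # --- expression link ------------------------------------------------
        if expression is not None:
            for g in group_names:
                sub = significant[significant["group"] == g]
                try:
                    splits[g] = ex.split_by_expression_sign(sub, expression, scope=config.scope)
                except ValueError as err:
                    logger.warning("expression split skipped for %s: %s", g, err)
                corr = _stage("expression_link")(ex.windowed_correlation)(
                    sub, expression, win, parameter=config.correlation_parameter,
                    min_genes=config.min_genes)
                corrs[g] = corr
                corr.to_csv(outdir / f"correlation_{g}.tsv", sep="\t", index=False,
                            na_rep=mio.MISSING)
            if splits:
                split_table = pd.DataFrame([
                    {"group": g, "n_up": s.n_up, "n_down": s.n_down,
                     "p_methyl_score": s.p_methyl_score, "p_freq_neg": s.p_freq_neg,
                     "median_score_up": s.median_score_up,
                     "median_score_down": s.median_score_down,
                     "median_freq_neg_up": s.median_freq_neg_up,
                     "median_freq_neg_down": s.median_freq_neg_down}
                    for g, s in splits.items()
                ])
                split_table.to_csv(outdir / "expression_split.tsv", sep="\t", index=False)

    resolved = _to_plain(config)
    (outdir / "config.yaml").write_text(yaml.safe_dump(resolved, sort_keys=False))

    result = PipelineResult(
        stats=stats, significant=significant, contingency=contingency,
        dispersion=dispersion, summary=summary, profiles=profiles,
        difference_tracks=tracks, cluster_calls=calls, cluster_freqs=cluster_freqs,
        cluster_enrichment=enrichment, cluster_scan=scan,
        expression_splits=splits, correlations=corrs, outdir=outdir,
    )
    (outdir / "report.md").write_text(render_report(result, degenerate=degenerate))
    return result


def render_report(res: PipelineResult, degenerate: bool = False) -> str:
    """Markdown summary; every number also lives in an emitted TSV."""
    lines = ["# Differential methylation profile report", ""]
    lines.append(f"Probes tested: {res.stats.drop_duplicates('probe_id').shape[0]}")
    lines.append(f"Significant probe x gene rows: {len(res.significant)}")
    lines.append("")
    if degenerate:
        lines.append("**All stages degenerate: the survivor set is empty.**")
        return "\n".join(lines) + "\n"
    if res.contingency is not None:
        lines.append("## Probe sign contingency")
        lines.append("")
        lines.append("| group | negative | positive | freq_neg |")
        lines.append("|---|---|---|---|")
        for g, row in res.contingency.table.iterrows():
            tot = row["n_negative"] + row["n_positive"]
            lines.append(f"| {g} | {row['n_negative']} | {row['n_positive']} | "
                         f"{row['n_negative'] / tot:.4f} |")
        lines.append("")
        lines.append(f"chi2 = {res.contingency.chi2_stat:.4f}, dof = {res.contingency.dof}, "
                     f"p = {res.contingency.p_value:.3g}")
        lines.append("")
    if res.dispersion is not None:
        lines.append("## Methyl-score dispersion (F tests)")
        lines.append("")
        lines.append("| group A | group B | F | p |")
        lines.append("|---|---|---|---|")
        for _, row in res.dispersion.iterrows():
            lines.append(f"| {row['group_a']} | {row['group_b']} | {row['f_ratio']:.4f} | "
                         f"{row['p_value']:.3g} |")
        lines.append("")
    if not res.cluster_freqs.empty:
        lines.append("## Promoter cluster phenomenon")
        lines.append("")
        lines.append("| group | neg | pos | negpos | total | cluster freq | frac all-neg |")
        lines.append("|---|---|---|---|---|---|---|")
        for _, row in res.cluster_freqs.iterrows():
            lines.append(
                f"| {row['group']} | {row['neg']} | {row['pos']} | {row['negpos']} | "
                f"{row['total']} | {100 * row['cluster_frequency']:.2f}% | "
                f"{100 * row['frac_neg']:.2f}% |")
        lines.append("")
        if res.cluster_enrichment is not None:
            lines.append(f"all-neg enrichment: chi2 = {res.cluster_enrichment.chi2_stat:.4f}, "
                         f"p = {res.cluster_enrichment.p_value:.3g}")
            lines.append("")
    if res.correlations:
        lines.append("## Peak windowed methylation-expression correlation")
        lines.append("")
        lines.append("| group | window (lo..hi) | rho | p | n genes |")
        lines.append("|---|---|---|---|---|")
        for g, corr in res.correlations.items():
            valid = corr.dropna(subset=["rho"])
            if valid.empty:
                lines.append(f"| {g} | (all windows masked) | . | . | . |")
                continue
            peak = valid.loc[valid["rho"].abs().idxmax()]
            lines.append(f"| {g} | {int(peak['lo'])}..{int(peak['hi'])} | {peak['rho']:.4f} | "
                         f"{peak['p_value']:.3g} | {int(peak['n_genes'])} |")
        lines.append("")
    if res.expression_splits:
        lines.append("## Expression-sign split")
        lines.append("")
        lines.append("| group | n up | n down | p (methyl score) | p (freq neg) |")
        lines.append("|---|---|---|---|---|")
        for g, s in res.expression_splits.items():
            lines.append(f"| {g} | {s.n_up} | {s.n_down} | {s.p_methyl_score:.3g} | "
                         f"{s.p_freq_neg:.3g} |")
        lines.append("")
    return "\n".join(lines) + "\n"
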