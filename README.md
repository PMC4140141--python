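# methylprofile

TSS-relative differential DNA-methylation profiling for two-condition
Infinium beta-value data.

`methylprofile` compares per-probe methylation between a disease and a
healthy group of samples (the motivating application is chronic
periodontitis versus healthy gingival tissue on the 450K array), and asks
*where along the gene* — promoter, TSS neighbourhood, or gene body — the
differences between functional gene classes concentrate, and whether they
track differential mRNA expression. Its intended users are epigenomics
analysts who already have a normalised beta-value matrix and per-probe
gene annotation and want the downstream comparative statistics, plus a
synthetic-data generator so the whole pipeline can be exercised and
validated without access to patient arrays.

## The statistics

For each probe *i* with beta values in a disease group *D* and a healthy
group *H*:

* **p-value** — two-sided Mann-Whitney U test of *D* vs *H* (exact when
  both groups have n ≤ 10 without ties, tie-corrected normal approximation
  otherwise);
* **q-value** — Storey FDR over all tested probes
  (q_i = min_{p_j ≥ p_i} π̂₀ · m · p_j / rank(p_j), with π̂₀ from the
  λ-grid smoother; Benjamini–Hochberg available as `method="bh"`);
* **methyl score** — mean(beta_D) − mean(beta_H) ∈ [−1, 1]; a probe is
  *negative* (hypomethylated in disease) if its score is < 0, *positive*
  if > 0.

Probes with q ≤ 0.05 located within ±2,000 bp of the transcription start
site feed four analyses:

1. **group comparison** — Pearson χ² on the gene-group × {negative,
   positive} table; two-sided F tests of methyl-score variance; Tukey
   summaries;
2. **window scan** — 140-bp sliding windows (1-base shift) from +2,000
   down to −2,000; per window, the difference in negative-probe frequency
   (freq-neg) or mean methyl score between two groups, with a per-window
   Mann-Whitney test on the probes inside;
3. **cluster analysis** — genes with ≥3 significant probes in the promoter
   (0 to −1,700) are classed `neg` / `pos` / `negpos` by sign homogeneity;
   the *cluster frequency* is (neg+pos)/total; an 800-bp/50-base scan maps
   where all-negative and all-positive clusters concentrate;
4. **expression link** — genes split by the sign of differential mRNA
   expression and compared on mean methyl score and freq-neg
   (Mann-Whitney), plus a 140-bp windowed Spearman correlation of
   delta-mRNA against freq-neg, mean score, or their product (the
   *interaction* parameter).

## Worked example

Simulate a compact study (300 immune-class, 100 cell-cycle, 80 stable
genes; 12 disease vs 11 healthy samples; a −0.3 hypomethylation effect
planted in immune genes between −1,500 and +900 bp) and run the stages:

```python
import methylprofile as mp

cfg = mp.SimConfig(genes_per_group={"immune": 300, "cellcycle": 100, "stable": 80},
                   seed=7)
study = mp.simulate(cfg)
stats = mp.compute_probe_stats(study.beta, study.annotation)
sig = mp.filter_significant(stats)                    # q <= 0.05, +/-2000 bp
counts = mp.sign_counts(sig)
res = mp.sign_contingency_test(counts)

win = mp.make_windows()                               # 3,861 windows of 140 bp
track = mp.difference_track(sig[sig.group == "immune"],
                            sig[sig.group == "cellcycle"], win)
runs = mp.significant_runs(track, direction="positive")
corr = mp.windowed_correlation(sig[sig.group == "immune"], study.expression, win)
```

Output for this seed:

```
probes tested: 2933
significant (q<=0.05, +/-2000): 521
           n_negative  n_positive
group
cellcycle          26          14
immune            419          30
stable             22          10
chi2 = 47.71, dof = 2, p = 4.36e-11
largest run of significantly higher immune freq-neg: -1143..-899 bp (105 windows)
peak interaction correlation: rho = -0.74 (p = 0.00029) in window -1417..-1277 with 19 genes
```

Reading it: 93% of the significant immune-class probes are hypomethylated
in disease against ~65% in the background classes (the χ² p-value rejects
homogeneity); the longest run of windows where the immune freq-neg
significantly exceeds the cell-cycle one sits inside the planted
−1,500…+900 region; and the windowed Spearman correlation between the
interaction parameter and delta-mRNA peaks negative — hypomethylated
genes are the up-regulated ones, as planted (`expr_slope < 0`).

The same pipeline runs from the shell:

```sh
methylprofile simulate --seed 7 --outdir sim_out --genes 300 100 80
methylprofile all --synthetic --seed 7 --outdir full_out
methylprofile probe-stats --beta sim_out/beta.tsv --samples sim_out/samples.tsv \
    --annotation sim_out/annotation.tsv --out-significant sig.tsv
```

`methylprofile all` writes every table as TSV plus `report.md` and the
resolved `config.yaml` into the output directory.

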