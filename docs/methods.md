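# Methods

## Coordinate model

All positions are signed TSS-relative offsets in base pairs: 0 at the
transcription start site, positive downstream (gene body), negative
upstream (promoter). Genomic inputs are converted once
(`tss_relative_offset`: `probe − tss` on the + strand, `tss − probe` on
the −), and everything downstream is strand-agnostic. The initial probe
selection spans −2,500 to the gene end; the analysis scope is the
inclusive interval [−2,000, +2,000], motivated by CpG-island
shore/shelf reach (≈2 kb each) around promoter CGIs. The promoter for
cluster analysis is the inclusive interval [−1,700, 0]; offset 0 counts
as promoter. One TSS per gene is assumed; a probe annotated to several
genes contributes one row per gene but its p/q statistics are computed
once.

## Per-probe testing

The disease/healthy contrast is tested on beta values directly with the
two-sided Mann-Whitney U test. Rank tests are invariant to monotone
transforms, so testing betas or M-values gives identical p-values; the
choice matters only for the methyl score, which is deliberately kept on
the beta scale (a score of −0.3 is a 30-percentage-point methylation
drop). The exact null distribution is used when both groups have n ≤ 10
and the data are tie-free; otherwise the tie-corrected normal
approximation with continuity correction. A probe whose values are
identical across all samples is degenerate and reported at p = 1.

FDR control defaults to Storey's q-value: π₀ is estimated on the λ-grid
0.05…0.95 (step 0.05) with a cubic polynomial smoother evaluated at
λ = 0.95 and clipped into (0, 1]; q-values are the π₀-scaled step-up
minima. Benjamini–Hochberg (`method="bh"`, π₀ ≡ 1) is offered for users
who prefer the more conservative, assumption-free variant; Storey's
q ≤ BH q always. Significance means q ≤ 0.05 (inclusive) inside
[−2,000, +2,000] (inclusive). Zero-score probes are classified "zero"
and excluded from every negative/positive frequency denominator, and by
default from promoter sign sets; they still count toward probe totals
and mean scores.

## Window statistics

Sliding windows are inclusive integer intervals [w − 140, w] labelled
by their 5′ offset w, stepping by −1 from +2,000 down to −1,860
(3,861 windows). Inclusive ends are a documented convention: a probe on
a boundary belongs to both adjacent windows; a half-open convention
would shift counts by exactly those boundary probes.

Between-group difference tracks report Δ = value_A − value_B per window
for freq-neg or mean methyl score. The per-window test is Mann-Whitney
on the per-probe values inside the window: the raw methyl scores for
mean-score mode, and −1/+1 sign indicators for freq-neg mode (a
two-proportion χ² is available behind `test="proportion"`). Windows
where either group has fewer than 3 probes of the tested kind are
masked — the 800-bp scan's ">3 probes" rule indicates sparsity masking
was part of the original design, and 3 is the smallest count for which
the rank test is non-trivial. No multiple-testing correction is applied
across windows: the track is an exploratory localisation profile and
its p-values are per-window, not family-wise. Indicator-mode p-values
depend only on the four sign counts and are memoised.

The positional cluster scan uses 800-bp windows shifted by 50 bp over
[−1,500, +750]; within a window, genes with ≥4 significant signed
probes ("more than three") are classed all-negative / all-positive /
mixed and the class fractions reported.

## Cluster classification

Genes with ≥3 significant signed probes ("more than two") in the
promoter are classed `neg` (all negative), `pos` (all positive) or
`negpos`. The probe-count threshold is applied after zero-sign
exclusion, so a category is always determined by actual signs; setting
`include_zero=True` makes zero-sign probes break homogeneity instead.
The cluster frequency is (|neg| + |pos|)/total, and the all-negative
enrichment test is Pearson χ² on the group × {neg, not-neg} table.
χ² tests never use continuity correction (the worked 2×2 examples are
uncorrected); expected cells below 1 attach a warning flag to the
result rather than aborting.

## Expression integration

Differential expression enters as a per-gene table (mean over array
probes; exact zeros excluded, as a zero has no direction). Per gene,
the methylation summary over a scope is: freq-neg over its signed
probes, mean score over all its significant probes, and their product —
the interaction parameter, which rewards genes that are both
consistently and strongly hypomethylated. The split analysis
Mann-Whitney-tests both parameters between up- and down-regulated
genes. The windowed correlation recomputes the summaries per 140-bp
window (genes qualify with ≥1 significant probe inside) and reports
Spearman's ρ against delta-mRNA; windows with fewer than `min_genes`
(default 10) genes are masked — rank correlations below that size are
dominated by noise, and real-data peak windows carry an order of
magnitude more genes. Spearman p-values use the t-approximation for
n ≥ 10 and full-enumeration permutation p for n < 10.

## Synthetic data

The generator emulates the study design: 12 disease vs 11 healthy
samples; 1,284 immune, 1,038 cell-cycle and 575 stable genes; per-gene
probe counts Poisson(6) (comparable to 450K promoter coverage) at
positions uniform over [−2,500, gene end]; gene lengths uniform on
[2,000, 20,000] bp. Beta values are Beta-distributed with per-probe
mean drawn uniform on [0.1, 0.9] and precision 50 (sd ≈ 0.06 at
mean 0.5) — bounded and skewed like array betas, without the
full bimodality or Infinium I/II chemistry structure of real arrays.

Two difference components are planted on the disease mean:

* the **effect**: a −0.3 shift on probes of the effect group (immune)
  inside [−1,500, +900] — the localised hypomethylation the pipeline
  must recover;
* a **background**: with probability 0.25 per probe (all groups), a
  N(0, 0.2) shift. Real two-condition tissue data yield thousands of
  significant probes in every gene class; without a background the
  non-effect classes are almost empty after FDR filtering and every
  between-group window test is masked. The background is sign-balanced
  so it biases no freq-neg comparison.

Shifted means are clipped into (0.01, 0.99) with a logged count.
Expression is delta_mrna = slope × (gene's realised mean shift inside
the effect window) + N(0, sd), with slope −5 and sd 0.5: affected genes
(shift ≈ −0.3) get delta ≈ +1.5, i.e. hypomethylation couples to
up-regulation, while unaffected genes are mostly noise. With sd = 0 the
relation is exactly linear and the slope is recoverable to machine
precision. All draws come from one seeded generator in a fixed order
(gene lengths → probe counts → positions → baseline means → background
→ beta values, disease block first → expression noise).

What the generator does *not* emulate — and hence what passing tests do
not establish about real arrays: probe-level spatial correlation along
a gene, bimodal beta distributions, cell-type composition differences
between inflamed and healthy tissue, batch structure, and Infinium
chemistry biases. One consequence worth noting: because the planted
effect concentrates the effect group's methyl scores near −0.3, the
synthetic effect group has *lower* score dispersion than the
background-only groups, whereas inflamed tissue shows the opposite; the
F test direction on synthetic data is therefore a generator property,
not a biological one.

`null_calibration` forces both the effect and the background to zero
and measures the p-value uniformity (KS distance) and the q ≤ 0.05
fraction; with the discrete rank test at n = 12/11 the null p-values
are sub-uniform, so the realised FDR sits below the nominal level.

## Problem sizes and defaults

Unit and property tests run on compact configurations (tens to a few
hundred genes, window steps of 10–25 where full resolution is not the
point); the end-to-end recovery suites and the acceptance script run
the full study-design generator (2,897 genes, ≈17,000 probes, 3,861
windows) over 10 seeds, which completes in well under a minute per
seed. The open design choices — pairwise (not pooled) F tests by
default, Mann-Whitney on sign indicators for the freq-neg window test,
per-gene (not per-probe) units in the expression split — are each
exposed as options with the default stated above.

## Known limitations

* Storey's π₀ smoother is a cubic polynomial on the λ-grid, not a
  smoothing spline; under a uniform null it estimates π₀ within
  [0.9, 1.1], which is the accuracy the pipeline needs.
* The window tracks are not corrected for multiplicity and should be
  read as localisation profiles, not as families of hypothesis tests.
* Genes with multiple TSSs, probe cross-reactivity and cell-composition
  correction are out of scope; inputs are assumed normalised.
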