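# robustsam

Robust gene selection for two-class expression data: the SAM moderated
statistic plus two outlier-resistant weighted variants, permutation-based
FDR estimation, a spike-in microarray simulator with controlled
contamination, and rank-based benchmarking metrics.

## The problem

Microarray (and other bulk expression) experiments routinely have
thousands of genes and only a handful of replicates per condition. A
single technically aberrant replicate inflates a gene's variance estimate,
collapses its *t*-like statistic, and buries a genuinely differential gene
deep in the ranked list — exactly where practitioners, who validate only a
few top-ranked genes, never look. This package implements statistics whose
variance term is robust to such outlying replicates, together with the
machinery to calibrate and evaluate them.

## The statistics

For gene *i* with control values *x*<sub>ij</sub> (*n*₁ replicates) and
treatment values *y*<sub>ij</sub> (*n*₂ replicates), the SAM statistic is

    d_i = (x̄_i − ȳ_i) / (s_i + s₀)

with pooled scatter
*s*<sub>i</sub> = √(a·(Σ(x−x̄)² + Σ(y−ȳ)²)), a = (1/n₁+1/n₂)/(n₁+n₂−2),
and fudge factor *s*₀ chosen to minimize the coefficient of variation of
*d* across the scatter range. The two modified statistics keep the
numerator but replace the scatter by a weighted sum of squared deviations
from each group's **median**,

    s̃_i = √( Σ_j w(x_ij)(x_ij − med_j x_ij)² + Σ_j w(y_ij)(y_ij − med_j y_ij)² )

with weights that shrink for replicates far from their group:

* **MSAM1** (Gaussian kernel): w(x) = (1/σ)·φ((x − median)/σ), where the
  bandwidth σ solves m = F⁻¹(1−p; 0, σ) for the dataset-wide maximal
  median-deviation *m* and a user tail probability *p* (default 0.001).
* **MSAM2** (inverse distance): w(x_ij) = 1 / Σ_k |x_ij − x_ik|.

Two comparators are included: a trim-based SAM (`sam_tbor`, drop the
largest and smallest replicate per group) and a standardized Wilcoxon
rank-sum statistic (`sam_wilcoxon`). Significance is assessed against a
permutation null: genes whose sorted statistic departs from the
permutation-expected order statistic by more than a half-width Δ are
called, and the FDR is estimated from the median (default) or mean
permutation exceedance count over the number of calls.

Sign convention: the numerator is mean(control) − mean(treatment), so a
gene induced by treatment carries a **negative** statistic.

## A worked example

`examples/03_simulate_and_rank.py` simulates a contaminated spike-in
dataset (2,000 genes, 5 control + 10 treatment replicates, 2% true DE
genes, the last two treatment replicates of DE genes contaminated) and
ranks the true genes with every statistic:

```
method            AUC  TRF(40)       RS
sam             0.910       23     3901
sam_wilcoxon    0.912       21     4211
sam_tbor        0.940       25     2763
msam1           0.952       27     2288
msam2           0.958       28     2056
```

AUC scores |d| as a classifier of the 40 true genes against the rest;
TRF(40) counts true genes ranked in the top 40 of their sign group
(higher is better); RS sums the true genes' within-sign ranks (lower is
better). The weighted variants recover more contaminated true genes than
plain SAM or its trim/rank comparators. The other examples cover the
evaluation metrics on a hand-built list (`01`), the equal-variance
outlier motivation (`02`), Δ/FDR calling (`04`) and a small benchmark
grid (`05`).

A thin CLI mirrors the library for shell use:

```sh
robustsam simulate --scenario beta_high --n1 5 --n2 10 --seed 1 --out run/
robustsam test run/expression.csv --method msam2 --fdr 0.2 --out run/
robustsam evaluate run/statistics.tsv run/truth.tsv
```

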