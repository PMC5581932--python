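# Methods

This note records the models, parameter choices and numerical conventions
behind `robustsam`, and what the simulation-based tests do and do not
establish.

## Test statistics

All five statistics operate on a genes × samples matrix with `control`
and `treatment` column labels and at least two replicates per group. The
numerator is always mean(control) − mean(treatment); a positive statistic
means higher expression in the control group. Statistics are intended for
log-scale expression values, but nothing enforces that.

**SAM.** d_i = (x̄_i − ȳ_i)/(s_i + s₀) with the pooled scatter
s_i = √(a(SS_x + SS_y)), a = (1/n₁ + 1/n₂)/(n₁ + n₂ − 2) — identical to
the pooled-SD two-sample *t* denominator (a property the tests exploit as
an oracle).

**Fudge factor.** s₀ is selected from the 0,5,…,100th percentiles of the
per-gene scatters. For each candidate the genes are split into up to 100
equal-count bins by scatter; within each bin the median absolute
deviation of the candidate statistic (scaled by 1.4826 for normal
consistency) is computed, and the candidate minimizing the coefficient of
variation (SD/mean) of the bin MADs wins. Ties break toward the smallest
candidate, so a constant-scatter input deterministically returns that
scatter value. An all-zero scatter vector is an error. s₀ is recalibrated
per method from that method's own (numerator, scatter) pairs: the
weighted scatters are built from *unnormalized* weights and live on a
different scale than the pooled scatter, so a shared s₀ would be
meaningless.

**Weighted variants.** Both replace s_i by
s̃_i = √(Σ w(x_ij)(x_ij − med_j x_ij)² + Σ w(y_ij)(y_ij − med_j y_ij)²),
deviations taken from the per-group median (midpoint convention for even
group sizes).

* MSAM1 weights are Gaussian densities centred at the group median,
  w = (1/σ)φ(dev/σ). The bandwidth is a single dataset-wide constant:
  m is the maximum |value − group median| over *all* genes and samples,
  and σ = m/z₁₋ₚ (one-sided standard-normal quantile), i.e. m sits at the
  100(1−p)th percentile of N(0, σ). The tail probability p (default
  0.001) is the only tuning knob: smaller p ⇒ smaller σ ⇒ harsher
  down-weighting of outliers; as p → 1 the weights flatten and the
  statistic approaches a median-centred SAM. A per-gene m would tie the
  bandwidth to each gene's own outliers and undo the robustness, which is
  why the global constant is the only calibration offered.
* MSAM2 weights are reciprocal summed distances,
  w(x_ij) = 1/Σ_k |x_ij − x_ik| (the self-distance contributes zero).
  They are parameter-free. A gene-group whose replicates are all
  identical has undefined weights; the direct weight function raises by
  default (an explicit equal-weight fallback exists), while the scatter
  computation short-circuits such groups to a zero contribution — correct
  for any finite weights, since every deviation from the median is zero.

Weights are deliberately **not** normalized to sum to one, following the
defining formulas; this affects the scale of s̃ (hence the per-method
s₀) but not the ranking behaviour that the weights exist to fix.

**Comparators.** `sam_tbor` removes exactly one largest and one smallest
observation per gene and group (ties: one copy each) and runs SAM on the
remainder; it requires ≥4 replicates per group and is reported as
not-applicable otherwise. `sam_wilcoxon` is the midrank rank-sum of the
treatment group centred at n₂(n₁+n₂+1)/2 and scaled by the no-tie null
SD, sign-matched to the mean difference. Its null SD ignores tie
corrections; only rank-based evaluation (RS/TRF/AUC), invariant to any
monotone rescaling, is claimed for it.

## Permutation FDR

Group labels are shuffled preserving group sizes; when the number of
distinct labelings C(n₁+n₂, n₁) is at most the requested B, the full set
is enumerated, otherwise B uniform draws (duplicates possible) are taken
from a seeded generator. Balanced-only permutation schemes are not used.
Under each relabeling the statistic is recomputed *in full* — medians,
bandwidth σ, distances and trimming all derive from the permuted data —
except for s₀, which is calibrated once on the original labeling and held
fixed so that the null ensemble shares the observed statistic's scale
(a per-permutation recalibration is available for study).

Each permuted statistic vector is sorted; the expected order statistic
d^E_(i) is the rank-wise mean. For a half-width Δ, sorted positions with
d_(i) − d^E_(i) > Δ are induced calls and < −Δ suppressed calls; d_up and
d_down are the extreme observed statistics inside those call sets. The
FDR estimate divides the per-permutation count of statistics ≥ d_up or
≤ d_down — summarized by its median (package default) or mean — by the
number of called genes. No null-proportion (π₀) multiplier is applied.
Estimates are capped at 1 for reporting, with the raw ratio retained.
Zero calls make the FDR undefined and raise; the Δ-table scan records
such rows as NaN instead. Target-FDR search returns the smallest grid Δ
whose median estimate meets the target, with an explicit unreachable
flag.

## Spike-in simulator

Each cell is d_ij = z_ij + s_ij + n_ij + t_ij:

| term | meaning | default |
|------|---------|---------|
| z̄_i = lb + ub·z_i | per-gene base level | beta(2,4) with (lb,ub)=(4,14); normal(10,1.5) with (0,1) |
| z_ij ~ unif((1∓α_i)z̄_i) | replicate noise, α_i = λ₁e^(−λ₁z̄_i) | λ₁ = 0.13 |
| s_ij ~ N(±μ_de, σ_de²) | DE spike-in, treatment columns of DE genes only | μ_de = 0.5 + Exp(rate 2) per gene; σ_de = 0.5 |
| n_ij ~ N(0, σ_n²) | measurement noise, every cell | σ_n = 0.4 |
| t_ij ~ N(0, σ_deo²) | contamination, DE genes × last n_deo treatment columns, high-noise scenarios only | σ_deo = 1, n_deo = ⌊0.2·n₂⌋ |

Defaults are the study conditions: 10,000 genes, 1% up- plus 1%
down-regulated (first block down, last block up), sample-size pairs drawn
from {(5,5),(5,10),(10,5),(10,10),(10,15),(15,10),(15,15)}. The
signal-dependent replicate noise encodes the low signal-to-noise ratio of
weakly expressed genes. Choices where the defining formulas leave room:

* The z̄ transform is implemented literally as lb + ub·z (beta range
  [4, 18]), not as a rescaling onto [lb, ub].
* Exp(λ₂) uses the rate parameterization (mean 1/λ₂ = 0.5), the R
  convention of the generator lineage this model follows; the mean DE
  shift is therefore μ_de_min + 1/λ₂ = 1.0, which a calibration test
  checks.
* One effect size μ_de is drawn per gene, with per-sample N(μ_de, σ_de²)
  shifts around it (a per-sample μ_de option exists).
* Each generation step consumes its own RNG substream spawned from the
  seed, so a contaminated dataset equals its clean counterpart plus the
  t-term, cell for cell — scenario pairs are exactly coupled.

What the simulator does **not** emulate: probe-level artifacts,
background or normalization effects, and between-gene correlation (genes
are independent). Benchmarks on these data therefore measure robustness
to the modelled contamination, not to every failure mode of real arrays;
the two real-data analyses that motivated the methods are outside the
test surface.

## Evaluation metrics

Ranks are computed within each statistic's sign group by descending
magnitude, ties sharing the worst rank: rank(i) = #{j : d_i d_j > 0 and
|d_j| ≥ |d_i|}. RS sums the true genes' ranks (lower better); TRF(r)
counts true genes with rank ≤ r (higher better; both sign groups
contribute). A statistic exactly 0 has rank 0 under the indicator
definition; such genes contribute 0 to RS, and are by default excluded
from the TRF numerator (the literal reading, which would count them as
top-ranked for every r, is available behind a flag). AUC is the
Mann–Whitney area under the ROC curve of the score |d| for true vs null
genes, midrank tie handling; a signed two-list AUC was considered and
rejected since RS/TRF are already magnitude-within-sign based and the two
definitions agree numerically on the benchmark data. TRUE FDR is
direction-aware: a call counts as correct only if the gene is truly DE
*and* the call's sign matches the gene's expected sign (treatment-induced
genes are expected on the negative side under the control-minus-treatment
numerator).

## Benchmark harness and problem sizes

`run_benchmark` averages RS/AUC/TRF over replicate datasets seeded
base_seed + rep (any cell reproducible in isolation) and reports
Monte-Carlo standard errors. `fdr_accuracy_experiment` computes, per
replicate and method, one B-permutation null (default B = 100), takes
every observed departure |d_(i) − d^E_(i)| as a candidate Δ so call
counts step one gene at a time, picks for each target the smallest Δ
whose median estimate meets it, and averages the realized TRUE FDR and
false/total call counts per target; the false-calls-at-matched-totals
comparison interpolates one method's curve at another's total-call
abscissae over the overlapping range.

The package's own test runs use 20-replicate benchmarks and 12-replicate
ordering checks at the full 10,000-gene size, and 50 replicates in the
acceptance script — sizes chosen to put Monte-Carlo standard errors well
below the effects being checked while keeping a default run fast on one
core. Statistical checks use three-standard-error bands.

## Known limitations

* The Wilcoxon comparator's exact historical formula varies between
  implementations; conclusions are restricted to rank-based metrics.
* FDR estimates at very small call counts are grainy (counts are
  integers); the Δ-table reports NaN rather than extrapolating.
* The simulator's independence across genes understates the variance of
  benchmark metrics relative to correlated real data.
* MSAM1's global bandwidth is dominated by the single most extreme
  median-deviation in the dataset; a heavy-tailed dataset with one
  extreme cell will flatten all weights (mitigate by lowering p).
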