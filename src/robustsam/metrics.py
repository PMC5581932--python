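"""Ranking-based evaluation of gene-selection statistics against truth.

All metrics rank genes WITHIN their statistic's sign (mirroring how the
SAM procedure treats induced and suppressed genes separately) by descending
magnitude:

    signed_rank(i) = #{ j : d_i * d_j > 0 and |d_j| >= |d_i| }

so the strongest gene on each side has rank 1, and tied magnitudes share
the larger (worst) rank.  A gene with statistic exactly 0 belongs to
neither sign group and has rank 0.

* RS (rank sum): sum of signed ranks over the truly DE genes; lower is
  better.
* TRF(r) (top-ranked frequency): number of truly DE genes with signed rank
  at most r; higher is better.  Both sign groups contribute, so TRF(r) can
  approach 2r.
* AUC: Mann-Whitney area under the ROC curve of the score |d| for
  discriminating truly DE from null genes (midrank tie handling).
* TRUE FDR: fraction of called genes that are false, where a call is true
  only when the gene is DE AND the call's sign matches the gene's expected
  sign (with the control-minus-treatment numerator, a treatment-induced
  gene is expected on the NEGATIVE side).
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

from .containers import SignificanceCall, TruthLabels

__all__ = [
    "signed_ranks",
    "rank_sum",
    "top_ranked_frequency",
    "ranking_auc",
    "true_fdr",
]


def signed_ranks(stats: np.ndarray) -> np.ndarray:
    """Per-gene rank among same-sign statistics by descending magnitude.

    Ties share the worst rank (the indicator definition uses |d_j| >= |d_i|);
    zero statistics receive rank 0.
    """
    d = np.asarray(stats, dtype=float)
    ranks = np.zeros(d.size, dtype=int)
    for mask in (d > 0, d < 0):
        if mask.any():
            # 'max' ties => rank equals the count of same-sign |d_j| >= |d_i|
            ranks[mask] = sps.rankdata(-np.abs(d[mask]), method="max")
    return ranks


def rank_sum(stats: np.ndarray, truth: TruthLabels) -> int:
    """RS: sum of the signed ranks of all truly DE genes (lower = better)."""
    return int(signed_ranks(stats)[truth.true_genes].sum())


def top_ranked_frequency(
    stats: np.ndarray,
    truth: TruthLabels,
    r: int,
    include_zero_statistics: bool = False,
) -> int:
    """TRF(r): number of truly DE genes with signed rank <= r.

    A zero statistic has rank 0, which the literal indicator formula would
    count as top-ranked for every r; by default such genes are excluded
    from the numerator (set ``include_zero_statistics=True`` for the
    strict-literal reading).
    """
    if r < 1:
        raise ValueError("rank cutoff r must be at least 1")
    ranks = signed_ranks(stats)[truth.true_genes]
    if not include_zero_statistics:
        ranks = ranks[ranks > 0]
    return int((ranks <= r).sum())


def ranking_auc(stats: np.ndarray, truth: TruthLabels) -> float:
    """ROC AUC of the score |d| for discriminating DE from null genes."""
    d = np.asarray(stats, dtype=float)
    labels = np.zeros(d.size, dtype=int)
    labels[truth.true_genes] = 1
    if labels.all() or not labels.any():
        raise ValueError("need at least one DE and one null gene")
    return float(roc_auc_score(labels, np.abs(d)))


def true_fdr(call: SignificanceCall, truth: TruthLabels) -> float:
    """Fraction of called genes that are false, direction-aware.

    With the control-minus-treatment numerator, genes truly induced in
    treatment (``truth.up_genes``) are expected among the NEGATIVE
    (suppressed-side) calls and truly suppressed genes among the POSITIVE
    calls; a call on the wrong side counts as false, as does any call on a
    null gene.
    """
    if call.n_called == 0:
        raise ValueError("TRUE FDR undefined with zero called genes")
    correct = np.intersect1d(call.up_genes, truth.down_genes).size
    correct += np.intersect1d(call.down_genes, truth.up_genes).size
    return (call.n_called - correct) / call.n_called
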