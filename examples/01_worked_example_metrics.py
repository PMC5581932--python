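"""Rank-based evaluation metrics on a small worked example.

Builds a 100-gene ranking in which 10 true genes occupy the
descending-magnitude ranks 1,2,4,5,6,9,10,11,13,15 (so positions 3,7,8,12
and 14 of the top-15 list are false positives) and evaluates it.
"""

import numpy as np

import robustsam as rs

stats = np.linspace(100.0, 1.0, 100)  # gene k has rank k+1 by |statistic|
true_ranks = np.array([1, 2, 4, 5, 6, 9, 10, 11, 13, 15])
truth = rs.TruthLabels(up_genes=true_ranks - 1, down_genes=np.array([], int))

print("RS      =", rs.rank_sum(stats, truth))
print("TRF(5)  =", rs.top_ranked_frequency(stats, truth, 5))
print("TRF(10) =", rs.top_ranked_frequency(stats, truth, 10))
print("AUC     =", round(rs.ranking_auc(stats, truth), 3))
print()
print("RS sums the within-sign ranks of the true genes (lower is better;")
print("perfect would be 1+..+10 = 55).  TRF(r) counts true genes ranked in")
print("the top r of their sign group; AUC scores |statistic| as a")
print("classifier of true vs null genes.")
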