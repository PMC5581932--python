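"""SAM-family test statistics for two-class differential expression.

Implements the classical SAM moderated statistic

    d_i = (xbar_i - ybar_i) / (s_i + s0)

with the pooled per-gene scatter ``s_i`` and the fudge factor ``s0``, plus
two robust modifications that replace ``s_i`` by a weighted scatter around
the per-group MEDIAN,

    s~_i = sqrt( sum_j w(x_ij) (x_ij - med_j x_ij)^2
               + sum_j w(y_ij) (y_ij - med_j y_ij)^2 ),

where the weights are either a Gaussian density centred at the group median
with a dataset-calibrated bandwidth (MSAM1) or the reciprocal summed
distance of each replicate to its group mates (MSAM2).  Replicates that sit
far from the rest of their group therefore contribute little to the scatter,
which keeps genes with a single outlying replicate from being buried by an
inflated variance.  Two comparator statistics round out the family: a
trim-based SAM (drop the single largest and smallest replicate per group,
then run SAM) and a standardized Wilcoxon rank-sum statistic.

Weights are deliberately NOT normalized to sum to one — the weighted scatter
lives on its own scale, which is why the fudge factor is recalibrated per
method from that method's own (numerator, scatter) pairs.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from .containers import (
    DegenerateDataError,
    GaussianWeightSpec,
    StatisticResult,
    TwoGroupExpression,
)

__all__ = [
    "group_means",
    "sam_scatter",
    "fudge_factor",
    "sam_statistics",
    "gaussian_sigma",
    "gaussian_weights",
    "inverse_distance_weights",
    "weighted_scatter",
    "msam_statistics",
    "trim_extremes",
    "wilcoxon_statistics",
    "compute_statistics",
]

#: consistency constant making the MAD unbiased for a normal SD
MAD_SCALE = 1.4826

#: candidate fudge-factor percentiles of the scatter distribution
S0_PERCENTILES = np.arange(0, 101, 5)

#: number of scatter-quantile bins used by the coefficient-of-variation search
N_S0_BINS = 100


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def group_means(expr: TwoGroupExpression) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene mean of the control columns and of the treatment columns."""
    return expr.control_values.mean(axis=1), expr.treatment_values.mean(axis=1)


def _sam_scatter_from(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    n1, n2 = X.shape[1], Y.shape[1]
    a = (1.0 / n1 + 1.0 / n2) / (n1 + n2 - 2)
    ss = ((X - X.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ss += ((Y - Y.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    return np.sqrt(a * ss)


def sam_scatter(expr: TwoGroupExpression) -> np.ndarray:
    """Pooled per-gene scatter s_i = sqrt(a * (SS_x + SS_y)).

    ``a = (1/n1 + 1/n2) / (n1 + n2 - 2)``, so ``s_i`` equals the classical
    pooled-SD two-sample t denominator.
    """
    return _sam_scatter_from(expr.control_values, expr.treatment_values)


def fudge_factor(numerators: np.ndarray, scatters: np.ndarray) -> float:
    """Choose s0 minimizing the coefficient of variation of the statistic.

    Candidates are the {0, 5, ..., 100}th percentiles of the scatters.  For
    each candidate the genes are split into up-to-100 equal-count bins by
    scatter; within each bin the (1.4826-scaled) median absolute deviation of
    ``numerator / (scatter + s0)`` is taken, and the candidate minimizing the
    coefficient of variation of the bin MADs wins.  Ties break toward the
    smallest candidate.
    """
    num = np.asarray(numerators, dtype=float)
    s = np.asarray(scatters, dtype=float)
    if num.shape != s.shape or num.ndim != 1:
        raise ValueError("numerators and scatters must be 1-D of equal length")
    if np.any(s < 0):
        raise ValueError("scatters must be nonnegative")
    if not np.any(s > 0):
        raise DegenerateDataError("every per-gene scatter is zero")

    candidates = np.percentile(s, S0_PERCENTILES)
    order = np.argsort(s, kind="stable")
    num_sorted = num[order]
    s_sorted = s[order]
    n_bins = min(N_S0_BINS, s.size)
    edges = np.linspace(0, s.size, n_bins + 1).astype(int)

    # (candidate x gene) statistics on the scatter-sorted grid
    d = num_sorted[None, :] / (s_sorted[None, :] + candidates[:, None])
    mads = np.empty((candidates.size, n_bins))
    for b in range(n_bins):
        block = d[:, edges[b]: edges[b + 1]]
        med = np.median(block, axis=1, keepdims=True)
        mads[:, b] = MAD_SCALE * np.median(np.abs(block - med), axis=1)

    mean_mad = mads.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(
            mean_mad > 0,
            mads.std(axis=1, ddof=1 if n_bins > 1 else 0) / mean_mad,
            0.0,
        )
    return float(candidates[int(np.argmin(cv))])


def sam_statistics(
    expr: TwoGroupExpression, s0: float | None = None
) -> StatisticResult:
    """The SAM statistic d_i = (xbar_i - ybar_i) / (s_i + s0).

    When ``s0`` is not supplied it is chosen by :func:`fudge_factor` on this
    dataset's numerators and scatters.
    """
    xbar, ybar = group_means(expr)
    num = xbar - ybar
    scat = sam_scatter(expr)
    if s0 is None:
        s0 = fudge_factor(num, scat)
    return StatisticResult(
        gene_ids=expr.gene_ids,
        numerator=num,
        scatter=scat,
        s0=float(s0),
        statistic=num / (scat + s0),
        method="sam",
    )


# ---------------------------------------------------------------------------
# weighting schemes
# ---------------------------------------------------------------------------

def _median_deviations(G: np.ndarray) -> np.ndarray:
    return G - np.median(G, axis=1, keepdims=True)


def gaussian_sigma(expr: TwoGroupExpression, p: float = 0.001) -> GaussianWeightSpec:
    """Calibrate the MSAM1 bandwidth from the whole dataset.

    ``m`` is the maximum absolute deviation from the per-gene, per-group
    median over ALL genes and samples (one data-dependent constant), and
    ``sigma = m / z_{1-p}`` where ``z_{1-p}`` is the one-sided standard
    normal quantile, so that ``m`` sits at the 100(1-p)th percentile of
    N(0, sigma).  Smaller ``p`` gives smaller ``sigma`` and hence harsher
    down-weighting of outlying replicates.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie strictly between 0 and 1")
    m = max(
        np.abs(_median_deviations(expr.control_values)).max(),
        np.abs(_median_deviations(expr.treatment_values)).max(),
    )
    if m == 0:
        raise DegenerateDataError(
            "dataset is fully constant within groups; sigma is undefined"
        )
    sigma = float(m / sps.norm.ppf(1.0 - p))
    return GaussianWeightSpec(p=p, m=float(m), sigma=sigma)


def gaussian_weights(values: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian-density weights (1/sigma) * phi((x - median)/sigma).

    The weight peaks at ``1/(sigma*sqrt(2*pi))`` for a replicate at the
    group median and decays smoothly with distance from it.  Weights are not
    normalized.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    v = np.asarray(values, dtype=float)
    return sps.norm.pdf(v - np.median(v), scale=sigma)


def inverse_distance_weights(
    values: np.ndarray, on_degenerate: str = "raise"
) -> np.ndarray:
    """Reciprocal summed-distance weights w_j = 1 / sum_k |x_j - x_k|.

    The farther a replicate sits from the rest of its group, the larger its
    summed distance and the smaller its weight.  If every replicate is
    identical, all summed distances are zero and the weight is undefined:
    by default this raises :class:`DegenerateDataError`; with
    ``on_degenerate="equal"`` every replicate receives the same (unit)
    weight instead — note the choice is irrelevant wherever the weights
    multiply all-zero squared deviations.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 replicates")
    dist = np.abs(v[:, None] - v[None, :]).sum(axis=1)
    if np.any(dist == 0):
        # sum_k |x_j - x_k| = 0 only if every value equals x_j
        if on_degenerate == "equal":
            return np.ones_like(v)
        raise DegenerateDataError(
            "all replicates identical; inverse-distance weights undefined"
        )
    return 1.0 / dist


def _weighted_group_ss(
    G: np.ndarray, scheme: str, sigma: float | None
) -> np.ndarray:
    """Vectorized weighted sum of squared median-deviations per gene.

    A fully constant gene-group contributes exactly 0 regardless of the
    weighting scheme (every deviation is zero), so it is short-circuited
    instead of tripping the degenerate-weight error.
    """
    dev = _median_deviations(G)
    if scheme == "gaussian":
        w = sps.norm.pdf(dev, scale=sigma)
        return (w * dev**2).sum(axis=1)
    if scheme == "inverse_distance":
        dist = np.abs(G[:, :, None] - G[:, None, :]).sum(axis=2)
        ss = np.zeros(G.shape[0])
        ok = dist.min(axis=1) > 0
        ss[ok] = (dev[ok] ** 2 / dist[ok]).sum(axis=1)
        degenerate = ~ok & (np.abs(dev).max(axis=1) > 0)
        if np.any(degenerate):
            # some but not all replicates identical cannot zero a distance
            # row, so this only fires for constant groups with dev==0;
            # anything else is a logic error worth failing loudly on.
            raise DegenerateDataError("inconsistent degenerate gene-group")
        return ss
    raise ValueError(f"unknown weighting scheme {scheme!r}")


def weighted_scatter(
    expr: TwoGroupExpression,
    weight_scheme: str | GaussianWeightSpec,
) -> np.ndarray:
    """Robust per-gene scatter s~_i with median-centred weighted deviations.

    ``weight_scheme`` is either a calibrated :class:`GaussianWeightSpec`
    (MSAM1) or the string ``"inverse_distance"`` (MSAM2).
    """
    if isinstance(weight_scheme, GaussianWeightSpec):
        scheme, sigma = "gaussian", weight_scheme.sigma
    elif weight_scheme == "inverse_distance":
        scheme, sigma = "inverse_distance", None
    else:
        raise ValueError(f"unknown weighting scheme {weight_scheme!r}")
    ss = _weighted_group_ss(expr.control_values, scheme, sigma)
    ss = ss + _weighted_group_ss(expr.treatment_values, scheme, sigma)
    return np.sqrt(ss)


def msam_statistics(
    expr: TwoGroupExpression,
    method: str = "msam1",
    p: float = 0.001,
    s0: float | None = None,
) -> StatisticResult:
    """Weighted modified SAM statistic d~_i = (xbar_i - ybar_i)/(s~_i + s0).

    The numerator is identical to SAM's; only the scatter changes.  When
    ``s0`` is not supplied it is recalibrated on this method's own
    (numerator, weighted-scatter) pairs, because the unnormalized weights
    put s~ on a different scale than s.
    """
    if method not in ("msam1", "msam2"):
        raise ValueError("method must be 'msam1' or 'msam2'")
    xbar, ybar = group_means(expr)
    num = xbar - ybar
    if method == "msam1":
        scat = weighted_scatter(expr, gaussian_sigma(expr, p))
    else:
        scat = weighted_scatter(expr, "inverse_distance")
    if s0 is None:
        s0 = fudge_factor(num, scat)
    return StatisticResult(
        gene_ids=expr.gene_ids,
        numerator=num,
        scatter=scat,
        s0=float(s0),
        statistic=num / (scat + s0),
        method=method,
    )


# ---------------------------------------------------------------------------
# comparator statistics
# ---------------------------------------------------------------------------

def _trim_group(G: np.ndarray) -> np.ndarray:
    """Drop exactly one smallest and one largest observation per gene."""
    return np.sort(G, axis=1)[:, 1:-1]


def trim_extremes(expr: TwoGroupExpression) -> TwoGroupExpression:
    """Remove the single largest and smallest replicate per gene and group.

    Used by the trim-based comparator (``sam_tbor``): SAM is then run on the
    trimmed matrix.  Requires at least 4 replicates per group so that 2
    survive.  With tied extremes exactly one copy of each is removed.
    Within-group column order is not preserved (replicates are
    exchangeable).
    """
    if expr.n1 < 4 or expr.n2 < 4:
        raise ValueError(
            "trimming requires at least 4 replicates per group "
            f"(got n1={expr.n1}, n2={expr.n2})"
        )
    X = _trim_group(expr.control_values)
    Y = _trim_group(expr.treatment_values)
    group = np.array(["control"] * X.shape[1] + ["treatment"] * Y.shape[1])
    return TwoGroupExpression(
        values=np.hstack([X, Y]), gene_ids=expr.gene_ids, group=group
    )


def _wilcoxon_values(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    n1, n2 = X.shape[1], Y.shape[1]
    N = n1 + n2
    ranks = sps.rankdata(np.hstack([X, Y]), axis=1)
    W = ranks[:, n1:].sum(axis=1)
    mu = n2 * (N + 1) / 2.0
    sd = np.sqrt(n1 * n2 * (N + 1) / 12.0)
    # minus sign matches the mean-difference direction (control - treatment)
    return -(W - mu) / sd


def wilcoxon_statistics(expr: TwoGroupExpression) -> StatisticResult:
    """Standardized two-sample Wilcoxon rank-sum comparator (midranks).

    The treatment rank-sum is centred at its null mean ``n2 (n1+n2+1)/2``
    and scaled by the no-tie null SD; the sign matches the mean-difference
    direction.  Only rank-based evaluation (RS/TRF/AUC), which is invariant
    to monotone rescaling, is claimed for this comparator.
    """
    xbar, ybar = group_means(expr)
    return StatisticResult(
        gene_ids=expr.gene_ids,
        numerator=xbar - ybar,
        scatter=np.full(expr.n_genes, np.nan),
        s0=float("nan"),
        statistic=_wilcoxon_values(expr.control_values, expr.treatment_values),
        method="sam_wilcoxon",
    )


# ---------------------------------------------------------------------------
# dispatcher + fast path for permutation loops
# ---------------------------------------------------------------------------

def compute_statistics(
    expr: TwoGroupExpression,
    method: str = "sam",
    p: float = 0.001,
    s0: float | None = None,
) -> StatisticResult:
    """Compute any of the five statistics by method tag."""
    if method == "sam":
        return sam_statistics(expr, s0=s0)
    if method in ("msam1", "msam2"):
        return msam_statistics(expr, method=method, p=p, s0=s0)
    if method == "sam_tbor":
        res = sam_statistics(trim_extremes(expr), s0=s0)
        return StatisticResult(
            gene_ids=res.gene_ids,
            numerator=res.numerator,
            scatter=res.scatter,
            s0=res.s0,
            statistic=res.statistic,
            method="sam_tbor",
        )
    if method == "sam_wilcoxon":
        return wilcoxon_statistics(expr)
    raise ValueError(f"unknown method tag {method!r}")


def _statistic_vector(
    values: np.ndarray,
    control_mask: np.ndarray,
    method: str,
    p: float = 0.001,
    s0: float | None = None,
) -> np.ndarray:
    """Statistic values for an arbitrary (possibly permuted) labeling.

    Bypasses container validation for speed inside permutation loops; all
    data-dependent ingredients (medians, sigma, distances, trim) are
    recomputed under the given labeling, while ``s0`` may be held fixed by
    the caller.
    """
    X = values[:, control_mask]
    Y = values[:, ~control_mask]
    if method == "sam_wilcoxon":
        return _wilcoxon_values(X, Y)
    if method == "sam_tbor":
        X, Y = _trim_group(X), _trim_group(Y)
        method = "sam"
    num = X.mean(axis=1) - Y.mean(axis=1)
    if method == "sam":
        scat = _sam_scatter_from(X, Y)
    elif method == "msam1":
        m = max(
            np.abs(_median_deviations(X)).max(),
            np.abs(_median_deviations(Y)).max(),
        )
        if m == 0:
            raise DegenerateDataError("fully constant dataset under relabeling")
        sigma = m / sps.norm.ppf(1.0 - p)
        scat = np.sqrt(
            _weighted_group_ss(X, "gaussian", sigma)
            + _weighted_group_ss(Y, "gaussian", sigma)
        )
    elif method == "msam2":
        scat = np.sqrt(
            _weighted_group_ss(X, "inverse_distance", None)
            + _weighted_group_ss(Y, "inverse_distance", None)
        )
    else:
        raise ValueError(f"unknown method tag {method!r}")
    if s0 is None:
        s0 = fudge_factor(num, scat)
    return num / (scat + s0)
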