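"""Unit and property tests for the SAM-family statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import robustsam as rs
from robustsam.containers import DegenerateDataError

from conftest import make_expr


# ---------------------------------------------------------------------------
# group means and pooled scatter
# ---------------------------------------------------------------------------

def test_group_means_matches_per_gene_loop(random_expr):
    xbar, ybar = rs.group_means(random_expr)
    X, Y = random_expr.control_values, random_expr.treatment_values
    for i in range(random_expr.n_genes):
        assert xbar[i] == pytest.approx(np.mean(X[i]))
        assert ybar[i] == pytest.approx(np.mean(Y[i]))


def test_group_means_hand_example():
    expr = make_expr([[1, 2, 3]], [[4, 5, 6]])
    xbar, ybar = rs.group_means(expr)
    assert (xbar[0], ybar[0]) == (2.0, 5.0)


def test_sam_scatter_hand_example():
    # a = (1/3 + 1/3)/4 = 1/6, SS = 2 + 2 = 4 -> s = sqrt(4/6)
    expr = make_expr([[1, 2, 3]], [[4, 5, 6]])
    assert rs.sam_scatter(expr)[0] == pytest.approx(np.sqrt(4 / 6))


def test_sam_scatter_zero_for_constant_gene():
    expr = make_expr([[7, 7, 7]], [[7, 7, 7]])
    assert rs.sam_scatter(expr)[0] == 0.0


def test_sam_scatter_equals_pooled_t_denominator(random_expr):
    """s_i is the pooled-SD two-sample t denominator: |t| = |num| / s."""
    s = rs.sam_scatter(random_expr)
    X, Y = random_expr.control_values, random_expr.treatment_values
    t, _ = sps.ttest_ind(X, Y, axis=1, equal_var=True)
    num = X.mean(axis=1) - Y.mean(axis=1)
    np.testing.assert_allclose(num / s, t, rtol=1e-10)


def test_location_shift_moves_numerator_not_scatter(random_expr):
    shifted = make_expr(
        random_expr.control_values + 3.7, random_expr.treatment_values + 3.7
    )
    np.testing.assert_allclose(
        rs.sam_scatter(shifted), rs.sam_scatter(random_expr)
    )
    np.testing.assert_allclose(
        rs.weighted_scatter(shifted, "inverse_distance"),
        rs.weighted_scatter(random_expr, "inverse_distance"),
    )
    num0 = np.subtract(*rs.group_means(random_expr))
    num1 = np.subtract(*rs.group_means(shifted))
    np.testing.assert_allclose(num1, num0, atol=1e-12)


# ---------------------------------------------------------------------------
# fudge factor
# ---------------------------------------------------------------------------

def _fudge_oracle(num, s):
    """Independent brute-force re-implementation of the CV criterion."""
    cands = np.percentile(s, np.arange(0, 101, 5))
    order = np.argsort(s, kind="stable")
    nb = min(100, s.size)
    edges = np.linspace(0, s.size, nb + 1).astype(int)
    best, best_cv = None, np.inf
    for c in cands:
        d = num[order] / (s[order] + c)
        mads = []
        for b in range(nb):
            blk = d[edges[b]: edges[b + 1]]
            mads.append(1.4826 * np.median(np.abs(blk - np.median(blk))))
        mads = np.asarray(mads)
        cv = mads.std(ddof=1) / mads.mean() if mads.mean() > 0 else 0.0
        if cv < best_cv - 1e-15:
            best, best_cv = c, cv
    return best


def test_fudge_factor_matches_bruteforce_oracle(rng):
    num = rng.normal(size=200)
    s = rng.gamma(2.0, 0.3, size=200)
    assert rs.fudge_factor(num, s) == pytest.approx(_fudge_oracle(num, s))


def test_fudge_factor_is_a_scatter_percentile(rng):
    num = rng.normal(size=150)
    s = rng.gamma(2.0, 0.3, size=150)
    cands = np.percentile(s, np.arange(0, 101, 5))
    assert np.min(np.abs(cands - rs.fudge_factor(num, s))) < 1e-12


def test_fudge_factor_constant_scatter_breaks_tie_low(rng):
    s = np.full(50, 0.8)
    assert rs.fudge_factor(rng.normal(size=50), s) == pytest.approx(0.8)


def test_fudge_factor_rejects_all_zero_scatter():
    with pytest.raises(DegenerateDataError):
        rs.fudge_factor(np.ones(10), np.zeros(10))


# ---------------------------------------------------------------------------
# SAM statistic
# ---------------------------------------------------------------------------

def test_sam_statistic_hand_example():
    expr = make_expr([[1, 2, 3]], [[4, 5, 6]])
    res = rs.sam_statistics(expr, s0=0.5)
    assert res.statistic[0] == pytest.approx((2 - 5) / (np.sqrt(4 / 6) + 0.5))


def test_sam_statistic_zero_for_permuted_null_gene():
    expr = make_expr([[1, 5, 3, 2]], [[2, 3, 1, 5]])
    res = rs.sam_statistics(expr, s0=0.3)
    assert res.statistic[0] == 0.0


def test_statistic_identity_holds(random_expr):
    for method in ("sam", "msam1", "msam2"):
        res = rs.compute_statistics(random_expr, method=method)
        np.testing.assert_allclose(
            res.statistic, res.numerator / (res.scatter + res.s0)
        )
        assert res.s0 >= 0
        assert (res.scatter >= 0).all()


# ---------------------------------------------------------------------------
# Gaussian weighting (MSAM1)
# ---------------------------------------------------------------------------

def test_gaussian_sigma_calibration_examples():
    """m=2 with p=0.05 -> sigma 1.22; p=0.1 -> 1.56 (one-sided quantile)."""
    # a one-gene dataset whose maximal median-deviation is exactly 2
    expr = make_expr([[0, 0, 2]], [[0, 0, 1]])
    spec = rs.gaussian_sigma(expr, p=0.05)
    assert spec.m == 2.0
    assert spec.sigma == pytest.approx(1.22, abs=0.005)
    assert rs.gaussian_sigma(expr, p=0.1).sigma == pytest.approx(1.56, abs=0.005)


def test_gaussian_sigma_quantile_identity():
    expr = make_expr([[0, 0, 2]], [[0, 0, 1]])
    p = 1 - sps.norm.cdf(1.0)  # z_{1-p} = 1 => sigma = m
    assert rs.gaussian_sigma(expr, p=p).sigma == pytest.approx(2.0)


def test_gaussian_sigma_increasing_in_p():
    expr = make_expr([[0, 1, 3]], [[2, 2, 5]])
    sigmas = [rs.gaussian_sigma(expr, p).sigma for p in (0.001, 0.01, 0.1, 0.3)]
    assert np.all(np.diff(sigmas) > 0)


def test_gaussian_sigma_rejects_constant_dataset():
    with pytest.raises(DegenerateDataError):
        rs.gaussian_sigma(make_expr([[1, 1, 1]], [[2, 2, 2]]), p=0.05)


def test_gaussian_weights_peak_and_density_value():
    w = rs.gaussian_weights(np.array([5.0, 5.0, 5.0, 6.0]), sigma=1.0)
    assert w[0] == pytest.approx(1 / np.sqrt(2 * np.pi))
    # |value - median| = 1 at sigma 1 -> standard normal density at 1
    assert w[3] == pytest.approx(0.2420, abs=1e-4)


def test_gaussian_weights_decrease_with_distance_from_median():
    """The outlying replicate gets the smallest weight (AML gene pattern)."""
    values = np.array([0.55, 4.11, 7.79, 7.96, 19.60]) * 1e3
    w = rs.gaussian_weights(values, sigma=4.0e3)
    assert np.argmin(w) == 4
    dev = np.abs(values - np.median(values))
    assert np.all(np.diff(w[np.argsort(dev)]) <= 0)


# ---------------------------------------------------------------------------
# inverse-distance weighting (MSAM2)
# ---------------------------------------------------------------------------

def test_inverse_distance_weights_hand_example():
    np.testing.assert_allclose(
        rs.inverse_distance_weights(np.array([0.0, 0.0, 3.0])),
        [1 / 3, 1 / 3, 1 / 6],
    )


def test_inverse_distance_weights_pair_symmetry():
    np.testing.assert_allclose(
        rs.inverse_distance_weights(np.array([2.0, 7.0])), [0.2, 0.2]
    )


@given(st.floats(min_value=3.0, max_value=50.0))
@settings(deadline=None, max_examples=25)
def test_inverse_distance_weight_decreases_as_point_moves_away(far):
    cluster = np.array([0.0, 0.5, 1.0])
    w_near = rs.inverse_distance_weights(np.append(cluster, far))[-1]
    w_farther = rs.inverse_distance_weights(np.append(cluster, far + 1.0))[-1]
    assert w_farther < w_near


def test_inverse_distance_weights_degenerate_raises_and_fallback():
    values = np.full(4, 2.5)
    with pytest.raises(DegenerateDataError):
        rs.inverse_distance_weights(values)
    np.testing.assert_allclose(
        rs.inverse_distance_weights(values, on_degenerate="equal"), np.ones(4)
    )


# ---------------------------------------------------------------------------
# weighted scatter and modified statistics
# ---------------------------------------------------------------------------

def _weighted_scatter_oracle(expr, scheme, sigma=None):
    """Double-loop recomputation of the weighted scatter."""
    out = []
    for i in range(expr.n_genes):
        total = 0.0
        for G in (expr.control_values[i], expr.treatment_values[i]):
            med = np.median(G)
            if np.all(G == G[0]):
                continue
            for j, v in enumerate(G):
                if scheme == "gaussian":
                    w = sps.norm.pdf(v - med, scale=sigma)
                else:
                    w = 1.0 / sum(abs(v - u) for u in G)
                total += w * (v - med) ** 2
        out.append(np.sqrt(total))
    return np.array(out)


@pytest.mark.parametrize("scheme", ["gaussian", "inverse_distance"])
def test_weighted_scatter_matches_double_loop_oracle(random_expr, scheme):
    if scheme == "gaussian":
        spec = rs.gaussian_sigma(random_expr, p=0.001)
        got = rs.weighted_scatter(random_expr, spec)
        want = _weighted_scatter_oracle(random_expr, "gaussian", spec.sigma)
    else:
        got = rs.weighted_scatter(random_expr, "inverse_distance")
        want = _weighted_scatter_oracle(random_expr, "inverse_distance")
    np.testing.assert_allclose(got, want, rtol=1e-10)


def test_weighted_scatter_zero_for_constant_gene():
    expr = make_expr([[3, 3, 3], [3, 3, 3]], [[4, 4, 4], [4, 5, 6]])
    spec = rs.gaussian_sigma(expr, p=0.001)
    assert rs.weighted_scatter(expr, spec)[0] == 0.0
    assert rs.weighted_scatter(expr, "inverse_distance")[0] == 0.0


def test_numerator_identical_across_methods(random_expr):
    nums = [
        rs.compute_statistics(random_expr, method=m).numerator
        for m in ("sam", "msam1", "msam2")
    ]
    np.testing.assert_array_equal(nums[0], nums[1])
    np.testing.assert_array_equal(nums[0], nums[2])


def test_motivating_example_outlier_case_more_significant():
    """(5,5,5,5,8.54) and (3,4,5,6,7) share the variance, but the tight
    cluster with one outlier should score stronger under both weighted
    statistics at a common s0."""
    control = np.zeros((2, 5))
    case1, case2 = [5, 5, 5, 5, 8.54], [3, 4, 5, 6, 7]
    expr = make_expr(control, np.array([case1, case2]))
    assert np.var(case1) == pytest.approx(np.var(case2), rel=1e-2)
    for method in ("msam1", "msam2"):
        d = rs.msam_statistics(expr, method=method, s0=0.5).statistic
        assert abs(d[0]) > abs(d[1])
    # plain SAM cannot separate the two cases (equal mean would be needed;
    # here its preference is driven by the means alone)
    s = rs.sam_statistics(expr, s0=0.5)
    np.testing.assert_allclose(s.scatter[0], s.scatter[1], rtol=1e-2)


def test_msam2_three_sample_hand_computation():
    # gene: control (0,0,0) constant; treatment (0,0,3)
    expr = make_expr([[0, 0, 0]], [[0.0, 0.0, 3.0]])
    # weights (1/3, 1/3, 1/6); median 0 -> ss = (1/6)*9 = 1.5
    want = np.sqrt(1.5)
    got = rs.weighted_scatter(expr, "inverse_distance")[0]
    assert got == pytest.approx(want)
    res = rs.msam_statistics(expr, method="msam2", s0=0.25)
    assert res.statistic[0] == pytest.approx(-1.0 / (want + 0.25))


def test_outlier_downweighting_versus_sam():
    """As a single treatment replicate runs away, SAM's statistic collapses
    while the weighted statistics stay bounded away from zero."""
    control = np.zeros((1, 5))
    s0 = 0.3
    sam_mags, msam2_mags = [], []
    for K in (2.0, 10.0, 50.0):
        expr = make_expr(control, [[1, 1, 1, 1, 1 + K]])
        sam_mags.append(abs(rs.sam_statistics(expr, s0=s0).statistic[0]))
        msam2_mags.append(
            abs(rs.msam_statistics(expr, method="msam2", s0=s0).statistic[0])
        )
    assert sam_mags[0] > sam_mags[1] > sam_mags[2]
    assert msam2_mags[-1] > sam_mags[-1]


# ---------------------------------------------------------------------------
# comparators
# ---------------------------------------------------------------------------

def test_trim_extremes_examples():
    expr = make_expr([[1, 2, 3, 4, 5]], [[1, 1, 5, 5]])
    trimmed = rs.trim_extremes(expr)
    np.testing.assert_array_equal(np.sort(trimmed.control_values[0]), [2, 3, 4])
    np.testing.assert_array_equal(np.sort(trimmed.treatment_values[0]), [1, 5])


def test_trim_extremes_requires_four_replicates():
    with pytest.raises(ValueError, match="at least 4"):
        rs.trim_extremes(make_expr([[1, 2, 3]], [[1, 2, 3, 4]]))


def test_sam_tbor_equals_sam_on_manually_trimmed_matrix(rng):
    expr = make_expr(
        rng.normal(size=(30, 5)), rng.normal(size=(30, 6))
    )
    via_tag = rs.compute_statistics(expr, method="sam_tbor", s0=0.2)
    manual = rs.sam_statistics(rs.trim_extremes(expr), s0=0.2)
    np.testing.assert_allclose(via_tag.statistic, manual.statistic)


def test_wilcoxon_complete_separation_is_minimal():
    expr = make_expr(
        [[1, 2, 3], [5, 6, 7]], [[4, 5, 6], [1, 2, 3]]
    )
    d = rs.wilcoxon_statistics(expr).statistic
    # gene 0: all control < all treatment -> most negative achievable value
    assert d[0] == min(d)
    assert d[1] == -d[0]


def test_wilcoxon_identical_tied_groups_is_zero():
    expr = make_expr([[2, 2, 2]], [[2, 2, 2]])
    assert rs.wilcoxon_statistics(expr).statistic[0] == 0.0


def test_wilcoxon_matches_rank_sum_oracle(rng):
    expr = make_expr(rng.normal(size=(20, 4)), rng.normal(size=(20, 5)))
    d = rs.wilcoxon_statistics(expr).statistic
    n1, n2 = 4, 5
    N = n1 + n2
    for i in range(20):
        ranks = sps.rankdata(expr.values[i])
        W = ranks[n1:].sum()
        want = -(W - n2 * (N + 1) / 2) / np.sqrt(n1 * n2 * (N + 1) / 12)
        assert d[i] == pytest.approx(want)
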