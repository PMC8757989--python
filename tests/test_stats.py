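"""Validation statistics against printed values and definitional oracles."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from welsh.stats import (
    StatError,
    bh_adjust,
    chi_square_independence,
    fisher_z_compare,
    fit_line,
    sample_size_for_correlation,
    spearman_rho,
    two_sample_t,
    wilson_ci,
)


# ---------------------------------------------------------------------------
# definitional oracles, coded independently of the implementations they check


def bh_oracle(p):
    """O(m^2) Benjamini-Hochberg from the definition: q_i is the smallest
    p_j * m / rank_j over all j with p_j >= p_i."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    rank = {i: k + 1 for k, i in enumerate(order)}
    out = []
    for i in range(m):
        q = min(min(p[j] * m / rank[j] for j in range(m) if p[j] >= p[i]), 1.0)
        out.append(q)
    return out


def mid_ranks(v):
    """Average ranks with ties sharing their mean rank."""
    order = sorted(range(len(v)), key=lambda i: v[i])
    ranks = [0.0] * len(v)
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and v[order[j]] == v[order[i]]:
            j += 1
        mean_rank = (i + j + 1) / 2  # ranks are 1-based
        for k in range(i, j):
            ranks[order[k]] = mean_rank
        i = j
    return ranks


def pearson(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


class TestWilson:
    @pytest.mark.parametrize(
        "k, n, lo, hi",
        [(113, 524, 0.183, 0.253), (1523, 1723, 0.868, 0.898), (32, 233, 0.099, 0.187)],
    )
    def test_reproduces_published_intervals(self, k, n, lo, hi):
        ci = wilson_ci(k, n)
        assert round(ci.low, 3) == lo
        assert round(ci.high, 3) == hi

    def test_boundary_counts(self):
        assert wilson_ci(0, 10).low == 0.0
        assert wilson_ci(10, 10).high == 1.0

    def test_always_contains_sample_proportion(self):
        for n in range(1, 61):
            for k in range(n + 1):
                ci = wilson_ci(k, n)
                assert ci.low <= k / n <= ci.high

    def test_undefined_for_empty_sample(self):
        with pytest.raises(StatError):
            wilson_ci(0, 0)


class TestSpearman:
    def test_monotone_extremes(self):
        assert spearman_rho([1, 2, 3, 4], [10, 20, 30, 40]).rho == pytest.approx(1.0)
        assert spearman_rho([1, 2, 3, 4], [40, 30, 20, 10]).rho == pytest.approx(-1.0)

    def test_tied_sample_matches_rank_pearson_oracle(self):
        x, y = [1, 2, 2, 4], [3, 1, 4, 5]
        expected = pearson(mid_ranks(x), mid_ranks(y))
        assert spearman_rho(x, y).rho == pytest.approx(expected, abs=1e-12)

    def test_random_samples_match_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            n = int(rng.integers(4, 30))
            x = rng.integers(0, 6, n).tolist()  # heavy ties
            y = rng.normal(size=n).tolist()
            if len(set(x)) < 2:
                continue
            expected = pearson(mid_ranks(x), mid_ranks(y))
            assert spearman_rho(x, y).rho == pytest.approx(expected, abs=1e-12)

    def test_p_value_uses_t_approximation(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=40)
        y = 0.5 * x + rng.normal(size=40)
        res = spearman_rho(x, y)
        t = res.rho * math.sqrt((res.n - 2) / (1 - res.rho**2))
        assert res.p_raw == pytest.approx(2 * sps.t.sf(abs(t), res.n - 2), rel=1e-9)

    def test_constant_sample_rejected(self):
        with pytest.raises(StatError):
            spearman_rho([1, 1, 1, 1], [1, 2, 3, 4])


class TestFisherZ:
    @pytest.mark.parametrize(
        "r1, n1, r2, n2, printed",
        [
            (0.291, 386, 0.552, 147, 0.001),
            (0.291, 386, 0.520, 125, 0.008),
            (0.291, 386, 0.469, 242, 0.011),
        ],
    )
    def test_published_contrast_p_values(self, r1, n1, r2, n2, printed):
        assert round(fisher_z_compare(r1, n1, r2, n2).p, 3) == printed

    def test_strongest_contrast_below_milli(self):
        assert fisher_z_compare(0.291, 386, 0.576, 216).p < 0.001

    def test_identical_correlations(self):
        cmp = fisher_z_compare(0.5, 50, 0.5, 80)
        assert cmp.z_stat == 0.0
        assert cmp.p == 1.0

    def test_antisymmetric_under_swap(self):
        a = fisher_z_compare(0.3, 40, 0.6, 60)
        b = fisher_z_compare(0.6, 60, 0.3, 40)
        assert a.z_stat == pytest.approx(-b.z_stat)
        assert a.p == pytest.approx(b.p)

    @pytest.mark.parametrize("bad", [(1.0, 50, 0.5, 50), (0.5, 3, 0.5, 50)])
    def test_invalid_inputs(self, bad):
        with pytest.raises(StatError):
            fisher_z_compare(*bad)


class TestBenjaminiHochberg:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03]) == [0.03]

    def test_step_up_example(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_matches_definitional_oracle_on_random_vectors(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            m = int(rng.integers(1, 25))
            p = rng.random(m).tolist()
            assert bh_adjust(p) == pytest.approx(bh_oracle(p), abs=1e-12)

    def test_order_preserving_and_dominating(self):
        rng = np.random.default_rng(13)
        p = rng.random(10).tolist()
        q = bh_adjust(p)
        # adjusted values never fall below the raw ones and are capped at 1
        assert all(0 <= pi <= qi <= 1 for pi, qi in zip(p, q))
        # order-preserving: a smaller raw p never gets a larger adjusted p
        assert all(
            q[i] <= q[j] for i in range(10) for j in range(10) if p[i] <= p[j]
        )

    def test_rejects_out_of_range(self):
        with pytest.raises(StatError):
            bh_adjust([0.5, 1.2])


class TestChiSquare:
    def test_error_by_literacy_table(self):
        stat, df, p = chi_square_independence(
            [[113, 411], [32, 201], [40, 393], [21, 512]]
        )
        assert stat == pytest.approx(82.2, abs=0.1)
        assert df == 3
        assert p < 0.001

    def test_proportional_table_is_independent(self):
        stat, _, p = chi_square_independence([[10, 90], [20, 180]])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_row_permutation_invariance(self):
        t = [[5, 10], [7, 3], [2, 9]]
        assert chi_square_independence(t)[0] == pytest.approx(
            chi_square_independence(t[::-1])[0]
        )

    def test_zero_margin_rejected(self):
        with pytest.raises(StatError):
            chi_square_independence([[0, 0], [5, 3]])


class TestWelchT:
    def test_identical_samples(self):
        t, _, p = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0
        assert p == 1.0

    def test_matches_definitional_welch_formulas(self):
        x = [4.1, 5.2, 6.3, 5.5, 4.9]
        y = [3.0, 3.8, 2.9, 4.4]
        nx, ny = len(x), len(y)
        mx, my = sum(x) / nx, sum(y) / ny
        vx = sum((a - mx) ** 2 for a in x) / (nx - 1)
        vy = sum((b - my) ** 2 for b in y) / (ny - 1)
        se2 = vx / nx + vy / ny
        t_exp = (mx - my) / math.sqrt(se2)
        df_exp = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
        t, df, p = two_sample_t(x, y)
        assert t == pytest.approx(t_exp, rel=1e-12)
        assert df == pytest.approx(df_exp, rel=1e-12)
        assert p == pytest.approx(2 * sps.t.sf(abs(t_exp), df_exp), rel=1e-9)

    def test_swap_negates_t_preserves_p(self):
        x, y = [1.0, 2.0, 4.0], [5.0, 6.0, 9.0]
        t1, _, p1 = two_sample_t(x, y)
        t2, _, p2 = two_sample_t(y, x)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_degenerate_samples_rejected(self):
        with pytest.raises(StatError):
            two_sample_t([1.0], [2.0, 3.0])


class TestFitLine:
    def test_exact_line(self):
        fit = fit_line([1, 2, 3, 4, 5], [3, 5, 7, 9, 11])
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)

    def test_constant_shift_moves_intercept_only(self):
        x = [1.0, 2.0, 5.0, 7.0]
        y = [2.0, 1.0, 6.0, 5.0]
        base = fit_line(x, y)
        shifted = fit_line(x, [v + 10 for v in y])
        assert shifted.slope == pytest.approx(base.slope)
        assert shifted.intercept == pytest.approx(base.intercept + 10)

    def test_zero_predictor_variance_rejected(self):
        with pytest.raises(StatError):
            fit_line([2, 2, 2], [1, 2, 3])


class TestSampleSize:
    def test_planning_value_for_moderate_correlation(self):
        assert sample_size_for_correlation(0.40, 0.05, 0.80) == 47

    def test_limit_for_near_perfect_correlation(self):
        assert sample_size_for_correlation(0.999999, 0.05, 0.80) == 4

    def test_monotone_in_r_and_power(self):
        ns = [sample_size_for_correlation(r, 0.05, 0.80) for r in (0.2, 0.4, 0.6, 0.8)]
        assert ns == sorted(ns, reverse=True)
        np_ = [sample_size_for_correlation(0.4, 0.05, b) for b in (0.5, 0.8, 0.9, 0.99)]
        assert np_ == sorted(np_)

    def test_zero_correlation_rejected(self):
        with pytest.raises(StatError):
            sample_size_for_correlation(0.0)
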