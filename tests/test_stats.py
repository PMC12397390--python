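"""Two-sample battery, literal Holm-Bonferroni, and auxiliary tests,
checked against full-enumeration oracles."""

import math
from itertools import combinations

import numpy as np
import pytest
from scipy import stats as sps

from accelseg.stats import (
    GroupComparisonResult,
    StatError,
    bws_asymptotic_sf,
    bws_statistic,
    bws_test,
    correlate_severity,
    holm_bonferroni,
    kolmogorov_smirnov,
    mann_whitney_u,
    run_battery,
    welch_t_test,
)


# ---------------------------------------------------------------- oracles

def mwu_p_enumeration(a, b):
    """Two-sided exact MWU p by symmetric-deviation enumeration of all
    C(n1+n2, n1) labelings (valid for tie-free data)."""
    pooled = np.concatenate([a, b])
    n1 = len(a)
    ranks = sps.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    mu = n1 * len(b) / 2
    count = 0
    total = 0
    for comb in combinations(range(len(pooled)), n1):
        u = ranks[list(comb)].sum() - n1 * (n1 + 1) / 2
        count += abs(u - mu) >= abs(u_obs - mu) - 1e-12
        total += 1
    return count / total


def bws_b_oracle(x, y):
    """Literal loop implementation of the rank-discrepancy statistic."""
    n, m = len(x), len(y)
    pooled = sorted(list(x) + list(y))
    rx = sorted(pooled.index(v) + 1 for v in x)
    ry = sorted(pooled.index(v) + 1 for v in y)
    bx = sum((rx[i - 1] - (m + n) / n * i) ** 2
             / ((i / (n + 1)) * (1 - i / (n + 1)) * (m * (m + n) / n))
             for i in range(1, n + 1)) / n
    by = sum((ry[j - 1] - (m + n) / m * j) ** 2
             / ((j / (m + 1)) * (1 - j / (m + 1)) * (n * (m + n) / m))
             for j in range(1, m + 1)) / m
    return 0.5 * (bx + by)


def bws_p_enumeration(a, b):
    pooled = list(a) + list(b)
    n = len(a)
    b_obs = bws_b_oracle(a, b)
    count = total = 0
    for comb in combinations(range(len(pooled)), n):
        x = [pooled[i] for i in comb]
        y = [pooled[i] for i in range(len(pooled)) if i not in comb]
        count += bws_b_oracle(x, y) >= b_obs - 1e-12
        total += 1
    return count / total


def ks_d_oracle(a, b):
    """Max ECDF gap by sweeping every pooled value."""
    a, b = np.asarray(a), np.asarray(b)
    grid = np.concatenate([a, b])
    return max(
        abs(np.mean(a <= v) - np.mean(b <= v)) for v in grid
    )


# ---------------------------------------------------------------- MWU

class TestMannWhitneyU:
    def test_identical_multisets_no_separation(self):
        assert mann_whitney_u([1, 2, 3], [1, 2, 3]).p == pytest.approx(1.0)

    def test_fully_separated_small_groups(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.p == pytest.approx(0.1)  # 2/20 labelings as extreme
        assert res.method == "exact"

    def test_matches_full_enumeration_at_study_sizes(self, rng):
        a = rng.standard_normal(5)
        b = rng.standard_normal(10) + 0.8
        res = mann_whitney_u(a, b)
        assert res.method == "exact"
        assert res.p == pytest.approx(mwu_p_enumeration(a, b), abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(StatError):
            mann_whitney_u([], [1.0])


# ---------------------------------------------------------------- KS

class TestKolmogorovSmirnov:
    def test_identical_samples(self):
        res = kolmogorov_smirnov([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.p == pytest.approx(1.0)

    def test_fully_separated_samples(self):
        assert kolmogorov_smirnov([1, 2], [3, 4]).statistic == pytest.approx(1.0)

    def test_statistic_matches_ecdf_sweep(self, rng):
        a = rng.standard_normal(5)
        b = rng.standard_normal(10) + 0.5
        res = kolmogorov_smirnov(a, b)
        assert res.statistic == pytest.approx(ks_d_oracle(a, b), abs=1e-12)


# ---------------------------------------------------------------- BWS

class TestBWS:
    def test_interleaved_samples_near_null(self):
        res = bws_test([1, 3, 5], [2, 4, 6], method="exact_permutation")
        assert res.statistic < 1.0
        assert res.p > 0.5

    def test_fully_separated_minimal_p(self):
        res = bws_test([1, 2, 3], [10, 11, 12], method="exact_permutation")
        # equal group sizes: observed split and its mirror share the maximal B
        assert res.p == pytest.approx(2 / math.comb(6, 3))

    def test_statistic_matches_loop_oracle_and_scipy(self, rng):
        a = rng.standard_normal(6)
        b = rng.standard_normal(8) + 0.3
        assert bws_statistic(a, b) == pytest.approx(bws_b_oracle(list(a), list(b)), rel=1e-12)
        assert bws_statistic(a, b) == pytest.approx(
            float(sps.bws_test(a, b).statistic), rel=1e-12
        )

    @pytest.mark.parametrize("n1,n2", [(4, 4), (5, 10)])
    def test_permutation_p_matches_full_enumeration(self, n1, n2, rng):
        a = rng.standard_normal(n1)
        b = rng.standard_normal(n2) + 1.0
        res = bws_test(a, b, method="exact_permutation")
        assert res.p == pytest.approx(bws_p_enumeration(list(a), list(b)), abs=1e-12)

    def test_ties_use_midranks_and_flag(self):
        res = bws_test([1, 1, 2, 3], [1, 2, 2, 4], method="exact_permutation")
        assert res.ties

    def test_asymptotic_reproduces_limit_critical_values(self):
        assert bws_asymptotic_sf(1.933) == pytest.approx(0.10, abs=1e-3)
        assert bws_asymptotic_sf(2.492) == pytest.approx(0.05, abs=1e-3)
        assert bws_asymptotic_sf(3.857) == pytest.approx(0.01, abs=1e-3)

    def test_asymptotic_refused_for_small_samples(self):
        with pytest.raises(StatError, match="asymptotic"):
            bws_test([1, 2, 3, 4], [5, 6, 7, 8], method="asymptotic")

    def test_monte_carlo_close_to_exact(self, rng):
        a = rng.standard_normal(5)
        b = rng.standard_normal(10) + 1.0
        exact = bws_test(a, b, method="exact_permutation").p
        mc = bws_test(a, b, method="monte_carlo", n_resamples=4999, rng=1).p
        assert mc == pytest.approx(exact, abs=0.03)


# ---------------------------------------------------------------- rank invariance

def test_battery_invariant_under_monotone_transform(rng):
    """All three tests are rank/ECDF based: x → exp(x) changes nothing."""
    a = rng.standard_normal(5)
    b = rng.standard_normal(10) + 0.6
    for fn in (mann_whitney_u, kolmogorov_smirnov,
               lambda u, v: bws_test(u, v, method="exact_permutation")):
        p1 = fn(a, b).p
        p2 = fn(np.exp(a), np.exp(b)).p
        assert p1 == pytest.approx(p2, abs=1e-14)


# ---------------------------------------------------------------- Holm

class TestHolmBonferroni:
    def test_variance_battery_example(self):
        res = holm_bonferroni([0.013, 0.018, 0.019], alpha=0.05)
        np.testing.assert_allclose(res.p_adjusted, [0.039, 0.036, 0.019])
        assert res.significant.all()

    def test_skewness_battery_example(self):
        res = holm_bonferroni([0.019, 0.032, 0.061], alpha=0.05)
        np.testing.assert_allclose(res.p_adjusted, [0.057, 0.064, 0.061])
        assert not res.significant.any()  # smallest adjusted > α stops everything

    def test_single_p_multiplier_one(self):
        res = holm_bonferroni([0.04])
        assert res.p_adjusted[0] == pytest.approx(0.04)
        assert res.significant[0]

    def test_largest_raw_p_returned_unchanged(self, rng):
        p = rng.uniform(0, 0.3, 5)
        res = holm_bonferroni(p)
        assert res.p_adjusted[-1] == pytest.approx(np.max(p))

    def test_no_monotonization(self):
        # literal multipliers may produce non-monotone adjusted sequences
        res = holm_bonferroni([0.013, 0.018, 0.019])
        assert res.p_adjusted[1] < res.p_adjusted[0]

    def test_cap_at_one_flagged(self):
        res = holm_bonferroni([0.5, 0.9, 0.95])
        assert res.p_adjusted[0] == 1.0 and res.capped[0]

    def test_sequential_rule_stops_once(self):
        # first test passes, second fails, third would pass on its own
        res = holm_bonferroni([0.002, 0.04, 0.045], alpha=0.05)
        assert list(res.significant) == [True, False, False]

    def test_invalid_p_rejected(self):
        with pytest.raises(StatError):
            holm_bonferroni([0.1, 1.2])


# ---------------------------------------------------------------- Welch / correlation

class TestWelch:
    def test_identical_groups(self):
        res = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_hand_example(self):
        # means 0.5 vs 10.5, both variances 0.5 → t = −10/√0.5
        res = welch_t_test([0.0, 1.0], [10.0, 11.0])
        assert res.statistic == pytest.approx(-10 / np.sqrt(0.5), rel=1e-12)

    def test_both_constant_equal_rejected(self):
        with pytest.raises(StatError):
            welch_t_test([2.0, 2.0], [2.0, 2.0])


class TestCorrelation:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        res = correlate_severity(x, 3 * x + 1)
        assert res["pearson"].statistic == pytest.approx(1.0)

    def test_monotone_nonlinear(self):
        x = np.arange(1.0, 11.0)
        res = correlate_severity(x, np.exp(x))
        assert res["spearman"].statistic == pytest.approx(1.0)
        assert res["pearson"].statistic < 1.0

    def test_null_pairs_average_near_zero(self):
        gen = np.random.default_rng(4)
        rs = [correlate_severity(gen.standard_normal(13),
                                 gen.standard_normal(13))["pearson"].statistic
              for _ in range(1000)]
        assert abs(np.mean(rs)) < 0.1

    def test_constant_input_rejected(self):
        with pytest.raises(StatError):
            correlate_severity([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


# ---------------------------------------------------------------- error calibration

def _enumerated_rejection_levels(n1=5, n2=10, alpha=0.05):
    """Exact P(p ≤ α) for MWU, KS and BWS at the given sizes: under the
    null with continuous data every rank split is equally likely, so the
    rejection probability is the fraction of splits whose p ≤ α."""
    from accelseg.stats import _bws_null_enumeration

    vals = np.arange(float(n1 + n2))
    counts = np.zeros(3)
    total = 0
    for comb in combinations(range(n1 + n2), n1):
        a = vals[list(comb)]
        b = np.delete(vals, list(comb))
        counts[0] += mann_whitney_u(a, b).p <= alpha
        counts[1] += kolmogorov_smirnov(a, b).p <= alpha
        total += 1
    # BWS: every split's p is its B's upper-tail rank within the split set
    null_b = _bws_null_enumeration(vals + 1.0, n1)
    p_bws = np.array([np.mean(null_b >= b - 1e-12) for b in null_b])
    counts[2] = np.count_nonzero(p_bws <= alpha)
    return counts / total

class TestErrorRates:
    def test_type_one_error_matches_exact_attainable_levels(self, null_battery_pvalues):
        """Each exact-path test's null rejection rate at α=0.05 equals its
        enumerated attainable level (all C(15,5) rank splits are equally
        likely under the null) and never exceeds the nominal level.

        MWU and BWS land near 0.04; the exact KS is markedly conservative
        at 5-vs-10 — its attainable level is exactly 58/3003 ≈ 0.019, a
        known discreteness effect, so only validity (≤ α) is nominal there.
        """
        n_sim = len(null_battery_pvalues)
        rates = (null_battery_pvalues <= 0.05).mean(axis=0)
        exact_levels = _enumerated_rejection_levels()
        for rate, level in zip(rates, exact_levels):
            mc_tol = 3 * np.sqrt(level * (1 - level) / n_sim)
            assert rate == pytest.approx(level, abs=mc_tol)
            assert rate <= 0.05 + mc_tol  # valid level
        # the non-conservative tests sit inside the conventional band
        assert 0.03 <= rates[0] <= 0.07  # MWU
        assert 0.03 <= rates[2] <= 0.07  # BWS

    def test_holm_controls_family_wise_error(self, null_battery_pvalues):
        """Under the global null, the Holm-adjusted 3-test battery declares
        any significance in at most ~α of simulations."""
        fwer = np.mean([
            holm_bonferroni(row).any_significant for row in null_battery_pvalues
        ])
        assert fwer <= 0.05 + 2.5 * np.sqrt(0.05 * 0.95 / len(null_battery_pvalues))


def test_run_battery_assembles_three_tests(rng):
    a = rng.standard_normal(5) + 1.5
    b = rng.standard_normal(10)
    cmp = run_battery(a, b, feature="mean_var", rng=rng)
    assert isinstance(cmp, GroupComparisonResult)
    assert sorted(cmp.test_names) == ["bws", "kolmogorov_smirnov", "mann_whitney_u"]
    assert np.all(np.diff(cmp.p_raw) >= 0)
    assert cmp.p_adjusted[-1] == pytest.approx(cmp.p_raw[-1])
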