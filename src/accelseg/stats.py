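"""Two-sample test battery, literal Holm-Bonferroni adjustment, and
auxiliary tests for cohort metadata.

The group comparison asks whether a per-animal summary statistic (mean
segmental variance σ̄²_d, or mean segmental |skewness| γ̄_d) has the same
underlying distribution in sham and lesioned animals. Because the cohorts
are small and the summaries are not plausibly normal, three nonparametric
two-sample tests are run — Mann-Whitney U, two-sample Kolmogorov-Smirnov,
and Baumgartner-Weiß-Schindler (BWS) — and their p-values corrected for
multiple testing.

The Holm-Bonferroni adjustment here is the *literal* step-down multiplier

    p̃_i = p_i · (N_HT + 1 − i)        (p_i sorted ascending, i = 1…N_HT)

without the cumulative-maximum monotonization of the textbook procedure;
significance decisions still follow the sequential rule (once a sorted
test fails α, all later ones are declared non-significant), so the
inference is identical. Adjusted values are capped at 1 with a flag.

The BWS statistic for pooled sorted ranks R (group X, sizes n, m):

    B_X = (1/n) Σ_i  [R_i − (m+n)/n · i]² / [ i/(n+1)·(1 − i/(n+1)) · m(m+n)/n ]

and symmetrically B_Y; B = (B_X + B_Y)/2. Large B means the empirical
distribution functions diverge, with tails up-weighted by the 1/(t(1−t))
factor. Its asymptotic null distribution coincides with the
Anderson-Darling limiting distribution (identical weighting of the
squared ECDF discrepancy); small-sample p-values come from permutation
enumeration instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sps

EXACT_ENUMERATION_LIMIT = 100_000  # max C(n1+n2, n1) for full enumeration
MWU_EXACT_MAX_N = 25  # exact MWU null up to this pooled size (no ties)
BWS_ASYMPTOTIC_MIN_N = 20  # below this, refuse the asymptotic path


class StatError(ValueError):
    pass


@dataclass
class TestResult:
    """Outcome of a single hypothesis test."""

    test_name: str
    statistic: float
    p: float
    method: str  # "exact" | "permutation" | "monte_carlo" | "asymptotic"
    n1: int
    n2: int
    ties: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise StatError(f"p-value {self.p} outside [0, 1]")


@dataclass
class GroupComparisonResult:
    """A test battery after literal Holm-Bonferroni adjustment.

    Rows are sorted by ascending raw p-value. ``significant`` applies the
    sequential rule at level ``alpha``; ``capped`` marks adjusted values
    clipped to 1.
    """

    feature: str
    test_names: list[str]  # sorted by ascending raw p
    p_raw: np.ndarray
    p_adjusted: np.ndarray
    significant: np.ndarray
    alpha: float
    capped: np.ndarray
    results: list[TestResult] = field(default_factory=list)

    @property
    def n_tests(self) -> int:
        return len(self.test_names)

    @property
    def any_significant(self) -> bool:
        return bool(self.significant.any())


def _check_samples(a, b, min_n=1):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < min_n or b.size < min_n:
        raise StatError(f"both samples need ≥ {min_n} observations")
    return a, b


def _has_ties(a: np.ndarray, b: np.ndarray) -> bool:
    pooled = np.concatenate([a, b])
    return np.unique(pooled).size < pooled.size


def mann_whitney_u(a, b) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact null distribution when the pooled size is ≤ 25 and there are no
    ties; otherwise the normal approximation with tie correction.
    """
    a, b = _check_samples(a, b)
    ties = _has_ties(a, b)
    exact = (a.size + b.size) <= MWU_EXACT_MAX_N and not ties
    res = sps.mannwhitneyu(a, b, alternative="two-sided",
                           method="exact" if exact else "asymptotic")
    return TestResult("mann_whitney_u", float(res.statistic), float(res.pvalue),
                      "exact" if exact else "asymptotic", a.size, b.size, ties)


def kolmogorov_smirnov(a, b) -> TestResult:
    """Two-sided two-sample Kolmogorov-Smirnov test (exact at small n)."""
    a, b = _check_samples(a, b)
    exact = a.size * b.size <= 10_000
    res = sps.ks_2samp(a, b, alternative="two-sided",
                       method="exact" if exact else "asymp")
    return TestResult("kolmogorov_smirnov", float(res.statistic), float(res.pvalue),
                      "exact" if exact else "asymptotic", a.size, b.size,
                      _has_ties(a, b))


def bws_statistic(a, b) -> float:
    """The BWS rank statistic B = (B_X + B_Y)/2, midranks under ties."""
    a, b = _check_samples(a, b, min_n=2)
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)  # midranks
    return _bws_from_ranks(np.sort(ranks[: a.size]), np.sort(ranks[a.size:]))


def _bws_from_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    n, m = rx.size, ry.size
    i = np.arange(1, n + 1)
    j = np.arange(1, m + 1)
    bx = np.mean((rx - (m + n) / n * i) ** 2
                 / ((i / (n + 1)) * (1 - i / (n + 1)) * (m * (m + n) / n)))
    by = np.mean((ry - (m + n) / m * j) ** 2
                 / ((j / (m + 1)) * (1 - j / (m + 1)) * (n * (m + n) / m)))
    return float(0.5 * (bx + by))


def _bws_null_enumeration(ranks: np.ndarray, n: int) -> np.ndarray:
    """B for every split of the pooled (mid)ranks into groups of n and m."""
    total = ranks.size
    m = total - n
    combos = np.fromiter(
        (i for c in combinations(range(total), n) for i in c), dtype=np.intp
    ).reshape(-1, n)
    n_comb = combos.shape[0]
    mask = np.zeros((n_comb, total), dtype=bool)
    mask[np.arange(n_comb)[:, None], combos] = True
    rx = np.sort(ranks[combos], axis=1)
    ry = np.sort(np.broadcast_to(ranks, (n_comb, total))[~mask].reshape(n_comb, m), axis=1)
    i = np.arange(1, n + 1)
    j = np.arange(1, m + 1)
    wx = (i / (n + 1)) * (1 - i / (n + 1)) * (m * (m + n) / n)
    wy = (j / (m + 1)) * (1 - j / (m + 1)) * (n * (m + n) / m)
    bx = np.mean((rx - (m + n) / n * i) ** 2 / wx, axis=1)
    by = np.mean((ry - (m + n) / m * j) ** 2 / wy, axis=1)
    return 0.5 * (bx + by)


def bws_asymptotic_sf(b: float) -> float:
    """Upper-tail probability of the BWS limiting null distribution.

    Uses the Marsaglia-Marsaglia polynomial approximation of the
    Anderson-Darling limiting CDF (absolute accuracy ≈ 1e-4; reproduces
    the 90/95/99% critical values 1.933/2.492/3.857).
    """
    z = float(b)
    if z <= 0:
        return 1.0
    if z < 2:
        cdf = (z ** -0.5 * math.exp(-1.2337141 / z)
               * (2.00012 + (0.247105 - (0.0649821 - (0.0347962
                  - (0.011672 - 0.00168691 * z) * z) * z) * z) * z))
    else:
        cdf = math.exp(-math.exp(1.0776 - (2.30695 - (0.43424 - (0.082433
                       - (0.008056 - 0.0003146 * z) * z) * z) * z) * z))
    return min(1.0, max(0.0, 1.0 - cdf))


def bws_test(a, b, method: str = "auto", n_resamples: int = 9999,
             rng: np.random.Generator | int | None = None) -> TestResult:
    """Baumgartner-Weiß-Schindler two-sample test.

    method
        ``"exact_permutation"`` — p from full enumeration of all
        C(n1+n2, n1) group assignments (requires that count ≤ 1e5);
        ``"monte_carlo"`` — p from ``n_resamples`` random reassignments;
        ``"asymptotic"`` — limiting-distribution p, refused for pooled
        sizes < 20 where the approximation is unreliable;
        ``"auto"`` — exact enumeration when feasible, else Monte Carlo.

    Ties are handled by midranks and flagged on the result.
    """
    a, b = _check_samples(a, b, min_n=2)
    n, m = a.size, b.size
    ties = _has_ties(a, b)
    pooled_ranks = sps.rankdata(np.concatenate([a, b]))
    b_obs = _bws_from_ranks(np.sort(pooled_ranks[:n]), np.sort(pooled_ranks[n:]))
    n_comb = math.comb(n + m, n)

    if method == "auto":
        method = "exact_permutation" if n_comb <= EXACT_ENUMERATION_LIMIT else "monte_carlo"

    if method == "exact_permutation":
        if n_comb > EXACT_ENUMERATION_LIMIT:
            raise StatError(f"{n_comb} assignments exceed the enumeration limit")
        null = _bws_null_enumeration(pooled_ranks, n)
        p = float(np.count_nonzero(null >= b_obs - 1e-12) / null.size)
        return TestResult("bws", b_obs, p, "permutation", n, m, ties)
    if method == "monte_carlo":
        gen = np.random.default_rng(rng)
        count = 0
        for _ in range(n_resamples):
            perm = gen.permutation(pooled_ranks)
            if _bws_from_ranks(np.sort(perm[:n]), np.sort(perm[n:])) >= b_obs - 1e-12:
                count += 1
        p = (count + 1) / (n_resamples + 1)
        return TestResult("bws", b_obs, float(p), "monte_carlo", n, m, ties)
    if method == "asymptotic":
        if n + m < BWS_ASYMPTOTIC_MIN_N:
            raise StatError(
                f"asymptotic BWS p-value refused for pooled size {n + m} < "
                f"{BWS_ASYMPTOTIC_MIN_N}; use a permutation method"
            )
        return TestResult("bws", b_obs, bws_asymptotic_sf(b_obs), "asymptotic", n, m, ties)
    raise StatError(f"unknown method {method!r}")


def holm_bonferroni(p_values, alpha: float = 0.05,
                    test_names: list[str] | None = None,
                    feature: str = "") -> GroupComparisonResult:
    """Literal Holm-Bonferroni step-down adjustment with sequential decisions.

    Raw p-values are sorted ascending and each multiplied by
    (N_HT + 1 − i); no running-maximum monotonization is applied, so the
    largest raw p-value is returned unchanged. Adjusted values above 1 are
    capped (flagged). Significance follows the sequential rule: the first
    sorted test with p̃ > α and every test after it are non-significant.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise StatError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise StatError("p-values must lie in [0, 1]")
    if not 0 < alpha < 1:
        raise StatError("alpha must lie in (0, 1)")
    names = test_names if test_names is not None else [f"test_{k+1}" for k in range(p.size)]
    if len(names) != p.size:
        raise StatError("test_names must align with p_values")

    order = np.argsort(p, kind="stable")
    p_sorted = p[order]
    n_ht = p.size
    multipliers = n_ht + 1 - np.arange(1, n_ht + 1)
    adjusted = p_sorted * multipliers
    capped = adjusted > 1.0
    adjusted = np.minimum(adjusted, 1.0)

    significant = np.zeros(n_ht, dtype=bool)
    for i in range(n_ht):
        if adjusted[i] <= alpha and (i == 0 or significant[i - 1]):
            significant[i] = True
        else:
            break  # sequential stop: everything after stays non-significant
    return GroupComparisonResult(
        feature=feature,
        test_names=[names[k] for k in order],
        p_raw=p_sorted,
        p_adjusted=adjusted,
        significant=significant,
        alpha=alpha,
        capped=capped,
    )


def run_battery(a, b, alpha: float = 0.05, feature: str = "",
                rng: np.random.Generator | int | None = None) -> GroupComparisonResult:
    """MWU + KS + BWS on two samples, Holm-adjusted as one battery."""
    results = [
        mann_whitney_u(a, b),
        kolmogorov_smirnov(a, b),
        bws_test(a, b, method="auto", rng=rng),
    ]
    cmp = holm_bonferroni(
        [r.p for r in results], alpha=alpha,
        test_names=[r.test_name for r in results], feature=feature,
    )
    by_name = {r.test_name: r for r in results}
    cmp.results = [by_name[name] for name in cmp.test_names]
    return cmp


def welch_t_test(a, b) -> TestResult:
    """Unpaired two-sided t-test with Welch's unequal-variance correction."""
    a, b = _check_samples(a, b, min_n=2)
    if np.var(a) == 0 and np.var(b) == 0 and np.mean(a) == np.mean(b):
        raise StatError("both groups constant and equal: t undefined")
    if np.allclose(a, a.mean()) and np.allclose(b, b.mean()) and not np.isclose(a.mean(), b.mean()):
        # zero variance but distinct means: infinite separation
        return TestResult("welch_t", float("inf"), 0.0, "asymptotic", a.size, b.size)
    res = sps.ttest_ind(a, b, equal_var=False)
    return TestResult("welch_t", float(res.statistic), float(res.pvalue),
                      "asymptotic", a.size, b.size)


def correlate_severity(summaries, rotations) -> dict[str, TestResult]:
    """Pearson and Spearman correlation of a per-animal summary statistic
    (e.g. mean segmental variance) against apomorphine-induced rotations.
    """
    x, y = _check_samples(summaries, rotations, min_n=3)
    if x.size != y.size:
        raise StatError("paired inputs must share length")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise StatError("constant input: correlation undefined")
    pr = sps.pearsonr(x, y)
    sr = sps.spearmanr(x, y)
    n = x.size
    return {
        "pearson": TestResult("correlation", float(pr.statistic), float(pr.pvalue),
                              "asymptotic", n, n),
        "spearman": TestResult("correlation", float(sr.statistic), float(sr.pvalue),
                               "asymptotic", n, n),
    }
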