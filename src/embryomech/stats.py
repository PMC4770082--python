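"""The statistical tests used across the embryo-mechanics analyses.

Thin, convention-explicit wrappers: every report records exactly which
variant ran (exact vs approximate, continuity correction, tie handling),
because the defaults differ between software packages and the analyses —
granule-brightness comparisons, stiffness-distribution shifts, live-birth
proportions, normality screens — are sensitive to them.

Defaults: two-sided everywhere; Wilcoxon rank-sum exact by enumeration for
small tie-free samples, otherwise normal approximation with tie and
continuity corrections; Yates correction for 2×2 χ²; Welch t-test;
Kolmogorov–Smirnov exact for small samples; Lilliefors by seeded
Monte-Carlo null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.proportion import proportions_ztest

__all__ = [
    "TestReport",
    "wilcoxon_rank_sum",
    "ks_two_sample",
    "chi2_contingency",
    "two_proportion_ztest",
    "lilliefors_normality",
    "t_test_two_sided",
]


@dataclass
class TestReport:
    name: str
    statistic: float
    p_value: float
    method: dict = field(default_factory=dict)
    summary: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0 + 1e-12:
            raise ValueError(f"p-value outside [0, 1]: {self.p_value}")
        self.p_value = min(float(self.p_value), 1.0)


def _summaries(x, y):
    return {
        "n_x": int(len(x)), "n_y": int(len(y)),
        "median_x": float(np.median(x)), "median_y": float(np.median(y)),
        "mean_x": float(np.mean(x)), "mean_y": float(np.mean(y)),
    }


def wilcoxon_rank_sum(x, y, mode: str = "auto") -> TestReport:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    ``mode='auto'`` uses exact null enumeration when n_x + n_y ≤ 20 and
    there are no ties, otherwise the normal approximation with tie
    correction and continuity correction.  ``'exact'``/``'asymptotic'``
    force a variant.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    ties = np.unique(np.r_[x, y]).size < x.size + y.size
    if np.unique(np.r_[x, y]).size == 1:  # fully degenerate: no evidence
        return TestReport(
            name="wilcoxon_rank_sum",
            statistic=float(x.size * y.size / 2.0),
            p_value=1.0,
            method={"mode": "degenerate", "ties_present": True},
            summary=_summaries(x, y),
        )
    if mode == "auto":
        mode = "exact" if (x.size + y.size <= 20 and not ties) else "asymptotic"
    if mode == "exact" and ties:
        raise ValueError("exact enumeration requires tie-free data")
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided",
        method="exact" if mode == "exact" else "asymptotic",
        use_continuity=True,
    )
    return TestReport(
        name="wilcoxon_rank_sum",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method={"mode": mode, "continuity_correction": mode == "asymptotic",
                "tie_correction": mode == "asymptotic", "ties_present": bool(ties)},
        summary=_summaries(x, y),
    )


def ks_two_sample(x, y, mode: str = "auto", exact_max_product: int = 400) -> TestReport:
    """Two-sample Kolmogorov–Smirnov test on D = sup |ECDF_x − ECDF_y|.

    Exact p by enumeration when n_x·n_y ≤ ``exact_max_product``; otherwise
    the asymptotic Kolmogorov distribution with effective sample size.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 values")
    if mode == "auto":
        mode = "exact" if x.size * y.size <= exact_max_product else "asymptotic"
    res = sps.ks_2samp(x, y, alternative="two-sided",
                       method="exact" if mode == "exact" else "asymp")
    return TestReport(
        name="ks_two_sample",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method={"mode": mode},
        summary=_summaries(x, y),
    )


def chi2_contingency(table, yates: bool = True) -> TestReport:
    """Pearson χ² test on a 2×k contingency table.

    Yates continuity correction applies to 2×2 tables only (the default,
    switchable).  A warning flag is set when any expected count falls below
    5, the test's validity guard.
    """
    table = np.asarray(table, float)
    if table.ndim != 2 or np.any(table < 0) or np.any(table != np.round(table)):
        raise ValueError("table must be a 2-D array of non-negative integer counts")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("all-zero row or column margin")
    correction = bool(yates) and table.shape == (2, 2)
    chi2, p, dof, expected = sps.chi2_contingency(table, correction=correction)
    return TestReport(
        name="chi2_contingency",
        statistic=float(chi2),
        p_value=float(p),
        method={"yates_correction": correction, "df": int(dof),
                "min_expected": float(expected.min()),
                "expected_below_5": bool((expected < 5).any())},
        summary={"table": table.astype(int).tolist()},
    )


def two_proportion_ztest(s1: int, n1: int, s2: int, n2: int) -> TestReport:
    """Two-sided two-proportion z-test with pooled variance."""
    for s, n in ((s1, n1), (s2, n2)):
        if n <= 0:
            raise ValueError("sample sizes must be positive")
        if not 0 <= s <= n:
            raise ValueError("successes must lie in [0, n]")
    z, p = proportions_ztest([s1, s2], [n1, n2], alternative="two-sided")
    if not np.isfinite(z):  # identical degenerate proportions (0/ n or n/n)
        z, p = 0.0, 1.0
    return TestReport(
        name="two_proportion_ztest",
        statistic=float(z),
        p_value=float(p),
        method={"pooled_variance": True},
        summary={"p1": s1 / n1, "p2": s2 / n2, "n1": n1, "n2": n2},
    )


def lilliefors_normality(x, n_mc: int = 2000, seed: int = 0) -> TestReport:
    """Lilliefors test of composite normality.

    The statistic is the KS distance between the sample ECDF and the
    Gaussian fitted by the sample mean and s.d.; since the fit uses the
    data, the null distribution is obtained by ``n_mc`` seeded Monte-Carlo
    replicates of the same statistic on standard-normal samples, with the
    add-one p-value estimator.
    """
    x = np.asarray(x, float)
    if x.size < 4:
        raise ValueError("Lilliefors test needs n >= 4")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant sample: normality is undefined")

    def stat(sample):
        z = (sample - sample.mean()) / sample.std(ddof=1)
        return _ks_to_normal(z)

    d = stat(x)
    rng = np.random.default_rng(seed)
    null = np.array([stat(rng.standard_normal(x.size)) for _ in range(n_mc)])
    p = (1.0 + np.sum(null >= d)) / (n_mc + 1.0)
    return TestReport(
        name="lilliefors_normality",
        statistic=float(d),
        p_value=float(p),
        method={"null": "monte_carlo", "n_mc": int(n_mc), "seed": int(seed)},
        summary={"n": int(x.size), "mean": float(x.mean()), "sd": float(sd)},
    )


def _ks_to_normal(z: np.ndarray) -> float:
    z = np.sort(z)
    n = z.size
    cdf = sps.norm.cdf(z)
    d_plus = np.max(np.arange(1, n + 1) / n - cdf)
    d_minus = np.max(cdf - np.arange(0, n) / n)
    return float(max(d_plus, d_minus))


def t_test_two_sided(x, y, pooled: bool = False) -> TestReport:
    """Two-sided t-test for a difference in means (Welch by default)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 values")
    res = sps.ttest_ind(x, y, equal_var=pooled)
    return TestReport(
        name="t_test_two_sided",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method={"variant": "pooled" if pooled else "welch",
                "df": float(res.df)},
        summary=_summaries(x, y),
    )
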