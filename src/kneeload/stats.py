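"""Group-comparison statistics: gated two-sample tests, effect sizes,
Bonferroni correction, and smallest-detectable-effect power analysis.

Test choice is gated on distributional checks at α = 0.05: Shapiro–Wilk on
each group and Levene's test (median-centred, i.e. Brown–Forsythe) across
groups.  If either group departs from normality or the variances differ, a
Mann–Whitney U test is used; otherwise an unpaired Student's t-test with the
requested sidedness.  Cohen's d (mean difference over pooled SD) is always
reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats


@dataclass(frozen=True)
class GroupComparison:
    """Outcome of one two-group comparison."""

    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    test: str  # t_one_tailed | t_two_tailed | mann_whitney
    p: float
    cohens_d: float
    alpha: float
    significant: bool


def cohens_d(mean_a, sd_a, n_a, mean_b, sd_b, n_b) -> float:
    """Cohen's d: mean difference divided by the pooled standard deviation."""
    if n_a < 2 or n_b < 2:
        raise ValueError("need at least 2 observations per group")
    pooled = np.sqrt(((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / (n_a + n_b - 2))
    if pooled == 0:
        return 0.0
    return float((mean_a - mean_b) / pooled)


def choose_and_run_test(a, b, tails: int = 1, alpha: float = 0.05) -> GroupComparison:
    """Distribution-gated two-group comparison.

    Parameters
    ----------
    a, b : array-like
        Per-subject values for the two groups (n >= 3 each).
    tails : {1, 2}
        Sidedness; one-tailed tests the hypothesis mean(a) > mean(b).
    alpha : float
        Significance level applied to the chosen test's p-value (pass a
        Bonferroni-corrected value for families of tests).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 observations per group")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    alternative = "greater" if tails == 1 else "two-sided"

    normal = (
        stats.shapiro(a).pvalue >= 0.05
        and stats.shapiro(b).pvalue >= 0.05
        and len(np.unique(a)) > 1
        and len(np.unique(b)) > 1
    )
    equal_var = True
    if normal:
        equal_var = stats.levene(a, b, center="median").pvalue >= 0.05

    if normal and equal_var:
        test = "t_one_tailed" if tails == 1 else "t_two_tailed"
        p = stats.ttest_ind(a, b, alternative=alternative).pvalue
    else:
        test = "mann_whitney"
        p = stats.mannwhitneyu(a, b, alternative=alternative).pvalue
    d = cohens_d(a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b))
    return GroupComparison(
        n_a=len(a),
        n_b=len(b),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)),
        sd_b=float(b.std(ddof=1)),
        test=test,
        p=float(p),
        cohens_d=d,
        alpha=alpha,
        significant=bool(p < alpha),
    )


def compare_summary_stats(
    mean_a, sd_a, n_a, mean_b, sd_b, n_b, tails: int = 1, alpha: float = 0.05
) -> GroupComparison:
    """Student's t-test and Cohen's d from printed summary statistics.

    Published studies often report only means and SDs; this mode reproduces
    the t-test and effect size from those summaries (no distribution gating
    is possible without the raw data).
    """
    alternative = "greater" if tails == 1 else "two-sided"
    res = stats.ttest_ind_from_stats(
        mean_a, sd_a, n_a, mean_b, sd_b, n_b, equal_var=True, alternative=alternative
    )
    d = cohens_d(mean_a, sd_a, n_a, mean_b, sd_b, n_b)
    return GroupComparison(
        n_a=n_a,
        n_b=n_b,
        mean_a=float(mean_a),
        mean_b=float(mean_b),
        sd_a=float(sd_a),
        sd_b=float(sd_b),
        test="t_one_tailed" if tails == 1 else "t_two_tailed",
        p=float(res.pvalue),
        cohens_d=d,
        alpha=alpha,
        significant=bool(res.pvalue < alpha),
    )


def bonferroni_alpha(family_alpha: float = 0.05, n_tests: int = 18, ndigits: int = 4) -> float:
    """Per-test significance level α / m, rounded for reporting.

    With the study's family of 18 tests (five movements × three knee-load
    variables plus three speed comparisons) and α = 0.05 this is 0.0028.
    """
    if not 0 < family_alpha < 1:
        raise ValueError("family alpha must be in (0, 1)")
    if n_tests < 1:
        raise ValueError("need at least one test")
    return round(family_alpha / n_tests, ndigits)


def _power_two_sample_t(d: float, n_per_group: int, alpha: float, tails: int) -> float:
    """Power of an unpaired two-sample t-test at effect size d (noncentral t)."""
    df = 2 * n_per_group - 2
    nc = d * np.sqrt(n_per_group / 2.0)
    if tails == 1:
        tcrit = stats.t.ppf(1 - alpha, df)
        return float(stats.nct.sf(tcrit, df, nc))
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    return float(stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc))


def smallest_detectable_effect(
    n_per_group: int, power: float = 0.8, alpha: float = 0.05, tails: int = 1
) -> float:
    """Smallest Cohen's d detectable at the given power and α.

    Solves the noncentral-t power equation of the unpaired two-sample t-test
    for the effect size, to 1e-6.  For 26 participants per group, power 0.8
    and one-tailed α = 0.05 the answer is 0.70.
    """
    if not 0 < power < 1 or not 0 < alpha < 1:
        raise ValueError("power and alpha must be in (0, 1)")
    if n_per_group < 2:
        raise ValueError("need at least 2 participants per group")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    hi = 0.5
    while _power_two_sample_t(hi, n_per_group, alpha, tails) < power:
        hi *= 2.0
        if hi > 1e3:
            raise ValueError("requested power unattainable at this sample size")
    return float(
        optimize.brentq(
            lambda d: _power_two_sample_t(d, n_per_group, alpha, tails) - power,
            1e-12,
            hi,
            xtol=1e-6,
        )
    )
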