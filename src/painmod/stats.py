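"""Group-level statistics for responder cohorts.

Paired effect summaries (Cohen's D of within-subject differences, paired
t), percent pain change, rating-variability comparisons, pooled
two-proportion z tests, a Lilliefors-style Kolmogorov-Smirnov normality
gate that routes pairwise comparisons to Student's t or Mann-Whitney U,
Bonferroni correction over the three pairwise group contrasts, and
one-way ANOVA with uncorrected post hoc t-tests for questionnaire
scores.

Conventions: SDs use the n-1 denominator; paired-effect p-values are
two-sided (the one-tailed rule applies only to subject classification);
post hoc and pairwise t-tests are pooled-variance Student's t.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

BONFERRONI_FAMILY = 3  # the three pairwise contrasts among the response classes


@dataclass(frozen=True)
class EffectSummary:
    """Paired effect of one group: statistics of within-subject differences."""

    group: str
    n: int
    mean_diff: float
    sd_diff: float
    cohens_d: float
    t_value: float
    p_value: float
    df: int
    degenerate: bool = False  # sd_diff == 0: t/p undefined


@dataclass(frozen=True)
class GroupComparison:
    measure: str
    group_a: str
    group_b: str
    test_used: str  # "t_test" | "mann_whitney"
    statistic: float
    raw_p: float
    bonferroni_p: float
    normality_p: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class AnovaResult:
    measure: str
    f_value: float
    df_between: int
    df_within: int
    p_value: float
    posthoc: tuple[GroupComparison, ...] = ()
    degenerate: bool = False


def paired_effect(diffs: Sequence[float] | np.ndarray, group: str = "all") -> EffectSummary:
    """Paired effect summary of a vector of within-subject differences.

    Cohen's D = |mean| / SD of the differences; t = mean / (SD / sqrt(n))
    with n-1 degrees of freedom and a two-sided p.  A zero-SD vector is
    returned flagged degenerate with NaN t and p.
    """
    arr = np.asarray(diffs, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError("need a 1-D vector of at least 2 differences")
    if not np.all(np.isfinite(arr)):
        raise ValueError("differences must be finite")
    n = arr.size
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    if sd == 0.0:
        return EffectSummary(group, n, mean, sd, math.nan, math.nan, math.nan,
                             n - 1, degenerate=True)
    d = abs(mean) / sd
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df=n - 1)
    return EffectSummary(group, n, mean, sd, d, t, float(p), n - 1)


def percent_change(control_mean: float, test_mean: float) -> float:
    """Percent pain change of one subject relative to its control series."""
    if not np.isfinite(control_mean) or not np.isfinite(test_mean):
        raise ValueError("means must be finite")
    if control_mean <= 0:
        raise ValueError("percent change undefined for control mean <= 0")
    return 100.0 * (test_mean - control_mean) / control_mean


def mean_sem(values: Sequence[float] | np.ndarray) -> tuple[float, float]:
    """Cohort summary: mean and standard error of the mean."""
    arr = np.asarray(values, dtype=float)
    return float(arr.mean()), float(arr.std(ddof=1) / math.sqrt(arr.size))


def two_proportion_test(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Pooled two-independent-proportions z test (two-sided).

    With a pooled proportion of exactly 0 or 1 the statistic is defined
    as z = 0, p = 1 (no evidence of a difference).
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n < 1 or not 0 <= k <= n:
            raise ValueError("need 0 <= k <= n with n >= 1")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return 0.0, 1.0
    se = math.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    z = (p1 - p2) / se
    return z, float(2.0 * sps.norm.sf(abs(z)))


def normality_gate(groups: Mapping[str, np.ndarray]) -> tuple[str, dict[str, float]]:
    """Choose t-test vs Mann-Whitney from per-group KS normality.

    Each group is tested against a normal law with its own estimated mean
    and SD (Lilliefors critical values).  If any group rejects at 0.05 —
    or is degenerate (zero variance) — pairwise comparisons use
    ``mann_whitney``; otherwise ``t_test``.  Returns the choice and the
    per-group normality p-values.
    """
    pvals: dict[str, float] = {}
    choice = "t_test"
    for name, values in groups.items():
        arr = np.asarray(values, dtype=float)
        if arr.size < 4:
            raise ValueError(f"group {name!r} needs n >= 4 for the normality gate")
        if arr.std(ddof=1) == 0.0:
            warnings.warn(f"group {name!r} has zero variance; using Mann-Whitney")
            pvals[name] = 0.0
            choice = "mann_whitney"
            continue
        _, p = lilliefors(arr, dist="norm")
        pvals[name] = float(p)
        if p < 0.05:
            choice = "mann_whitney"
    return choice, pvals


def _pairwise(
    measure: str,
    name_a: str,
    a: np.ndarray,
    name_b: str,
    b: np.ndarray,
    test_used: str,
    normality_p: dict[str, float],
    family: int,
) -> GroupComparison:
    if test_used == "t_test":
        stat, p = sps.ttest_ind(a, b, equal_var=True)
    else:
        method = "exact" if max(a.size, b.size) <= 20 else "asymptotic"
        stat, p = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return GroupComparison(
        measure=measure,
        group_a=name_a,
        group_b=name_b,
        test_used=test_used,
        statistic=float(stat),
        raw_p=float(p),
        bonferroni_p=min(1.0, float(p) * family),
        normality_p=normality_p,
    )


def compare_groups(
    measure: str,
    groups: Mapping[str, Sequence[float] | np.ndarray],
    family_size: int = BONFERRONI_FAMILY,
) -> list[GroupComparison]:
    """All pairwise group comparisons for one measure, Bonferroni-corrected.

    The test (pooled t vs Mann-Whitney) is gated per comparison by KS
    normality of the two groups involved.  Groups with n < 2 are skipped
    with a warning.
    """
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    names = list(arrays)
    out: list[GroupComparison] = []
    for i, name_a in enumerate(names):
        for name_b in names[i + 1:]:
            a, b = arrays[name_a], arrays[name_b]
            if a.size < 2 or b.size < 2:
                warnings.warn(
                    f"{measure}: skipping {name_a} vs {name_b} (group with n < 2)"
                )
                continue
            if min(a.size, b.size) >= 4:
                test_used, pvals = normality_gate({name_a: a, name_b: b})
            else:  # too small for the gate; rank test is the safe branch
                test_used, pvals = "mann_whitney", {}
            out.append(
                _pairwise(measure, name_a, a, name_b, b, test_used, pvals, family_size)
            )
    return out


def anova_with_posthoc(
    measure: str, groups: Mapping[str, Sequence[float] | np.ndarray]
) -> AnovaResult:
    """One-way fixed-effects ANOVA; uncorrected post hoc t-tests if p < 0.05.

    Zero within-group variance everywhere (with unequal means) makes F
    unbounded: the result is flagged degenerate instead.
    """
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(arrays) < 2 or any(a.size < 2 for a in arrays.values()):
        raise ValueError("need >= 2 groups with n >= 2 each")
    k = len(arrays)
    big_n = sum(a.size for a in arrays.values())
    df_b, df_w = k - 1, big_n - k
    if all(a.std(ddof=1) == 0.0 for a in arrays.values()):
        means = [a.mean() for a in arrays.values()]
        if np.ptp(means) > 0:
            return AnovaResult(measure, math.inf, df_b, df_w, 0.0, degenerate=True)
        return AnovaResult(measure, 0.0, df_b, df_w, 1.0, degenerate=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant-input warnings handled above
        f, p = sps.f_oneway(*arrays.values())
    posthoc: tuple[GroupComparison, ...] = ()
    if p < 0.05:
        names = list(arrays)
        posthoc = tuple(
            _pairwise(measure, a, arrays[a], b, arrays[b], "t_test", {}, family=1)
            for i, a in enumerate(names)
            for b in names[i + 1:]
        )
    return AnovaResult(measure, float(f), df_b, df_w, float(p), posthoc)
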