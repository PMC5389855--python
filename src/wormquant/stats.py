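"""Cohort statistics for group comparisons.

Cohort tables are pandas DataFrames with columns ``subject_id``,
``experiment_id``, ``group``, ``value`` and an optional boolean ``excluded``
flag (lost or bagged animals), honored by every operation here. Includes
relative-fluorescence normalization against per-experiment controls,
Welch/pooled t-tests and one-way ANOVA with Bonferroni correction, the
Wilcoxon rank-sum lifespan test (exact for small cohorts, tie-corrected
normal approximation with continuity correction otherwise), survival
summaries, and scored-proportion comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, erf, sqrt

import numpy as np
import pandas as pd
from scipy import stats as sps

#: Combined-sample-size cutoff below which the rank-sum p-value is computed
#: by exhaustive enumeration rather than the normal approximation.
EXACT_RANKSUM_MAX_N = 20

COHORT_COLUMNS = ("subject_id", "experiment_id", "group", "value")


@dataclass(frozen=True)
class ComparisonResult:
    group_a: str
    group_b: str
    statistic_name: str
    statistic: float
    p_raw: float
    p_adjusted: float
    m_comparisons: int
    n_a: int
    n_b: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_raw <= 1.0 and 0.0 <= self.p_adjusted <= 1.0):
            raise ValueError("p-values must lie in [0, 1]")
        if self.p_adjusted + 1e-12 < self.p_raw:
            raise ValueError("adjusted p cannot be smaller than raw p")


def bonferroni(p_raw: float, m: int) -> float:
    """Bonferroni-adjusted p-value, min(1, m * p_raw)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, m * p_raw)


def _active(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table missing columns {missing}")
    if (table["group"].astype(str) == "").any() or (table["experiment_id"].astype(str) == "").any():
        raise ValueError("every row needs nonempty group and experiment labels")
    if "excluded" in table.columns:
        return table[~table["excluded"].astype(bool)]
    return table


def _group_values(table: pd.DataFrame, group: str) -> np.ndarray:
    vals = table.loc[table["group"] == group, "value"].to_numpy(dtype=float)
    return vals


# ---------------------------------------------------------------------------
# Relative fluorescence
# ---------------------------------------------------------------------------


def relative_values(table: pd.DataFrame, control_group: str) -> pd.DataFrame:
    """Divide each value by the mean of same-experiment control values.

    Every experiment must contain at least one control row with nonzero mean;
    control rows are kept (their per-experiment mean becomes 1), so pooled
    cross-experiment comparisons against control are dimensionless.
    """
    tab = _active(table).copy()
    out = []
    for exp_id, sub in tab.groupby("experiment_id", sort=False):
        ctrl = sub.loc[sub["group"] == control_group, "value"]
        if ctrl.empty:
            raise ValueError(f"experiment {exp_id!r} has no {control_group!r} control rows")
        mean = float(ctrl.mean())
        if mean == 0:
            raise ValueError(f"experiment {exp_id!r} has zero control mean")
        rel = sub.copy()
        rel["value"] = sub["value"] / mean
        out.append(rel)
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# t-tests / ANOVA with Bonferroni
# ---------------------------------------------------------------------------


def ttest_bonferroni(
    table: pd.DataFrame,
    comparisons: list[tuple[str, str]],
    m: int | str = "auto",
    equal_var: bool = False,
) -> list[ComparisonResult]:
    """Two-sided two-sample t-tests (Welch by default) with Bonferroni correction.

    ``m="auto"`` sets the correction factor to the number of listed
    comparisons. ``equal_var=True`` switches to the pooled-variance test.
    """
    tab = _active(table)
    m_val = len(comparisons) if m == "auto" else int(m)
    if m != "auto" and m_val < len(comparisons):
        raise ValueError("m must be >= the number of comparisons")
    results = []
    for group, control in comparisons:
        a = _group_values(tab, group)
        b = _group_values(tab, control)
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"groups {group!r} vs {control!r} need n >= 2")
        t, p = sps.ttest_ind(a, b, equal_var=equal_var)
        results.append(
            ComparisonResult(
                group_a=group,
                group_b=control,
                statistic_name="t (Welch)" if not equal_var else "t (pooled)",
                statistic=float(t),
                p_raw=float(p),
                p_adjusted=bonferroni(float(p), m_val),
                m_comparisons=m_val,
                n_a=len(a),
                n_b=len(b),
            )
        )
    return results


def anova_bonferroni(
    table: pd.DataFrame,
    groups: list[str],
    posthoc_pairs: list[tuple[str, str]] | None = None,
    equal_var: bool = False,
) -> tuple[ComparisonResult, list[ComparisonResult]]:
    """One-way ANOVA omnibus F plus Bonferroni-corrected post-hoc t-tests."""
    tab = _active(table)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    samples = [_group_values(tab, g) for g in groups]
    for g, s in zip(groups, samples):
        if len(s) < 2:
            raise ValueError(f"group {g!r} needs n >= 2")
    f, p = sps.f_oneway(*samples)
    if not np.isfinite(f):  # identical values in every group
        f, p = 0.0, 1.0
    omnibus = ComparisonResult(
        group_a="|".join(groups),
        group_b="",
        statistic_name="F (one-way ANOVA)",
        statistic=float(f),
        p_raw=float(p),
        p_adjusted=float(p),
        m_comparisons=1,
        n_a=sum(len(s) for s in samples),
        n_b=0,
    )
    posthoc = ttest_bonferroni(table, posthoc_pairs, equal_var=equal_var) if posthoc_pairs else []
    return omnibus, posthoc


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------


def _ranksum_exact_p(ranks: np.ndarray, n_a: int, w_obs: float) -> float:
    """Two-sided exact p by exhaustive enumeration of group-A rank subsets."""
    n = len(ranks)
    mu = n_a * (n + 1) / 2.0
    dev = abs(w_obs - mu) - 1e-9  # tolerance for float midranks
    count = 0
    for idx in combinations(range(n), n_a):
        w = sum(ranks[i] for i in idx)
        if abs(w - mu) >= dev:
            count += 1
    return count / comb(n, n_a)


def _sample_sum_moments(ranks: np.ndarray, n_a: int) -> tuple[float, float]:
    """Exact variance and 4th central moment of the rank sum of a simple
    random sample of ``n_a`` ranks drawn without replacement.

    Computed from the centered power sums of the (mid)rank population, so
    ties are handled exactly.
    """
    N = len(ranks)
    y = np.asarray(ranks, dtype=float) - float(np.mean(ranks))
    P2 = float(np.sum(y**2))
    P4 = float(np.sum(y**4))

    def p(k: int) -> float:  # joint inclusion probability of k distinct items
        num = den = 1.0
        for i in range(k):
            num *= n_a - i
            den *= N - i
        return num / den

    var = (p(1) - p(2)) * P2
    m4 = (
        p(1) * P4
        - 4 * p(2) * P4
        + 3 * p(2) * (P2**2 - P4)
        + 6 * p(3) * (2 * P4 - P2**2)
        + p(4) * (3 * P2**2 - 6 * P4)
    )
    return var, m4


def _ranksum_normal_p(ranks: np.ndarray, n_a: int, w_obs: float) -> float:
    """Two-sided approximate p: normal with continuity correction plus an
    Edgeworth kurtosis term.

    The rank-sum null is platykurtic at small n, so the plain normal curve
    under-covers mid-range p-values; the fourth-moment (Edgeworth) term uses
    the exact finite-population moments of the rank sum, which also absorbs
    the usual tie correction of the variance.
    """
    n = len(ranks)
    mu = n_a * (n + 1) / 2.0
    var, m4 = _sample_sum_moments(ranks, n_a)
    if var <= 0:  # all observations tied
        return 1.0
    excess_kurt = m4 / var**2 - 3.0
    dev = max(abs(w_obs - mu) - 0.5, 0.0)  # continuity correction toward the mean
    z = dev / sqrt(var)
    dens = np.exp(-z * z / 2.0) / sqrt(2.0 * np.pi)
    p = 2.0 * (1.0 - _phi(z)) + 2.0 * dens * (excess_kurt / 24.0) * (z**3 - 3.0 * z)
    return float(min(1.0, max(p, 0.0)))


def _phi(z: float) -> float:
    return 0.5 * (1.0 + erf(z / sqrt(2.0)))


def wilcoxon_ranksum(days_a, days_b, method: str = "auto") -> ComparisonResult:
    """Two-sided Wilcoxon rank-sum test on two samples (e.g. death days).

    Ranks use midranks for ties. ``method="exact"`` enumerates all
    C(n_a+n_b, n_a) assignments of ranks to group A and reports the exact
    permutation p; ``"approx"`` uses the normal approximation with
    tie-corrected variance and a 0.5 continuity correction; ``"auto"``
    switches from exact to approx above a combined n of
    ``EXACT_RANKSUM_MAX_N``.
    """
    a = np.asarray(days_a, dtype=float)
    b = np.asarray(days_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)  # midranks
    w_obs = float(ranks[: a.size].sum())
    n = pooled.size
    if method == "auto":
        method = "exact" if n <= EXACT_RANKSUM_MAX_N else "approx"
    if method == "exact":
        p = _ranksum_exact_p(ranks, a.size, w_obs)
    elif method == "approx":
        p = _ranksum_normal_p(ranks, a.size, w_obs)
    else:
        raise ValueError(f"unknown method {method!r}")
    return ComparisonResult(
        group_a="a",
        group_b="b",
        statistic_name="W (rank sum of group a)",
        statistic=w_obs,
        p_raw=float(p),
        p_adjusted=float(p),
        m_comparisons=1,
        n_a=int(a.size),
        n_b=int(b.size),
    )


# ---------------------------------------------------------------------------
# Survival summaries and scored proportions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SurvivalSummary:
    n: int
    mean: float
    sem: float  # NaN when n < 2
    median: float
    survival_curve: tuple  # S(t) for t = 0..horizon, fraction with death day > t


def survival_summary(days, scoring_horizon: int) -> SurvivalSummary:
    """Mean +/- s.e.m., median, and fraction-surviving-by-day curve.

    s.e.m. uses the sample standard deviation (n-1 denominator) and is NaN
    for n < 2; S(t) is the fraction of the cohort with death day strictly
    greater than t, reported for t = 0..scoring_horizon.
    """
    d = np.asarray(days, dtype=float)
    if d.size == 0:
        raise ValueError("empty cohort")
    if np.any(d <= 0):
        raise ValueError("death days must be positive")
    mean = float(d.mean())
    sem = float(d.std(ddof=1) / sqrt(d.size)) if d.size >= 2 else float("nan")
    median = float(np.median(d))
    curve = tuple(float(np.mean(d > t)) for t in range(int(scoring_horizon) + 1))
    return SurvivalSummary(n=int(d.size), mean=mean, sem=sem, median=median, survival_curve=curve)


def proportion_scored(
    table: pd.DataFrame,
    comparisons: list[tuple[str, str]] | None = None,
    m: int | str = "auto",
) -> tuple[pd.DataFrame, list[ComparisonResult]]:
    """Percent of positively scored animals per group per experiment.

    ``value`` is a boolean score per worm. Percentages are computed within
    each (experiment, group); comparisons are then run on the per-experiment
    percentages via :func:`ttest_bonferroni`, matching a design where the
    unit of replication is the independent experiment.
    """
    tab = _active(table)
    if tab.empty:
        raise ValueError("no scored animals")
    pct = (
        tab.groupby(["experiment_id", "group"])["value"]
        .agg(lambda v: 100.0 * np.count_nonzero(v) / len(v))
        .reset_index()
        .rename(columns={"value": "percent"})
    )
    results: list[ComparisonResult] = []
    if comparisons:
        per_exp = pct.rename(columns={"percent": "value"}).copy()
        per_exp["subject_id"] = per_exp["experiment_id"]
        results = ttest_bonferroni(per_exp, comparisons, m=m)
    return pct, results
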