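"""Between-cohort statistical comparisons.

Scalar engagement metrics and baseline scores are compared with a two-sample
Welch t-test (the cohorts' variances differ markedly, so the pooled-variance
test is not assumed), two-tailed, with Cohen's d on the pooled standard
deviation as the effect size. Fitted sentiment slopes are compared through a
time x cohort interaction term in an OLS on the stacked per-bin means; a
seeded permutation alternative is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .inclusion import THRESHOLD, filter_corpus, initial_state
from .sessions import ChatSession
from .trajectory import (
    BIN_CENTERS,
    AggregateTrend,
    BinnedTrajectory,
    aggregate,
    fit_trend,
    improvement_percent,
)


@dataclass(slots=True)
class CohortComparison:
    metric: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    difference: float
    percent_difference: float
    statistic: float
    p_value: float
    cohens_d: float


@dataclass(slots=True)
class SlopeComparison:
    sentiment: str
    slope_a: float
    slope_b: float
    improvement_a: float
    improvement_b: float
    delta_improvement: float
    interaction: float
    interaction_se: float
    p_value: float


def percent_difference(mean_a: float, mean_b: float) -> float:
    """(mean_a - mean_b) / mean_b x 100: the relative excess of A over B."""
    return (mean_a - mean_b) / mean_b * 100.0


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Classical Cohen's d with the pooled standard deviation."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    va, vb = a.var(ddof=1), b.var(ddof=1)
    pooled = np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
    if pooled == 0:
        return 0.0
    return float((a.mean() - b.mean()) / pooled)


def compare_metric(
    values_a: Sequence[float],
    values_b: Sequence[float],
    metric: str = "",
    method: str = "welch",
) -> CohortComparison:
    """Two-tailed two-sample comparison of a scalar metric.

    ``method`` is ``"welch"`` (default) or ``"mannwhitney"``. If both samples
    have zero variance the test is degenerate; by convention p = 1 and d = 0.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        statistic, p = 0.0, 1.0
        d = 0.0
    elif method == "welch":
        res = stats.ttest_ind(a, b, equal_var=False)
        statistic, p = float(res.statistic), float(res.pvalue)
        d = cohens_d(a, b)
    elif method == "mannwhitney":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        statistic, p = float(res.statistic), float(res.pvalue)
        d = cohens_d(a, b)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CohortComparison(
        metric=metric,
        n_a=int(a.size),
        n_b=int(b.size),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)),
        sd_b=float(b.std(ddof=1)),
        difference=float(a.mean() - b.mean()),
        percent_difference=percent_difference(a.mean(), b.mean()),
        statistic=statistic,
        p_value=p,
        cohens_d=d,
    )


def compare_baselines(
    sessions_a: Iterable[ChatSession],
    sessions_b: Iterable[ChatSession],
    sentiment: str,
    threshold: float = THRESHOLD,
    pre_filtered: bool = False,
    method: str = "welch",
) -> CohortComparison:
    """Compare initial emotional states between cohorts for one sentiment.

    Applies inclusion filtering first (unless ``pre_filtered``), then runs
    :func:`compare_metric` on the per-session initial scores.
    """
    sessions_a, sessions_b = list(sessions_a), list(sessions_b)
    if not pre_filtered:
        sessions_a, _ = filter_corpus(sessions_a, sentiment, threshold)
        sessions_b, _ = filter_corpus(sessions_b, sentiment, threshold)
    init_a = [initial_state(s, sentiment) for s in sessions_a]
    init_b = [initial_state(s, sentiment) for s in sessions_b]
    if not init_a or not init_b:
        raise ValueError("both cohorts must have included sessions")
    return compare_metric(init_a, init_b, metric=f"baseline_{sentiment}", method=method)


def compare_slopes(trend_a: AggregateTrend, trend_b: AggregateTrend) -> SlopeComparison:
    """Compare fitted slopes between two cohorts via an interaction OLS.

    Stacks the two aggregates' per-bin means with a cohort indicator g
    (g = 1 for cohort A) and fits y ~ 1 + t + g + t*g; the t*g coefficient
    estimates slope_A - slope_B and its two-tailed t-test is reported. With a
    perfect (zero-residual) fit the t statistic is degenerate; p is then 1
    for a zero interaction and 0 otherwise.
    """
    import statsmodels.api as sm

    rows_x, rows_y, rows_g = [], [], []
    for g, tr in ((1.0, trend_a), (0.0, trend_b)):
        mask = ~np.isnan(tr.aggregate.mean)
        if mask.sum() < 2:
            raise ValueError("each cohort needs >= 2 populated bins")
        rows_x.append(BIN_CENTERS[mask])
        rows_y.append(tr.aggregate.mean[mask])
        rows_g.append(np.full(mask.sum(), g))
    x = np.concatenate(rows_x)
    y = np.concatenate(rows_y)
    g = np.concatenate(rows_g)
    X = np.column_stack([np.ones_like(x), x, g, x * g])
    fit = sm.OLS(y, X).fit()
    est = float(fit.params[3])
    se = float(fit.bse[3])
    p = float(fit.pvalues[3])
    if not np.isfinite(p) or fit.mse_resid < 1e-18:
        # (near-)zero residual variance: the t statistic is pure round-off
        p = 1.0 if abs(est) < 1e-9 else 0.0
    return SlopeComparison(
        sentiment=trend_a.sentiment,
        slope_a=trend_a.fit.slope,
        slope_b=trend_b.fit.slope,
        improvement_a=trend_a.improvement_pct,
        improvement_b=trend_b.improvement_pct,
        delta_improvement=trend_a.improvement_pct - trend_b.improvement_pct,
        interaction=est,
        interaction_se=se,
        p_value=p,
    )


def compare_slopes_permutation(
    trajectories_a: Sequence[BinnedTrajectory],
    trajectories_b: Sequence[BinnedTrajectory],
    n_permutations: int = 1000,
    seed: int = 0,
) -> dict:
    """Permutation test on the slope difference (label shuffles, seeded).

    The observed statistic is slope_A - slope_B from fits to each cohort's
    aggregate; the null distribution reassigns session trajectories to
    cohorts uniformly at random, preserving cohort sizes.
    """

    def slope_diff(ta: Sequence[BinnedTrajectory], tb: Sequence[BinnedTrajectory]) -> float:
        return fit_trend(aggregate(list(ta))).slope - fit_trend(aggregate(list(tb))).slope

    observed = slope_diff(trajectories_a, trajectories_b)
    pool = list(trajectories_a) + list(trajectories_b)
    n_a = len(trajectories_a)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(len(pool))
        pa = [pool[i] for i in perm[:n_a]]
        pb = [pool[i] for i in perm[n_a:]]
        if abs(slope_diff(pa, pb)) >= abs(observed):
            exceed += 1
    p = (exceed + 1) / (n_permutations + 1)
    return {"observed": observed, "p_value": p, "n_permutations": n_permutations}


def significance_marker(p: float) -> str:
    """Figure-style significance stars at .05 / .01 / .001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""
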