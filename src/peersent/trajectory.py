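"""Normalized-time binning, aggregation, and linear trend fitting.

Sessions vary widely in length, so each one is mapped onto a common relative
clock: a message at ``time_offset / duration`` lands in one of 100 bins of
width 0.01 covering [0, 1]. Binned trajectories are averaged across sessions
bin-by-bin, an ordinary least-squares line is fitted to the per-bin means
against the bin centers, and the session-level change is summarized by the
*improvement percentage*

    improvement% = |slope| / intercept x 100,

the fitted relative change over one full session (decline for negative
sentiments, rise for optimism). Goodness of fit is the coefficient of
determination R^2 and per-bin variability is reported as the standard error
of the mean (SEM).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .inclusion import THRESHOLD, filter_corpus
from .sessions import ChatSession

#: Number of normalized-time bins (width 0.01 over [0, 1]).
N_BINS = 100

#: Bin centers used as the regressor in the trend fit.
BIN_CENTERS = (np.arange(N_BINS) + 0.5) / N_BINS


@dataclass(slots=True)
class BinnedTrajectory:
    """One session x sentiment reduced to 100 normalized-time bins.

    ``bin_values[i]`` is the mean score of the session's messages falling in
    [0.01*i, 0.01*(i+1)), NaN where no scored message landed. t = 1.0 (the
    final message) is clamped into the last bin.
    """

    session_id: str
    sentiment: str
    bin_values: np.ndarray  # shape (100,), float, NaN = missing


@dataclass(slots=True)
class BinAggregate:
    """Per-bin mean, SEM and contributor count across sessions."""

    sentiment: str
    mean: np.ndarray  # shape (100,), NaN where no session contributes
    sem: np.ndarray
    n: np.ndarray  # int contributor counts
    n_sessions: int

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bin_center": BIN_CENTERS, "mean": self.mean, "sem": self.sem, "n": self.n}
        )


@dataclass(slots=True)
class TrendFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    stderr: float
    n_bins: int


@dataclass(slots=True)
class AggregateTrend:
    """Full trend summary for one sentiment: bins + OLS fit + improvement %."""

    sentiment: str
    aggregate: BinAggregate
    fit: TrendFit
    n_sessions: int
    improvement_pct: float

    def summary(self) -> dict:
        return {
            "sentiment": self.sentiment,
            "slope": self.fit.slope,
            "intercept": self.fit.intercept,
            "r2": self.fit.r_squared,
            "p": self.fit.p_value,
            "n_sessions": self.n_sessions,
            "improvement_pct": self.improvement_pct,
        }


def normalize_session(session: ChatSession, sentiment: str) -> BinnedTrajectory:
    """Bin one session's scored messages onto the normalized-time grid.

    Multiple scored messages falling in the same bin are averaged; bins with
    no scored message remain NaN. Messages without a score for the target
    sentiment contribute nothing.
    """
    if session.duration_min <= 0:
        raise ValueError("session duration must be > 0")
    sums = np.zeros(N_BINS)
    counts = np.zeros(N_BINS, dtype=int)
    for m in session.primary_user_messages():
        score = m.scores.get(sentiment)
        if score is None:
            continue
        t = m.time_offset_min / session.duration_min
        idx = min(int(t / 0.01), N_BINS - 1)
        sums[idx] += score
        counts[idx] += 1
    values = np.full(N_BINS, np.nan)
    mask = counts > 0
    values[mask] = sums[mask] / counts[mask]
    return BinnedTrajectory(session.session_id, sentiment, values)


def aggregate(trajectories: Sequence[BinnedTrajectory]) -> BinAggregate:
    """Per-bin mean and SEM over the non-missing values across sessions.

    SEM uses the sample standard deviation (ddof=1) divided by sqrt(n); for a
    single contributor it is defined as 0. Bins with zero contributors stay
    NaN and are excluded from any subsequent fit.
    """
    if len(trajectories) == 0:
        raise ValueError("aggregate requires at least one trajectory")
    stacked = np.vstack([t.bin_values for t in trajectories])
    present = ~np.isnan(stacked)
    n = present.sum(axis=0)
    mean = np.full(N_BINS, np.nan)
    sem = np.full(N_BINS, np.nan)
    any_mask = n > 0
    with np.errstate(invalid="ignore"):
        mean[any_mask] = np.nanmean(stacked[:, any_mask], axis=0)
    multi = n > 1
    if multi.any():
        sd = np.nanstd(stacked[:, multi], axis=0, ddof=1)
        sem[multi] = sd / np.sqrt(n[multi])
    sem[n == 1] = 0.0
    sentiment = trajectories[0].sentiment
    return BinAggregate(sentiment, mean, sem, n, n_sessions=len(trajectories))


def fit_trend(agg: BinAggregate, weight_by_n: bool = False) -> TrendFit:
    """OLS of per-bin mean score against bin center.

    The default is unweighted (every populated bin counts equally); with
    ``weight_by_n`` each bin is weighted by its contributor count (WLS).
    The p-value is the two-tailed t-test on the slope.
    """
    mask = ~np.isnan(agg.mean)
    x = BIN_CENTERS[mask]
    y = agg.mean[mask]
    if x.size < 2 or np.unique(x).size < 2:
        raise ValueError("trend fit requires >= 2 populated bins with distinct centers")
    if np.ptp(y) == 0:
        # constant response: flat line, no explained variance (R^2 = 0)
        return TrendFit(0.0, float(y[0]), 0.0, 1.0, 0.0, int(x.size))
    if not weight_by_n:
        res = stats.linregress(x, y)
        return TrendFit(
            slope=float(res.slope),
            intercept=float(res.intercept),
            r_squared=float(res.rvalue**2),
            p_value=float(res.pvalue),
            stderr=float(res.stderr),
            n_bins=int(x.size),
        )
    import statsmodels.api as sm

    X = sm.add_constant(x)
    fit = sm.WLS(y, X, weights=agg.n[mask]).fit()
    return TrendFit(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        p_value=float(fit.pvalues[1]),
        stderr=float(fit.bse[1]),
        n_bins=int(x.size),
    )


def improvement_percent(fit: TrendFit) -> float:
    """Relative fitted change over one full session, in percent.

    |y(1) - y(0)| / y(0) x 100 = |slope| / intercept x 100. Requires a
    positive fitted intercept (scores live on a positive 1-10 scale).
    """
    if fit.intercept <= 0:
        raise ValueError("improvement percent requires a positive intercept")
    return abs(fit.slope) / fit.intercept * 100.0


def trend(
    sessions: Iterable[ChatSession],
    sentiment: str,
    threshold: float = THRESHOLD,
    weight_by_n: bool = False,
    pre_filtered: bool = False,
) -> AggregateTrend:
    """Full chain for one sentiment: inclusion filter -> bin -> aggregate -> fit.

    Set ``pre_filtered`` when the sessions already passed inclusion filtering.
    """
    sessions = list(sessions)
    if not pre_filtered:
        sessions, _ = filter_corpus(sessions, sentiment, threshold)
    if not sessions:
        raise ValueError(f"no sessions included for sentiment {sentiment!r}")
    trajs = [normalize_session(s, sentiment) for s in sessions]
    agg = aggregate(trajs)
    fit = fit_trend(agg, weight_by_n=weight_by_n)
    return AggregateTrend(
        sentiment=sentiment,
        aggregate=agg,
        fit=fit,
        n_sessions=len(sessions),
        improvement_pct=improvement_percent(fit),
    )


# -- export / plotting ------------------------------------------------------


def export_trend(result: AggregateTrend, csv_path=None, json_path=None) -> None:
    """Write the per-bin table (CSV) and/or the fit summary (JSON)."""
    if csv_path is not None:
        result.aggregate.frame().to_csv(csv_path, index=False)
    if json_path is not None:
        with open(json_path, "w", encoding="utf-8") as fh:
            json.dump(result.summary(), fh, indent=2)


def plot_trend(result: AggregateTrend, ax=None, color: Optional[str] = None):
    """Band plot: per-bin means, +/-1 SEM shading, and the fitted line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    mask = ~np.isnan(result.aggregate.mean)
    x = BIN_CENTERS[mask]
    m = result.aggregate.mean[mask]
    s = result.aggregate.sem[mask]
    ax.plot(x, m, color=color or "black", lw=1, label="per-bin mean")
    ax.fill_between(x, m - s, m + s, alpha=0.3, color=color or "gray")
    ax.plot(
        x,
        result.fit.intercept + result.fit.slope * x,
        "--",
        color=color or "black",
        label=(
            f"fit: slope={result.fit.slope:.2f}, "
            f"b0={result.fit.intercept:.2f}, R2={result.fit.r_squared:.3f}"
        ),
    )
    ax.set_xlabel("normalized session time")
    ax.set_ylabel(f"{result.sentiment} score (1-10)")
    ax.set_ylim(1, 10)
    ax.legend(fontsize=8)
    return ax
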