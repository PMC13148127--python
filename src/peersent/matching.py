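"""Propensity-score matching between session cohorts.

Cohort membership (e.g. within vs outside business hours, resource received
vs not) is modeled with an unpenalized logistic regression on session
covariates: primary struggle topic, device, country, participant count,
binned conversation duration, binned engagement rate, and the initial
sentiment score. Sessions are then paired greedily, one nearest neighbor
without replacement, within a caliper equal to 25% of the pooled standard
deviation of all propensity scores. Covariate balance is diagnosed with
standardized mean differences (SMD) before and after matching.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .inclusion import initial_state
from .sessions import DEVICES, TOPICS, ChatSession, engagement_rate

#: Conversation-duration bins in minutes (half-open, last open-ended).
DURATION_EDGES = (0.0, 5.0, 10.0, 20.0, 45.0, 60.0)
DURATION_LABELS = ("0-5", "5-10", "10-20", "20-45", "45-60", ">60")

#: Engagement-rate bins in characters per minute.
ENGAGEMENT_EDGES = (0.0, 10.0, 20.0, 30.0, 40.0, 50.0)
ENGAGEMENT_LABELS = ("0-10", "10-20", "20-30", "30-40", "40-50", ">50")

#: Caliper as a fraction of the pooled propensity-score SD.
DEFAULT_CALIPER_FRACTION = 0.25

#: Country levels rarer than this are collapsed into "other".
DEFAULT_MIN_COUNTRY_COUNT = 10


def _bin(value: float, edges: Sequence[float], labels: Sequence[str], what: str) -> str:
    if value < 0:
        raise ValueError(f"{what} must be >= 0, got {value}")
    for i in range(len(edges) - 1):
        if edges[i] <= value < edges[i + 1]:
            return labels[i]
    return labels[-1]


def bin_duration(minutes: float) -> str:
    """Categorize a conversation duration; intervals are half-open [lo, hi)."""
    return _bin(minutes, DURATION_EDGES, DURATION_LABELS, "duration")


def bin_engagement(rate: float) -> str:
    """Categorize an engagement rate (chars/min); intervals half-open [lo, hi)."""
    return _bin(rate, ENGAGEMENT_EDGES, ENGAGEMENT_LABELS, "engagement rate")


def build_features(
    sessions: Sequence[ChatSession],
    sentiment: str,
    min_country_count: int = DEFAULT_MIN_COUNTRY_COUNT,
    country_levels: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Feature matrix for the propensity model, indexed by session_id.

    One-hot blocks for topic (the session's primary struggle), device,
    country (rare levels collapsed to "other"), duration bin and engagement
    bin; numeric participant count and initial sentiment score. Raises if a
    session lacks an initial score for the target sentiment (filter first).
    """
    rows = []
    ids = []
    countries = pd.Series([s.country for s in sessions])
    if country_levels is None:
        counts = countries.value_counts()
        keep = set(counts[counts >= min_country_count].index)
    else:
        keep = set(country_levels)
    for s in sessions:
        init = initial_state(s, sentiment)
        if init is None:
            raise ValueError(
                f"session {s.session_id} has no initial {sentiment} score; "
                "apply inclusion filtering before matching"
            )
        rows.append(
            {
                "topic": s.topics[0],
                "device": s.device,
                "country": s.country if s.country in keep else "other",
                "duration_bin": bin_duration(s.duration_min),
                "engagement_bin": bin_engagement(engagement_rate(s)),
                "participant_count": s.participant_count,
                "initial_score": init,
            }
        )
        ids.append(s.session_id)
    raw = pd.DataFrame(rows, index=ids)
    blocks = [raw[["participant_count", "initial_score"]].astype(float)]
    categorical = {
        "topic": list(TOPICS),
        "device": list(DEVICES),
        "duration_bin": list(DURATION_LABELS),
        "engagement_bin": list(ENGAGEMENT_LABELS),
        "country": sorted(set(raw["country"])),
    }
    for col, levels in categorical.items():
        cat = pd.Categorical(raw[col], categories=levels)
        dummies = pd.get_dummies(cat, prefix=col, dtype=float)
        dummies.index = raw.index
        blocks.append(dummies)
    return pd.concat(blocks, axis=1)


@dataclass(slots=True)
class PropensityModel:
    """Fitted propensity model: one score in (0, 1) per session."""

    scores_a: pd.Series
    scores_b: pd.Series
    coefficients: pd.Series
    intercept: float
    dropped_columns: list[str]
    separation_flag: bool

    @property
    def scores(self) -> pd.Series:
        return pd.concat([self.scores_a, self.scores_b])


def _fit_logistic(X: np.ndarray, y: np.ndarray, tol: float = 1e-8) -> tuple[np.ndarray, float]:
    """Unpenalized logistic fit; returns (coefficients, intercept)."""
    model = LogisticRegression(C=np.inf, solver="lbfgs", tol=tol, max_iter=10000)
    model.fit(X, y)
    return model.coef_[0], float(model.intercept_[0])


def fit_propensity(
    cohort_a: Sequence[ChatSession],
    cohort_b: Sequence[ChatSession],
    sentiment: str,
    min_country_count: int = DEFAULT_MIN_COUNTRY_COUNT,
    tol: float = 1e-8,
) -> PropensityModel:
    """Logistic regression of cohort membership (A = 1) on session features.

    Constant feature columns are dropped with a warning; one reference level
    per one-hot block is dropped so the unpenalized fit is identifiable.
    Near-perfect separation is flagged. Deterministic given the data.
    """
    if len(cohort_a) == 0 or len(cohort_b) == 0:
        raise ValueError("both cohorts must be nonempty")
    sessions = list(cohort_a) + list(cohort_b)
    features = build_features(sessions, sentiment, min_country_count=min_country_count)
    y = np.concatenate([np.ones(len(cohort_a)), np.zeros(len(cohort_b))])

    dropped: list[str] = []
    cols = []
    seen_blocks: set[str] = set()
    for col in features.columns:
        is_onehot = any(
            col.startswith(p + "_")
            for p in ("topic", "device", "country", "duration_bin", "engagement_bin")
        )
        if features[col].nunique() <= 1:
            dropped.append(col)
            continue
        if is_onehot:
            prefix = next(
                p
                for p in ("duration_bin", "engagement_bin", "topic", "device", "country")
                if col.startswith(p + "_")
            )
            if prefix not in seen_blocks:
                seen_blocks.add(prefix)  # reference level for the block
                dropped.append(col)
                continue
        cols.append(col)
    if dropped:
        warnings.warn(f"dropped feature columns: {dropped}", stacklevel=2)
    X = features[cols].to_numpy(dtype=float)
    coef, intercept = _fit_logistic(X, y, tol=tol)
    probs = 1.0 / (1.0 + np.exp(-(X @ coef + intercept)))
    separated = bool(np.all((probs > 0.999) == (y == 1)) and np.all((probs < 0.001) == (y == 0)))
    if separated:
        warnings.warn("near-perfect separation between cohorts", stacklevel=2)
    ids = [s.session_id for s in sessions]
    scores = pd.Series(probs, index=ids)
    return PropensityModel(
        scores_a=scores.iloc[: len(cohort_a)],
        scores_b=scores.iloc[len(cohort_a):],
        coefficients=pd.Series(coef, index=cols),
        intercept=intercept,
        dropped_columns=dropped,
        separation_flag=separated,
    )


@dataclass(slots=True)
class MatchResult:
    caliper: float
    pairs: list[tuple[str, str, float]]  # (treated_id, control_id, |score gap|)
    unmatched_treated: list[str]
    scores_a: pd.Series
    scores_b: pd.Series
    balance: Optional[pd.DataFrame] = None

    @property
    def matched_a(self) -> list[str]:
        a_first = set(self.scores_a.index)
        return [t if t in a_first else c for t, c, _ in self.pairs]

    def pair_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairs, columns=["treated_id", "control_id", "score_distance"])


def match(
    scores_a: Mapping[str, float] | pd.Series,
    scores_b: Mapping[str, float] | pd.Series,
    caliper_fraction: float = DEFAULT_CALIPER_FRACTION,
) -> MatchResult:
    """Greedy 1-nearest-neighbor matching without replacement within a caliper.

    The caliper is ``caliper_fraction`` x the SD of all scores, both cohorts
    pooled. Sessions of the smaller cohort are visited in ascending
    session_id order; each is paired with the nearest unused score in the
    other cohort if the gap is within the caliper, ties broken toward the
    lower session_id. Controls are used at most once.
    """
    if caliper_fraction <= 0:
        raise ValueError("caliper_fraction must be > 0")
    sa = pd.Series(dict(scores_a)) if not isinstance(scores_a, pd.Series) else scores_a
    sb = pd.Series(dict(scores_b)) if not isinstance(scores_b, pd.Series) else scores_b
    if sa.empty or sb.empty:
        raise ValueError("both cohorts must be nonempty")
    pooled_sd = float(np.concatenate([sa.to_numpy(), sb.to_numpy()]).std(ddof=1))
    caliper = caliper_fraction * pooled_sd

    treated, control = (sa, sb) if len(sa) <= len(sb) else (sb, sa)
    treated = treated.sort_index()
    control = control.sort_index()
    c_ids = np.array(control.index)
    c_scores = control.to_numpy(dtype=float)
    used = np.zeros(len(control), dtype=bool)

    pairs: list[tuple[str, str, float]] = []
    unmatched: list[str] = []
    for t_id, t_score in treated.items():
        gaps = np.abs(c_scores - t_score)
        gaps[used] = np.inf
        best = np.inf
        best_i = -1
        for i in np.flatnonzero(gaps <= caliper):
            # strict < keeps the first (lowest id, index is sorted) on ties
            if gaps[i] < best:
                best = gaps[i]
                best_i = i
        if best_i >= 0:
            used[best_i] = True
            pairs.append((str(t_id), str(c_ids[best_i]), float(best)))
        else:
            unmatched.append(str(t_id))
    return MatchResult(
        caliper=caliper,
        pairs=pairs,
        unmatched_treated=unmatched,
        scores_a=sa,
        scores_b=sb,
    )


def standardized_mean_differences(
    features_a: pd.DataFrame, features_b: pd.DataFrame
) -> pd.Series:
    """Per-column SMD = (mean_A - mean_B) / pooled SD; 0 where the pooled SD is 0."""
    ma, mb = features_a.mean(), features_b.mean()
    va, vb = features_a.var(ddof=1), features_b.var(ddof=1)
    pooled = np.sqrt((va + vb) / 2.0)
    smd = (ma - mb) / pooled
    smd[pooled == 0] = 0.0
    return smd.fillna(0.0)


def balance_diagnostics(
    result: MatchResult,
    cohort_a: Sequence[ChatSession],
    cohort_b: Sequence[ChatSession],
    sentiment: str,
    min_country_count: int = DEFAULT_MIN_COUNTRY_COUNT,
) -> pd.DataFrame:
    """SMD per feature before and after matching.

    Returns a DataFrame indexed by feature with columns ``smd_before`` and
    ``smd_after`` and stores it on ``result.balance``.
    """
    if not result.pairs:
        raise ValueError("balance diagnostics require at least one matched pair")
    fa = build_features(list(cohort_a), sentiment, min_country_count=min_country_count)
    fb = build_features(list(cohort_b), sentiment, min_country_count=min_country_count)
    fb = fb.reindex(columns=fa.columns, fill_value=0.0)
    a_ids = set(fa.index)
    matched_a = [t if t in a_ids else c for t, c, _ in result.pairs]
    matched_b = [c if t in a_ids else t for t, c, _ in result.pairs]
    before = standardized_mean_differences(fa, fb)
    after = standardized_mean_differences(fa.loc[matched_a], fb.loc[matched_b])
    table = pd.DataFrame({"smd_before": before, "smd_after": after})
    result.balance = table
    return table


def match_cohorts(
    cohort_a: Sequence[ChatSession],
    cohort_b: Sequence[ChatSession],
    sentiment: str,
    caliper_fraction: float = DEFAULT_CALIPER_FRACTION,
    min_country_count: int = DEFAULT_MIN_COUNTRY_COUNT,
) -> tuple[MatchResult, list[ChatSession], list[ChatSession]]:
    """Convenience chain: fit propensity, match, diagnose balance.

    Returns the match result plus the matched subsets of each cohort (pair
    order preserved).
    """
    model = fit_propensity(cohort_a, cohort_b, sentiment, min_country_count=min_country_count)
    result = match(model.scores_a, model.scores_b, caliper_fraction=caliper_fraction)
    balance_diagnostics(result, cohort_a, cohort_b, sentiment, min_country_count)
    by_id_a = {s.session_id: s for s in cohort_a}
    by_id_b = {s.session_id: s for s in cohort_b}
    matched_a = []
    matched_b = []
    for t, c, _ in result.pairs:
        if t in by_id_a:
            matched_a.append(by_id_a[t])
            matched_b.append(by_id_b[c])
        else:
            matched_a.append(by_id_a[c])
            matched_b.append(by_id_b[t])
    return result, matched_a, matched_b
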