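"""Descriptive tabulations: topics, EAP flows, resources, demographics, activity.

Sessions may carry several struggle topics; every topic-keyed table counts a
session once per topic, so column totals may exceed the session count.
Displayed percentages are rounded half-up to two decimals.
"""

from __future__ import annotations

import json
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Callable, Iterable, Sequence

import pandas as pd

from .compare import compare_metric, percent_difference
from .sessions import (
    TOPICS,
    ChatSession,
    engagement_rate,
    is_business_hours,
)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (table display convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def topic_distribution(sessions: Sequence[ChatSession]) -> pd.DataFrame:
    """Per-topic session counts and percent of total sessions (multi-label)."""
    total = len(sessions)
    counts = {t: 0 for t in TOPICS}
    for s in sessions:
        for t in set(s.topics):
            counts[t] += 1
    rows = [
        {
            "topic": t,
            "count": c,
            "percent": round_half_up(c / total * 100) if total else 0.0,
        }
        for t, c in counts.items()
    ]
    return (
        pd.DataFrame(rows)
        .sort_values("count", ascending=False, kind="stable")
        .reset_index(drop=True)
    )


def eap_flow_table(sessions: Sequence[ChatSession], direction: str) -> pd.DataFrame:
    """EAP inflow/outflow counts per struggle topic, sorted by percent.

    ``direction`` is "inflow" (sessions entered via an EAP referral) or
    "outflow" (sessions referred onward to EAP services). Per topic the
    percent is flagged/total x 100; a final "overall" row holds grand totals.
    """
    if direction not in ("inflow", "outflow"):
        raise ValueError(f"direction must be 'inflow' or 'outflow', got {direction!r}")
    flag = (lambda s: s.eap_inflow) if direction == "inflow" else (lambda s: s.eap_outflow)
    totals = {t: 0 for t in TOPICS}
    flagged = {t: 0 for t in TOPICS}
    grand_flagged = 0
    for s in sessions:
        f = flag(s)
        grand_flagged += int(f)
        for t in set(s.topics):
            totals[t] += 1
            flagged[t] += int(f)
    rows = [
        {
            "topic": t,
            "total_count": totals[t],
            "flagged_count": flagged[t],
            "percent": round_half_up(flagged[t] / totals[t] * 100) if totals[t] else 0.0,
        }
        for t in TOPICS
    ]
    table = (
        pd.DataFrame(rows)
        .sort_values("percent", ascending=False, kind="stable")
        .reset_index(drop=True)
    )
    n = len(sessions)
    overall = pd.DataFrame(
        [
            {
                "topic": "overall",
                "total_count": n,
                "flagged_count": grand_flagged,
                "percent": round_half_up(grand_flagged / n * 100) if n else 0.0,
            }
        ]
    )
    return pd.concat([table, overall], ignore_index=True)


def resource_table(sessions: Sequence[ChatSession]) -> tuple[pd.DataFrame, float]:
    """Resource-type x topic counts plus the per-session average.

    A resource counts once per topic of its session; the average is total
    resources over total sessions (not per topic).
    """
    from .sessions import RESOURCE_TYPES

    counts = pd.DataFrame(0, index=list(TOPICS), columns=list(RESOURCE_TYPES))
    total_resources = 0
    for s in sessions:
        total_resources += len(s.resources)
        for r in s.resources:
            for t in set(s.topics):
                counts.loc[t, r.resource_type] += 1
    counts["count"] = counts.sum(axis=1)
    average = total_resources / len(sessions) if sessions else 0.0
    return counts, average


def activity_histogram(sessions: Sequence[ChatSession]) -> tuple[pd.Series, dict]:
    """Hourly start-time counts and the business-hours cohort split."""
    hours = pd.Series(0, index=range(24), name="sessions")
    within = 0
    for s in sessions:
        hours[s.local_start.hour] += 1
        within += int(is_business_hours(s.local_start))
    n = len(sessions)
    cohorts = {
        "within": within,
        "outside": n - within,
        "outside_share_pct": round_half_up((n - within) / n * 100) if n else 0.0,
    }
    return hours, cohorts


def demographics_summary(sessions: Sequence[ChatSession]) -> dict:
    """Gender/race/age distributions among disclosing sessions.

    Percentages are computed over disclosures only; the disclosure rate over
    all sessions is reported separately.
    """
    disclosing = [s for s in sessions if s.demographics is not None]
    n_total = len(sessions)
    n_disc = len(disclosing)
    out: dict = {
        "n_sessions": n_total,
        "n_disclosing": n_disc,
        "disclosure_rate_pct": round_half_up(n_disc / n_total * 100) if n_total else 0.0,
    }
    if not disclosing:
        out["gender"] = pd.DataFrame(columns=["count", "percent"])
        out["race"] = pd.DataFrame(columns=["count", "percent"])
        out["age_median"] = None
        return out
    for field in ("gender", "race"):
        values = pd.Series([getattr(s.demographics, field) for s in disclosing])
        counts = values.value_counts()
        out[field] = pd.DataFrame(
            {
                "count": counts,
                "percent": [round_half_up(c / n_disc * 100) for c in counts],
            }
        )
    ages = pd.Series([s.demographics.age for s in disclosing])
    out["age_median"] = float(ages.median())
    out["age_mean"] = float(ages.mean())
    return out


_ENGAGEMENT_METRICS: dict[str, Callable[[ChatSession], float]] = {
    "duration_min": lambda s: s.duration_min,
    "n_messages": lambda s: s.n_user_messages,
    "n_chars": lambda s: s.n_user_chars,
    "chars_per_min": engagement_rate,
    "n_topics": lambda s: len(s.topics),
}


def engagement_summary(
    sessions: Iterable[ChatSession],
    cohort_fn: Callable[[ChatSession], bool] = lambda s: is_business_hours(s.local_start),
    labels: tuple[str, str] = ("within", "outside"),
) -> pd.DataFrame:
    """Per-cohort engagement metrics with Welch p-values.

    ``cohort_fn`` maps a session to True for the first cohort. For each of
    duration, messages, characters, chars/min and topic count the table holds
    the two cohort means/SDs, the percent excess of the larger mean over the
    smaller, and the two-tailed Welch p.
    """
    group_a, group_b = [], []
    for s in sessions:
        (group_a if cohort_fn(s) else group_b).append(s)
    if not group_a or not group_b:
        raise ValueError("both cohorts must be nonempty")
    rows = []
    for name, fn in _ENGAGEMENT_METRICS.items():
        va = [fn(s) for s in group_a]
        vb = [fn(s) for s in group_b]
        comp = compare_metric(va, vb, metric=name)
        hi, lo = (comp.mean_a, comp.mean_b) if comp.mean_a >= comp.mean_b else (comp.mean_b, comp.mean_a)
        rows.append(
            {
                "metric": name,
                f"mean_{labels[0]}": comp.mean_a,
                f"sd_{labels[0]}": comp.sd_a,
                f"mean_{labels[1]}": comp.mean_b,
                f"sd_{labels[1]}": comp.sd_b,
                "larger_cohort": labels[0] if comp.mean_a >= comp.mean_b else labels[1],
                "percent_difference": percent_difference(hi, lo),
                "p_value": comp.p_value,
            }
        )
    return pd.DataFrame(rows)


def write_report(sessions: Sequence[ChatSession], outdir) -> dict:
    """Emit the full descriptive table set as CSVs plus a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"n_sessions": len(sessions), "tables": {}}

    topic_distribution(sessions).to_csv(outdir / "topic_distribution.csv", index=False)
    manifest["tables"]["topic_distribution"] = "topic_distribution.csv"
    for direction in ("inflow", "outflow"):
        eap_flow_table(sessions, direction).to_csv(
            outdir / f"eap_{direction}.csv", index=False
        )
        manifest["tables"][f"eap_{direction}"] = f"eap_{direction}.csv"
    resources, avg = resource_table(sessions)
    resources.to_csv(outdir / "resources.csv", index_label="topic")
    manifest["tables"]["resources"] = "resources.csv"
    manifest["resources_per_session"] = round_half_up(avg)
    hours, cohorts = activity_histogram(sessions)
    hours.to_csv(outdir / "activity_histogram.csv", index_label="hour")
    manifest["tables"]["activity_histogram"] = "activity_histogram.csv"
    manifest["cohorts"] = cohorts
    demo = demographics_summary(sessions)
    for fld in ("gender", "race"):
        demo[fld].to_csv(outdir / f"demographics_{fld}.csv", index_label=fld)
        manifest["tables"][f"demographics_{fld}"] = f"demographics_{fld}.csv"
    manifest["disclosure_rate_pct"] = demo["disclosure_rate_pct"]
    try:
        engagement_summary(sessions).to_csv(outdir / "engagement_summary.csv", index=False)
        manifest["tables"]["engagement_summary"] = "engagement_summary.csv"
    except ValueError:
        pass  # single-cohort corpus
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
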