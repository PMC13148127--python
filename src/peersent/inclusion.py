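"""Session inclusion rules for sentiment-trend analysis.

A session enters the analysis of a given sentiment only if the user sent at
least three messages and opened the conversation in a sufficiently intense
emotional state: the *initial state* is the highest score for that sentiment
over the user's first three messages (users often warm up with brief
exchanges before expressing their struggle, so the maximum rather than the
first score is used). Negative sentiments require an initial state strictly
above 5 on the 1-10 scale; optimism requires strictly below 5. An initial
state of exactly 5 is excluded in both directions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .sessions import ChatSession, polarity

#: Default inclusion threshold on the 1-10 intensity scale.
THRESHOLD = 5.0

#: Number of opening user messages that define the initial emotional state.
INITIAL_WINDOW = 3

#: Minimum number of primary-user messages for a session to be analyzable.
MIN_USER_MESSAGES = 3

REASONS = ("ok", "too_few_messages", "no_scored_messages", "below_threshold", "above_threshold")


@dataclass(frozen=True, slots=True)
class InclusionDecision:
    session_id: str
    sentiment: str
    included: bool
    initial_score: Optional[float]
    reason: str


def initial_state(session: ChatSession, sentiment: str) -> Optional[float]:
    """Highest score for ``sentiment`` over the user's first 3 messages.

    Returns None if none of those messages carries a score for the sentiment.
    Later messages are ignored by design: the initial state describes how the
    user entered the conversation.
    """
    polarity(sentiment)  # validates label
    first = session.primary_user_messages()[:INITIAL_WINDOW]
    values = [m.scores[sentiment] for m in first if sentiment in m.scores]
    return max(values) if values else None


def include_session(
    session: ChatSession, sentiment: str, threshold: float = THRESHOLD
) -> InclusionDecision:
    """Apply the inclusion rule for one session x sentiment.

    Checks, in order: enough user messages; an initial state exists; the
    initial state clears the threshold in the direction required by the
    sentiment's polarity (strict inequalities; exactly ``threshold`` is
    excluded for both polarities).
    """
    pol = polarity(sentiment)
    if session.n_user_messages < MIN_USER_MESSAGES:
        return InclusionDecision(session.session_id, sentiment, False, None, "too_few_messages")
    init = initial_state(session, sentiment)
    if init is None:
        return InclusionDecision(session.session_id, sentiment, False, None, "no_scored_messages")
    if pol == "negative":
        if init > threshold:
            return InclusionDecision(session.session_id, sentiment, True, init, "ok")
        return InclusionDecision(session.session_id, sentiment, False, init, "below_threshold")
    # positive (optimism): needs room to improve upward
    if init < threshold:
        return InclusionDecision(session.session_id, sentiment, True, init, "ok")
    return InclusionDecision(session.session_id, sentiment, False, init, "above_threshold")


def filter_corpus(
    sessions: Iterable[ChatSession], sentiment: str, threshold: float = THRESHOLD
) -> tuple[list[ChatSession], list[InclusionDecision]]:
    """Partition a corpus into included sessions plus a full decision log.

    Every input session appears in the log exactly once; the included subset
    preserves input order.
    """
    included: list[ChatSession] = []
    log: list[InclusionDecision] = []
    for s in sessions:
        d = include_session(s, sentiment, threshold)
        log.append(d)
        if d.included:
            included.append(s)
    return included, log


def decisions_frame(decisions: Sequence[InclusionDecision]) -> pd.DataFrame:
    """Decision log as a DataFrame (CSV-ready)."""
    return pd.DataFrame(
        [
            {
                "session_id": d.session_id,
                "sentiment": d.sentiment,
                "included": d.included,
                "initial_score": d.initial_score,
                "reason": d.reason,
            }
            for d in decisions
        ],
        columns=["session_id", "sentiment", "included", "initial_score", "reason"],
    )
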