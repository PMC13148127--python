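import datetime as dt

import pytest

from peersent.sessions import ChatSession, Message, Resource


def build_session(
    scores,
    sentiment="stress",
    session_id="s1",
    duration=10.0,
    times=None,
    roles=None,
    char_counts=None,
    topics=("stress",),
    local_start=dt.datetime(2024, 1, 2, 10, 0),  # Tuesday morning
    resources=(),
    **kwargs,
):
    """Build a session from a list of per-message scores.

    Each entry of ``scores`` is a float (score for ``sentiment``), a dict
    (scores for several sentiments) or None (unscored message).
    """
    n = len(scores)
    if times is None:
        times = [duration * i / max(n - 1, 1) for i in range(n)]
    roles = roles or ["primary_user"] * n
    char_counts = char_counts or [50] * n
    messages = []
    for i, sc in enumerate(scores):
        if sc is None:
            smap = {}
        elif isinstance(sc, dict):
            smap = dict(sc)
        else:
            smap = {sentiment: float(sc)}
        messages.append(
            Message(
                index=i,
                time_offset_min=float(times[i]),
                author_role=roles[i],
                char_count=char_counts[i],
                scores=smap,
            )
        )
    return ChatSession(
        session_id=session_id,
        employer_id="employer_1",
        local_start=local_start,
        duration_min=float(duration),
        messages=messages,
        topics=tuple(topics),
        resources=[Resource(*r) if not isinstance(r, Resource) else r for r in resources],
        **kwargs,
    )


@pytest.fixture
def make_session():
    return build_session
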