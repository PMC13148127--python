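"""Session data model, JSONL serialization, and per-session derived attributes.

A *session* is one user's participation in one moderated peer-support chat:
an ordered list of messages (only the focal user's messages carry sentiment
scores), plus covariates used downstream for cohort construction and
propensity matching. Eight sentiments are tracked per message on a 1-10
intensity scale: seven negative dimensions and one positive (optimism).
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import pandas as pd

#: The eight tracked sentiment dimensions. The first seven are negative
#: (high score = high distress); optimism is positive (high score = hopeful).
SENTIMENTS: tuple[str, ...] = (
    "loneliness",
    "sadness",
    "stress",
    "anxiety",
    "depression",
    "despair",
    "helplessness",
    "optimism",
)

NEGATIVE_SENTIMENTS: frozenset[str] = frozenset(SENTIMENTS[:7])
POSITIVE_SENTIMENTS: frozenset[str] = frozenset({"optimism"})

#: The 14 struggle-topic categories a session may be tagged with.
TOPICS: tuple[str, ...] = (
    "anxiety",
    "caregiving_parenting",
    "depression",
    "financial_sdoh",
    "identity",
    "loneliness",
    "mental_health_conditions",
    "physical_health_medical",
    "relationship_issues",
    "social_connection_belonging",
    "stress",
    "suicide_self_harm",
    "trauma",
    "work_productivity_burnout",
)

DEVICES: tuple[str, ...] = ("mobile", "desktop", "tablet")
ROLES: tuple[str, ...] = ("primary_user", "peer", "moderator")
RESOURCE_TYPES: tuple[str, ...] = (
    "blog",
    "video",
    "employee_specific",
    "worksheet",
    "quote",
    "audio",
)
GENDERS: tuple[str, ...] = ("female", "male", "nonbinary")

SCHEMA_NAME = "peersent-sessions"
SCHEMA_VERSION = 1


class ValidationError(ValueError):
    """A record violates the session schema.

    Carries the offending ``field`` and, when raised during file parsing,
    the 1-based ``line`` number of the bad record.
    """

    def __init__(self, message: str, *, field: str = "", line: Optional[int] = None):
        self.field = field
        self.line = line
        prefix = f"line {line}: " if line is not None else ""
        super().__init__(f"{prefix}{message}")


def polarity(sentiment: str) -> str:
    """Return ``"negative"`` or ``"positive"`` for a sentiment label."""
    if sentiment in NEGATIVE_SENTIMENTS:
        return "negative"
    if sentiment in POSITIVE_SENTIMENTS:
        return "positive"
    raise ValidationError(f"unknown sentiment {sentiment!r}", field="sentiment")


@dataclass(slots=True)
class Message:
    """One chat message.

    ``scores`` is a partial map sentiment -> intensity in [1, 10]; a missing
    entry means the message was not scored for that sentiment (e.g. a
    clarifying or off-topic remark).
    """

    index: int
    time_offset_min: float
    author_role: str
    char_count: int
    scores: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if self.author_role not in ROLES:
            raise ValidationError(
                f"author_role {self.author_role!r} not in {ROLES}", field="author_role"
            )
        if self.time_offset_min < 0:
            raise ValidationError("time_offset_min must be >= 0", field="time_offset_min")
        if self.char_count < 0:
            raise ValidationError("char_count must be >= 0", field="char_count")
        for name, value in self.scores.items():
            if name not in SENTIMENTS:
                raise ValidationError(f"unknown sentiment {name!r}", field="scores")
            if not (1.0 <= value <= 10.0):
                raise ValidationError(
                    f"score {value} for {name!r} outside [1, 10]", field="scores"
                )


@dataclass(slots=True)
class Resource:
    """A resource shared in-session (type + share time in minutes)."""

    resource_type: str
    time_offset_min: float

    def validate(self) -> None:
        if self.resource_type not in RESOURCE_TYPES:
            raise ValidationError(
                f"resource_type {self.resource_type!r} not in {RESOURCE_TYPES}",
                field="resource_type",
            )


@dataclass(slots=True)
class Demographics:
    age: int
    gender: str
    race: str

    def validate(self) -> None:
        if self.gender not in GENDERS:
            raise ValidationError(f"gender {self.gender!r} not in {GENDERS}", field="gender")
        if not (0 < self.age < 130):
            raise ValidationError(f"implausible age {self.age}", field="age")


@dataclass(slots=True)
class ChatSession:
    """One user-chat session with covariates and flags.

    ``topics`` is an ordered tuple of struggle topics; the first entry is the
    primary struggle the user entered with and is the one used as the
    session's topic feature in propensity matching.
    """

    session_id: str
    employer_id: str
    local_start: _dt.datetime
    duration_min: float
    messages: list[Message] = field(default_factory=list)
    topics: tuple[str, ...] = ()
    device: str = "mobile"
    country: str = "US"
    participant_count: int = 1
    resources: list[Resource] = field(default_factory=list)
    eap_inflow: bool = False
    eap_outflow: bool = False
    demographics: Optional[Demographics] = None

    def validate(self) -> None:
        if self.duration_min <= 0:
            raise ValidationError("duration_min must be > 0", field="duration_min")
        if not self.topics:
            raise ValidationError("topics must be nonempty", field="topics")
        for t in self.topics:
            if t not in TOPICS:
                raise ValidationError(f"unknown topic {t!r}", field="topics")
        if self.device not in DEVICES:
            raise ValidationError(f"device {self.device!r} not in {DEVICES}", field="device")
        if not (1 <= self.participant_count <= 5):
            raise ValidationError(
                "participant_count must be in [1, 5]", field="participant_count"
            )
        prev = 0.0
        for m in self.messages:
            m.validate()
            if m.time_offset_min < prev:
                raise ValidationError(
                    "message time offsets must be nondecreasing", field="time_offset_min"
                )
            prev = m.time_offset_min
        for r in self.resources:
            r.validate()
        if self.demographics is not None:
            self.demographics.validate()

    # -- derived attributes -------------------------------------------------

    def primary_user_messages(self) -> list[Message]:
        return [m for m in self.messages if m.author_role == "primary_user"]

    @property
    def n_user_messages(self) -> int:
        return len(self.primary_user_messages())

    @property
    def n_user_chars(self) -> int:
        return sum(m.char_count for m in self.primary_user_messages())


def engagement_rate(session: ChatSession) -> float:
    """Characters typed by the primary user per minute of conversation."""
    if session.duration_min <= 0:
        raise ValidationError("duration_min must be > 0", field="duration_min")
    return session.n_user_chars / session.duration_min


def is_business_hours(local_start: _dt.datetime) -> bool:
    """True iff the session started Monday-Friday in [08:00, 17:00) local time.

    The interval is half-open so a 17:00 start counts as outside hours;
    classification uses the start time only.
    """
    if local_start.weekday() >= 5:
        return False
    t = local_start.time()
    return _dt.time(8, 0) <= t < _dt.time(17, 0)


COHORT_VARIABLES = ("business_hours", "resource_shared")


def split_cohorts(
    sessions: Iterable[ChatSession], variable: str = "business_hours"
) -> tuple[list[ChatSession], list[ChatSession], tuple[str, str]]:
    """Partition a corpus into the two cohorts of a study variable.

    For ``business_hours`` the cohorts are (within, outside) by session start
    time; for ``resource_shared`` they are (resource, no_resource) by whether
    at least one resource was shared in-session. Returns the two disjoint,
    exhaustive lists plus their labels.
    """
    if variable == "business_hours":
        key, labels = (lambda s: is_business_hours(s.local_start)), ("within", "outside")
    elif variable == "resource_shared":
        key, labels = (lambda s: len(s.resources) > 0), ("resource", "no_resource")
    else:
        raise ValueError(f"cohort variable must be one of {COHORT_VARIABLES}")
    first = [s for s in sessions if key(s)]
    second = [s for s in sessions if not key(s)]
    return first, second, labels


# -- serialization ----------------------------------------------------------


def _session_to_dict(s: ChatSession) -> dict:
    d = {
        "session_id": s.session_id,
        "employer_id": s.employer_id,
        "local_start": s.local_start.isoformat(),
        "duration_min": s.duration_min,
        "messages": [
            {
                "index": m.index,
                "time_offset_min": m.time_offset_min,
                "author_role": m.author_role,
                "char_count": m.char_count,
                "scores": m.scores,
            }
            for m in s.messages
        ],
        "topics": list(s.topics),
        "device": s.device,
        "country": s.country,
        "participant_count": s.participant_count,
        "resources": [
            {"resource_type": r.resource_type, "time_offset_min": r.time_offset_min}
            for r in s.resources
        ],
        "eap_inflow": s.eap_inflow,
        "eap_outflow": s.eap_outflow,
    }
    if s.demographics is not None:
        d["demographics"] = dataclasses.asdict(s.demographics)
    return d


def _session_from_dict(d: dict, line: Optional[int] = None) -> ChatSession:
    try:
        demo = d.get("demographics")
        session = ChatSession(
            session_id=d["session_id"],
            employer_id=d["employer_id"],
            local_start=_dt.datetime.fromisoformat(d["local_start"]),
            duration_min=d["duration_min"],
            messages=[Message(**m) for m in d["messages"]],
            topics=tuple(d["topics"]),
            device=d["device"],
            country=d["country"],
            participant_count=d["participant_count"],
            resources=[Resource(**r) for r in d.get("resources", [])],
            eap_inflow=d["eap_inflow"],
            eap_outflow=d["eap_outflow"],
            demographics=Demographics(**demo) if demo else None,
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ValidationError(f"malformed record: {exc}", field=str(exc), line=line) from exc
    try:
        session.validate()
    except ValidationError as exc:
        raise ValidationError(str(exc), field=exc.field, line=line) from exc
    return session


def write_sessions(sessions: Iterable[ChatSession], path) -> None:
    """Write a corpus as JSONL: a schema header line, then one session per line."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(json.dumps({"format": SCHEMA_NAME, "version": SCHEMA_VERSION}) + "\n")
        for s in sessions:
            fh.write(json.dumps(_session_to_dict(s), separators=(",", ":")) + "\n")


def iter_sessions(path) -> Iterator[ChatSession]:
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            raw = raw.strip()
            if not raw:
                continue
            try:
                d = json.loads(raw)
            except json.JSONDecodeError as exc:
                raise ValidationError(f"invalid JSON: {exc}", line=lineno) from exc
            if lineno == 1 and d.get("format") == SCHEMA_NAME:
                if d.get("version") != SCHEMA_VERSION:
                    raise ValidationError(
                        f"unsupported schema version {d.get('version')}",
                        field="version",
                        line=lineno,
                    )
                continue
            yield _session_from_dict(d, line=lineno)


def read_sessions(path) -> list[ChatSession]:
    """Read a JSONL corpus; an empty file yields an empty list."""
    return list(iter_sessions(path))


def session_metrics(sessions: Iterable[ChatSession]) -> pd.DataFrame:
    """Per-session derived metrics with stable column names."""
    rows = []
    for s in sessions:
        rows.append(
            {
                "session_id": s.session_id,
                "cohort": "within" if is_business_hours(s.local_start) else "outside",
                "duration_min": s.duration_min,
                "n_messages": s.n_user_messages,
                "n_chars": s.n_user_chars,
                "chars_per_min": engagement_rate(s),
                "n_topics": len(s.topics),
                "resource_flag": len(s.resources) > 0,
                "eap_inflow": s.eap_inflow,
                "eap_outflow": s.eap_outflow,
            }
        )
    cols = [
        "session_id",
        "cohort",
        "duration_min",
        "n_messages",
        "n_chars",
        "chars_per_min",
        "n_topics",
        "resource_flag",
        "eap_inflow",
        "eap_outflow",
    ]
    return pd.DataFrame(rows, columns=cols)
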