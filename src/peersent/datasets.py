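"""Reference population reconstructed from a deployment's aggregate tables.

The proprietary transcripts behind the reference DPS deployment (24,818
sessions from 13,879 employees at five large employers) are not available,
but its published aggregate tables are: struggle-topic counts, EAP inflow /
outflow counts per topic, resource-type x topic counts, demographic
disclosure counts, and the business-hours split. This module rebuilds a
session-level corpus that reproduces those marginals exactly, so the
descriptive tabulation code can be checked against the printed numbers.

The sessions are deliberately minimal (no messages, unit durations): they
carry exactly the covariates the descriptive tables consume. They are a
synthetic stand-in for the real corpus, not a sample from it.
"""

from __future__ import annotations

import datetime as _dt

from .sessions import ChatSession, Demographics, Resource

N_SESSIONS = 24_818

#: Sessions per primary struggle topic (sums to N_SESSIONS).
TOPIC_COUNTS = {
    "relationship_issues": 7531,
    "trauma": 2663,
    "work_productivity_burnout": 2650,
    "stress": 2074,
    "loneliness": 1757,
    "depression": 1570,
    "financial_sdoh": 1565,
    "social_connection_belonging": 1160,
    "anxiety": 1098,
    "mental_health_conditions": 723,
    "identity": 638,
    "caregiving_parenting": 617,
    "physical_health_medical": 399,
    "suicide_self_harm": 373,
}

#: Sessions entered via an EAP referral, per topic (total 5,482).
EAP_INFLOW_COUNTS = {
    "anxiety": 363,
    "loneliness": 513,
    "physical_health_medical": 116,
    "suicide_self_harm": 107,
    "trauma": 659,
    "relationship_issues": 1840,
    "identity": 140,
    "mental_health_conditions": 157,
    "depression": 324,
    "social_connection_belonging": 233,
    "stress": 387,
    "caregiving_parenting": 87,
    "work_productivity_burnout": 356,
    "financial_sdoh": 200,
}

#: Sessions referred onward to EAP services, per topic (total 2,720).
EAP_OUTFLOW_COUNTS = {
    "anxiety": 207,
    "depression": 252,
    "caregiving_parenting": 83,
    "mental_health_conditions": 97,
    "suicide_self_harm": 50,
    "trauma": 342,
    "loneliness": 210,
    "stress": 235,
    "social_connection_belonging": 120,
    "relationship_issues": 764,
    "physical_health_medical": 40,
    "identity": 43,
    "financial_sdoh": 105,
    "work_productivity_burnout": 172,
}

#: Shared resources by topic x type (33,632 resources in total).
RESOURCE_COUNTS = {
    # topic: (blog, video, employee_specific, worksheet, quote, audio)
    "relationship_issues": (5338, 3089, 1314, 983, 332, 2),
    "trauma": (1866, 956, 590, 382, 74, 0),
    "work_productivity_burnout": (1556, 749, 629, 170, 68, 0),
    "stress": (1347, 736, 496, 269, 55, 0),
    "loneliness": (1174, 649, 332, 195, 80, 0),
    "depression": (974, 516, 365, 151, 47, 0),
    "financial_sdoh": (871, 382, 442, 64, 27, 0),
    "social_connection_belonging": (651, 364, 227, 91, 35, 0),
    "anxiety": (753, 440, 265, 99, 35, 0),
    "mental_health_conditions": (453, 261, 154, 37, 15, 0),
    "identity": (380, 217, 104, 47, 11, 0),
    "caregiving_parenting": (361, 219, 158, 45, 14, 0),
    "physical_health_medical": (219, 128, 118, 19, 8, 0),
    "suicide_self_harm": (214, 107, 75, 29, 9, 0),
}
_RESOURCE_TYPE_ORDER = ("blog", "video", "employee_specific", "worksheet", "quote", "audio")

#: Business-hours session counts per topic where published; the remainder of
#: the 7,995 within-hours sessions is spread over the other topics
#: proportionally (largest remainder), which only affects topics whose split
#: was not published.
WITHIN_TOTAL = 7_995
WITHIN_KNOWN = {
    "relationship_issues": 2249,
    "work_productivity_burnout": 1029,
    "financial_sdoh": 744,
    "trauma": 734,
    "stress": 732,
    "loneliness": 1757 - 1313,  # outside-hours count published
}

#: Gender disclosures: 8,647 sessions (34.84% of the corpus).
GENDER_COUNTS = {"female": 5738, "male": 2538, "nonbinary": 371}

#: Device split (published N there is 24,817; the last session gets mobile).
DEVICE_COUNTS = {"mobile": 19855, "desktop": 4467, "tablet": 496}

_WITHIN_START = _dt.datetime(2024, 1, 2, 10, 0)  # Tuesday morning
_OUTSIDE_START = _dt.datetime(2024, 1, 6, 20, 0)  # Saturday evening


def _within_counts() -> dict[str, int]:
    counts = dict(WITHIN_KNOWN)
    remaining = WITHIN_TOTAL - sum(counts.values())
    other_topics = [t for t in TOPIC_COUNTS if t not in counts]
    pool = sum(TOPIC_COUNTS[t] for t in other_topics)
    quotas = {t: remaining * TOPIC_COUNTS[t] / pool for t in other_topics}
    floors = {t: int(quotas[t]) for t in other_topics}
    short = remaining - sum(floors.values())
    by_frac = sorted(other_topics, key=lambda t: quotas[t] - floors[t], reverse=True)
    for t in by_frac[:short]:
        floors[t] += 1
    counts.update(floors)
    return counts


def study_population_corpus() -> list[ChatSession]:
    """The reconstructed 24,818-session reference population.

    Deterministic; reproduces the published marginals exactly: topic counts,
    EAP inflow/outflow per topic, resources per topic x type, the 7,995 /
    16,823 business-hours split (including the published per-topic splits),
    gender disclosures, and device counts.
    """
    within = _within_counts()
    gender_seq: list[str] = (
        ["female"] * GENDER_COUNTS["female"]
        + ["male"] * GENDER_COUNTS["male"]
        + ["nonbinary"] * GENDER_COUNTS["nonbinary"]
    )
    device_seq_counts = dict(DEVICE_COUNTS)

    sessions: list[ChatSession] = []
    global_idx = 0
    disclosed = 0
    for topic, total in TOPIC_COUNTS.items():
        n_in = EAP_INFLOW_COUNTS[topic]
        n_out = EAP_OUTFLOW_COUNTS[topic]
        n_within = within[topic]
        # spread this topic's resources over its sessions round-robin
        resource_pool: list[Resource] = []
        for rtype, count in zip(_RESOURCE_TYPE_ORDER, RESOURCE_COUNTS[topic]):
            resource_pool.extend(Resource(rtype, 1.0) for _ in range(count))
        for j in range(total):
            resources = resource_pool[j::total]
            demographics = None
            if disclosed < len(gender_seq):
                demographics = Demographics(
                    age=36, gender=gender_seq[disclosed], race="white"
                )
                disclosed += 1
            for dev, left in device_seq_counts.items():
                if left > 0:
                    device_seq_counts[dev] -= 1
                    device = dev
                    break
            sessions.append(
                ChatSession(
                    session_id=f"ref{global_idx:06d}",
                    employer_id=f"employer_{global_idx % 5 + 1}",
                    local_start=_WITHIN_START if j < n_within else _OUTSIDE_START,
                    duration_min=1.0,
                    messages=[],
                    topics=(topic,),
                    device=device,
                    country="US",
                    participant_count=1,
                    resources=resources,
                    eap_inflow=j < n_in,
                    eap_outflow=j < n_out,
                    demographics=demographics,
                )
            )
            global_idx += 1
    return sessions


#: Published cohort means for engagement metrics (within / outside business
#: hours) — inputs for worked-example parity of the percent-difference
#: statistics.
ENGAGEMENT_COHORT_MEANS = {
    "duration_min": {"within": 33.63, "outside": 40.03},
    "chars_per_min": {"within": 86.75, "outside": 63.00},
    "n_messages": {"within": 20.36, "outside": 26.35},
    "n_chars": {"within": 1559.61, "outside": 1917.05},
    "n_topics": {"within": 6.21, "outside": 7.01},
}

#: Published cohort baseline means per sentiment (within / outside).
BASELINE_COHORT_MEANS = {
    "anxiety": {"within": 6.24, "outside": 6.25},
    "depression": {"within": 5.17, "outside": 5.26},
    "despair": {"within": 5.82, "outside": 5.88},
    "helplessness": {"within": 6.17, "outside": 6.17},
    "loneliness": {"within": 6.66, "outside": 6.74},
    "sadness": {"within": 6.62, "outside": 6.58},
    "stress": {"within": 6.96, "outside": 6.85},
    "optimism": {"within": 3.12, "outside": 3.10},
}
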