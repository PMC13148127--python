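"""Synthetic peer-support chat corpora with known ground truth.

The generator emulates the structure of a large employer DPS (digital peer
support) deployment so that every downstream stage — inclusion filtering,
trajectory fitting, propensity matching, cohort comparison, tabulation — can
be exercised against a recoverable truth:

* each session belongs to a cohort (within / outside business hours, set by
  its drawn start time) and an arm (resource shared or not);
* for every sentiment the session has a latent linear trajectory
  ``b_i + slope * t`` over normalized time t in [0, 1], where the intercept
  ``b_i`` is drawn per session around the cohort baseline and the slope is
  the configured truth for that sentiment x cohort x arm;
* an observed message score is the latent value plus Gaussian noise, clipped
  to [1, 10] and rounded to the nearest integer (emulating a rater that
  emits whole scale points);
* engagement covariates (duration, message count, characters, topic count)
  are drawn per cohort, giving the cohorts a genuine covariate imbalance for
  matching to correct.

A single pseudo-random stream seeded from ``config.seed`` drives all draws
in a fixed, documented order (start cells and minutes in bulk, then one
session at a time: duration, message count, message times, character counts,
topics, device, country, participants, resources, EAP flags, demographics,
then per-sentiment intercept and noise in canonical sentiment order), so the
same config yields a byte-identical corpus.
"""

from __future__ import annotations

import copy
import datetime as _dt
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .sessions import (
    DEVICES,
    GENDERS,
    NEGATIVE_SENTIMENTS,
    RESOURCE_TYPES,
    SENTIMENTS,
    TOPICS,
    ChatSession,
    Demographics,
    Message,
    Resource,
)

COHORTS = ("within", "outside")
ARMS = ("resource", "no_resource")

#: Monday anchoring the simulated week (weekday 0).
_BASE_DATE = _dt.datetime(2024, 1, 1)


class ConfigError(ValueError):
    """A synthetic-data configuration is invalid; names the offending field."""

    def __init__(self, message: str, field: str):
        self.field = field
        super().__init__(f"{field}: {message}")


# -- default study conditions ----------------------------------------------

#: Cohort baseline mean (SD) per sentiment on the 1-10 scale.
_DEFAULT_BASELINES = {
    "anxiety": {"within": (6.24, 2.40), "outside": (6.25, 2.29)},
    "depression": {"within": (5.17, 2.29), "outside": (5.26, 2.16)},
    "despair": {"within": (5.82, 2.31), "outside": (5.88, 2.19)},
    "helplessness": {"within": (6.17, 2.33), "outside": (6.17, 2.27)},
    "loneliness": {"within": (6.66, 1.99), "outside": (6.74, 2.00)},
    "sadness": {"within": (6.62, 1.82), "outside": (6.58, 1.83)},
    "stress": {"within": (6.96, 1.85), "outside": (6.85, 1.86)},
    "optimism": {"within": (3.12, 1.64), "outside": (3.10, 1.65)},
}

#: Improvement percentages by arm (resource shared / not), matched-cohort scale.
_ARM_IMPROVEMENT = {
    "anxiety": (36.3, 34.4),
    "depression": (38.7, 31.4),
    "despair": (33.8, 30.8),
    "helplessness": (33.0, 30.2),
    "loneliness": (32.7, 29.8),
    "sadness": (31.4, 31.8),
    "stress": (31.8, 30.5),
    "optimism": (59.9, 51.1),
}

#: Outside-minus-within improvement gaps (percentage points) where cohorts differ.
_COHORT_IMPROVEMENT_DELTA = {"depression": 2.3, "helplessness": 1.9, "loneliness": 0.5}

_TOPIC_COUNTS = {
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

_RESOURCE_TYPE_COUNTS = {
    "blog": 16157,
    "video": 8813,
    "employee_specific": 5269,
    "worksheet": 2581,
    "quote": 810,
    "audio": 2,
}

#: User ages grouped in 3-year increments (disclosing users).
_AGE_BIN_COUNTS = {
    (13, 15): 239, (16, 18): 954, (19, 21): 833, (22, 24): 691,
    (25, 27): 616, (28, 30): 630, (31, 33): 582, (34, 36): 640,
    (37, 39): 275, (40, 42): 484, (43, 45): 238, (46, 48): 266,
    (49, 51): 466, (52, 54): 194, (55, 57): 367, (58, 60): 169,
    (61, 63): 172, (64, 66): 106, (67, 69): 149, (70, 72): 91,
    (73, 75): 85, (76, 78): 139,
}

_RACE_WEIGHTS = {
    "white": 0.5339,
    "african_american": 0.1648,
    "hispanic": 0.1447,
    "asian": 0.0909,
    "american_indian_alaska_native": 0.0347,
    "native_hawaiian_pacific_islander": 0.0192,
    "middle_eastern_north_african": 0.0119,
}

#: Share of sessions starting within business hours.
_WITHIN_SHARE = 7995 / 24818


def _normalized(weights: dict) -> dict:
    total = sum(weights.values())
    return {k: v / total for k, v in weights.items()}


def _default_slopes() -> dict:
    slopes: dict = {}
    for s in SENTIMENTS:
        sign = 1.0 if s == "optimism" else -1.0
        delta = _COHORT_IMPROVEMENT_DELTA.get(s, 0.0)
        slopes[s] = {}
        for cohort in COHORTS:
            adj = delta / 2.0 if cohort == "outside" else -delta / 2.0
            intercept = _DEFAULT_BASELINES[s][cohort][0]
            slopes[s][cohort] = {
                "resource": sign * (_ARM_IMPROVEMENT[s][0] + adj) / 100.0 * intercept,
                "no_resource": sign * (_ARM_IMPROVEMENT[s][1] + adj) / 100.0 * intercept,
            }
    return slopes


def _default_start_time_weights() -> np.ndarray:
    """Hour x weekday start-time mixture tuned to the business-hours share.

    A diurnal profile (overnight trough, evening peak) is tiled over the
    week, then the Mon-Fri 08:00-17:00 cells are rescaled so the expected
    within-hours share matches the deployment's 32.2%.
    """
    hour_profile = np.array(
        [2.0, 1.5, 1.0, 1.0, 1.0, 1.5, 2.0, 3.0, 4.0, 4.5, 5.0, 5.0,
         5.0, 5.5, 6.0, 6.5, 7.0, 7.5, 7.5, 7.0, 6.0, 5.0, 4.0, 3.0]
    )
    w = np.tile(hour_profile, (7, 1)).astype(float)
    biz = np.zeros((7, 24), dtype=bool)
    biz[:5, 8:17] = True
    wb, wo = w[biz].sum(), w[~biz].sum()
    f = _WITHIN_SHARE * wo / (wb * (1.0 - _WITHIN_SHARE))
    w[biz] *= f
    return w / w.sum()


@dataclass
class SyntheticConfig:
    """All knobs of the generator; defaults emulate the deployment's scale.

    Distribution parameters are (mean, SD) pairs on natural units: minutes
    for durations (lognormal), counts for messages (negative binomial) and
    topics (rounded normal, clipped to [1, 14]), characters per message
    (lognormal), score units for baselines and per-message noise.
    """

    n_sessions: int = 1000
    seed: int = 0
    baseline: dict = field(default_factory=lambda: copy.deepcopy(_DEFAULT_BASELINES))
    true_slope: dict = field(default_factory=_default_slopes)
    message_count: dict = field(
        default_factory=lambda: {"within": (20.36, 25.55), "outside": (26.35, 30.95)}
    )
    duration: dict = field(
        default_factory=lambda: {"within": (33.63, 32.72), "outside": (40.03, 36.59)}
    )
    chars_per_message: dict = field(
        default_factory=lambda: {"within": (76.6, 1.0), "outside": (72.8, 1.0)}
    )
    topics_discussed: dict = field(
        default_factory=lambda: {"within": (6.21, 3.28), "outside": (7.01, 3.53)}
    )
    topic_weights: dict = field(default_factory=lambda: _normalized(_TOPIC_COUNTS))
    device_weights: dict = field(
        default_factory=lambda: {"mobile": 0.80, "desktop": 0.18, "tablet": 0.02}
    )
    country_weights: dict = field(
        default_factory=lambda: {"US": 0.7971, "CA": 0.06, "GB": 0.05, "IN": 0.04,
                                 "other": 0.0529}
    )
    participant_weights: tuple = (0.35, 0.30, 0.20, 0.10, 0.05)  # 1..5 peers
    resource_probability: float = 0.68
    extra_resources_mean: float = 1.0
    resource_type_weights: dict = field(
        default_factory=lambda: _normalized(_RESOURCE_TYPE_COUNTS)
    )
    eap_inflow_probability: float = 0.2209
    eap_outflow_probability: float = 0.1096
    demographic_disclosure_probability: float = 0.3484
    gender_weights: dict = field(
        default_factory=lambda: {"female": 0.6636, "male": 0.2935, "nonbinary": 0.0429}
    )
    race_weights: dict = field(default_factory=lambda: _normalized(_RACE_WEIGHTS))
    age_bin_weights: dict = field(default_factory=lambda: _normalized(_AGE_BIN_COUNTS))
    noise_sd: float = 1.5
    start_time_weights: np.ndarray = field(default_factory=_default_start_time_weights)
    employer_ids: tuple = ("employer_1", "employer_2", "employer_3", "employer_4",
                          "employer_5")

    def validate(self) -> None:
        if self.n_sessions < 0:
            raise ConfigError("must be >= 0", "n_sessions")
        for name in (
            "resource_probability",
            "eap_inflow_probability",
            "eap_outflow_probability",
            "demographic_disclosure_probability",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"probability {v} outside [0, 1]", name)
        if self.noise_sd < 0:
            raise ConfigError("must be >= 0", "noise_sd")
        if self.extra_resources_mean < 0:
            raise ConfigError("must be >= 0", "extra_resources_mean")
        for name, weights in (
            ("topic_weights", self.topic_weights),
            ("device_weights", self.device_weights),
            ("country_weights", self.country_weights),
            ("resource_type_weights", self.resource_type_weights),
            ("gender_weights", self.gender_weights),
            ("race_weights", self.race_weights),
            ("age_bin_weights", self.age_bin_weights),
        ):
            vals = list(weights.values())
            if any(v < 0 for v in vals):
                raise ConfigError("negative weight", name)
            if abs(sum(vals) - 1.0) > 1e-9:
                raise ConfigError(f"weights sum to {sum(vals)}, expected 1", name)
        if abs(sum(self.participant_weights) - 1.0) > 1e-9:
            raise ConfigError("weights must sum to 1", "participant_weights")
        w = np.asarray(self.start_time_weights, dtype=float)
        if w.shape != (7, 24):
            raise ConfigError(f"shape {w.shape}, expected (7, 24)", "start_time_weights")
        if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ConfigError("weights must be >= 0 and sum to 1", "start_time_weights")
        if set(self.topic_weights) - set(TOPICS):
            raise ConfigError("unknown topic in weights", "topic_weights")
        for s in SENTIMENTS:
            if s not in self.baseline:
                raise ConfigError(f"missing sentiment {s}", "baseline")
            for cohort in COHORTS:
                mean, sd = self.baseline[s][cohort]
                if sd < 0:
                    raise ConfigError(f"negative SD for {s}/{cohort}", "baseline")
                if s in NEGATIVE_SENTIMENTS and not (5.0 < mean <= 10.0):
                    raise ConfigError(
                        f"negative-sentiment baseline mean {mean} for {s}/{cohort} "
                        "must lie in (5, 10] so the corpus satisfies the inclusion "
                        "rule in expectation",
                        "baseline",
                    )
                if s == "optimism" and not (1.0 <= mean < 5.0):
                    raise ConfigError(
                        f"optimism baseline mean {mean} for {cohort} must lie in [1, 5)",
                        "baseline",
                    )
                if s not in self.true_slope or cohort not in self.true_slope[s]:
                    raise ConfigError(f"missing slope for {s}/{cohort}", "true_slope")
                for arm in ARMS:
                    if arm not in self.true_slope[s][cohort]:
                        raise ConfigError(
                            f"missing slope for {s}/{cohort}/{arm}", "true_slope"
                        )
        for name in ("message_count", "duration", "chars_per_message", "topics_discussed"):
            d = getattr(self, name)
            for cohort in COHORTS:
                if cohort not in d:
                    raise ConfigError(f"missing cohort {cohort}", name)
                mean, sd = d[cohort]
                if mean <= 0 or sd < 0:
                    raise ConfigError(f"invalid (mean, SD) = {(mean, sd)}", name)
        mc = self.message_count
        for cohort in COHORTS:
            mean, sd = mc[cohort]
            if sd**2 <= mean:
                raise ConfigError(
                    "negative-binomial counts need variance > mean", "message_count"
                )


def default_config(n_sessions: int = 1000, seed: int = 0, **overrides) -> SyntheticConfig:
    """Study-condition defaults, with keyword overrides for any field."""
    cfg = SyntheticConfig(n_sessions=n_sessions, seed=seed)
    for key, value in overrides.items():
        if not hasattr(cfg, key):
            raise ConfigError("unknown field", key)
        setattr(cfg, key, value)
    cfg.validate()
    return cfg


def constant_truth_config(
    n_sessions: int,
    seed: int,
    slope: float = -3.0,
    intercept: float = 6.5,
    baseline_sd: float = 0.8,
    noise_sd: float = 1.0,
    optimism_intercept: float = 3.1,
    optimism_slope: float = 2.4,
) -> SyntheticConfig:
    """A corpus where every negative sentiment follows one known line.

    Useful for parameter-recovery studies: all cohorts and arms share the
    given slope/intercept (optimism gets its own rising line), so the
    downstream fit has a single unambiguous truth.
    """
    baseline = {
        s: {c: (intercept, baseline_sd) for c in COHORTS} for s in SENTIMENTS
    }
    baseline["optimism"] = {c: (optimism_intercept, baseline_sd) for c in COHORTS}
    slopes = {
        s: {c: {a: slope for a in ARMS} for c in COHORTS} for s in SENTIMENTS
    }
    slopes["optimism"] = {c: {a: optimism_slope for a in ARMS} for c in COHORTS}
    return default_config(
        n_sessions, seed, baseline=baseline, true_slope=slopes, noise_sd=noise_sd
    )


# -- ground truth -----------------------------------------------------------


def ground_truth(config: SyntheticConfig) -> pd.DataFrame:
    """Deterministic truth ledger: slope, intercept and implied improvement.

    One row per sentiment x cohort x arm; the implied improvement percent is
    |slope| / intercept x 100 under the generator's linear model.
    """
    config.validate()
    rows = []
    for s in SENTIMENTS:
        for cohort in COHORTS:
            intercept = config.baseline[s][cohort][0]
            for arm in ARMS:
                slope = config.true_slope[s][cohort][arm]
                rows.append(
                    {
                        "sentiment": s,
                        "cohort": cohort,
                        "arm": arm,
                        "slope": slope,
                        "intercept": intercept,
                        "improvement_pct": abs(slope) / intercept * 100.0,
                    }
                )
    return pd.DataFrame(rows)


# -- generation -------------------------------------------------------------


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def _negbin_params(mean: float, sd: float) -> tuple[float, float]:
    var = sd**2
    r = mean**2 / (var - mean)
    return r, r / (r + mean)


def generate_sessions(
    config: SyntheticConfig, with_truth: bool = False
) -> list[ChatSession] | tuple[list[ChatSession], pd.DataFrame]:
    """Draw a corpus of chat sessions from the configured model.

    With ``with_truth`` also returns a per-session ledger of the drawn latent
    intercepts, cohort and arm (for recovery tests). The same config yields a
    byte-identical serialized corpus.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_sessions
    sessions: list[ChatSession] = []
    truth_rows: list[dict] = []
    if n == 0:
        return (sessions, pd.DataFrame(truth_rows)) if with_truth else sessions

    # bulk draws: start cell (weekday*24 + hour) and minute-within-hour
    flat = np.asarray(config.start_time_weights, dtype=float).ravel()
    cells = rng.choice(168, size=n, p=flat)
    minutes = rng.uniform(0.0, 60.0, size=n)

    topic_names = list(config.topic_weights)
    topic_p = np.array([config.topic_weights[t] for t in topic_names])
    device_p = np.array([config.device_weights.get(d, 0.0) for d in DEVICES])
    country_names = list(config.country_weights)
    country_p = np.array([config.country_weights[c] for c in country_names])
    rtype_names = [t for t in RESOURCE_TYPES if t in config.resource_type_weights]
    rtype_p = np.array([config.resource_type_weights[t] for t in rtype_names])
    gender_p = np.array([config.gender_weights.get(g, 0.0) for g in GENDERS])
    race_names = list(config.race_weights)
    race_p = np.array([config.race_weights[r] for r in race_names])
    age_bins = list(config.age_bin_weights)
    age_p = np.array([config.age_bin_weights[b] for b in age_bins])
    participant_p = np.asarray(config.participant_weights, dtype=float)

    ln_dur = {c: _lognormal_params(*config.duration[c]) for c in COHORTS}
    nb_msg = {c: _negbin_params(*config.message_count[c]) for c in COHORTS}
    ln_char = {
        c: (
            math.log(config.chars_per_message[c][0]) - config.chars_per_message[c][1] ** 2 / 2,
            config.chars_per_message[c][1],
        )
        for c in COHORTS
    }

    for i in range(n):
        weekday, hour = divmod(int(cells[i]), 24)
        start = _BASE_DATE + _dt.timedelta(days=weekday, hours=int(hour), minutes=float(minutes[i]))
        within = weekday < 5 and 8 <= hour < 17
        cohort = "within" if within else "outside"

        mu, sigma = ln_dur[cohort]
        duration = float(rng.lognormal(mu, sigma))
        r, p = nb_msg[cohort]
        n_msgs = max(1, int(rng.negative_binomial(r, p)))
        if n_msgs > 1:
            later = np.sort(rng.uniform(0.0, duration, size=n_msgs - 1))
            times = np.concatenate([[0.0], later])
        else:
            times = np.zeros(1)
        mu_c, sig_c = ln_char[cohort]
        chars = np.maximum(1, np.rint(rng.lognormal(mu_c, sig_c, size=n_msgs))).astype(int)

        t_mean, t_sd = config.topics_discussed[cohort]
        n_topics = int(np.clip(round(rng.normal(t_mean, t_sd)), 1, len(TOPICS)))
        primary = topic_names[rng.choice(len(topic_names), p=topic_p)]
        others = [t for t in TOPICS if t != primary]
        extra_idx = rng.choice(len(others), size=n_topics - 1, replace=False)
        topics = (primary, *(others[j] for j in sorted(extra_idx)))

        device = DEVICES[rng.choice(len(DEVICES), p=device_p)]
        country = country_names[rng.choice(len(country_names), p=country_p)]
        participants = 1 + int(rng.choice(5, p=participant_p))

        resources: list[Resource] = []
        if rng.random() < config.resource_probability:
            n_res = 1 + int(rng.poisson(config.extra_resources_mean))
            type_idx = rng.choice(len(rtype_names), size=n_res, p=rtype_p)
            res_times = np.sort(rng.uniform(0.0, duration, size=n_res))
            resources = [
                Resource(rtype_names[int(k)], float(tt))
                for k, tt in zip(type_idx, res_times)
            ]
        arm = "resource" if resources else "no_resource"

        eap_in = bool(rng.random() < config.eap_inflow_probability)
        eap_out = bool(rng.random() < config.eap_outflow_probability)

        demographics: Optional[Demographics] = None
        if rng.random() < config.demographic_disclosure_probability:
            lo, hi = age_bins[rng.choice(len(age_bins), p=age_p)]
            age = int(rng.integers(lo, hi + 1))
            gender = GENDERS[rng.choice(len(GENDERS), p=gender_p)]
            race = race_names[rng.choice(len(race_names), p=race_p)]
            demographics = Demographics(age=age, gender=gender, race=race)

        t_norm = times / duration
        score_matrix = np.empty((n_msgs, len(SENTIMENTS)))
        intercepts = {}
        for j, s in enumerate(SENTIMENTS):
            b_mean, b_sd = config.baseline[s][cohort]
            b = float(rng.normal(b_mean, b_sd))
            slope = config.true_slope[s][cohort][arm]
            eps = rng.normal(0.0, config.noise_sd, size=n_msgs)
            score_matrix[:, j] = np.clip(np.rint(b + slope * t_norm + eps), 1.0, 10.0)
            intercepts[s] = b

        messages = [
            Message(
                index=k,
                time_offset_min=float(times[k]),
                author_role="primary_user",
                char_count=int(chars[k]),
                scores={s: float(score_matrix[k, j]) for j, s in enumerate(SENTIMENTS)},
            )
            for k in range(n_msgs)
        ]

        session_id = f"s{i:07d}"
        sessions.append(
            ChatSession(
                session_id=session_id,
                employer_id=config.employer_ids[i % len(config.employer_ids)],
                local_start=start,
                duration_min=duration,
                messages=messages,
                topics=topics,
                device=device,
                country=country,
                participant_count=participants,
                resources=resources,
                eap_inflow=eap_in,
                eap_outflow=eap_out,
                demographics=demographics,
            )
        )
        if with_truth:
            truth_rows.append(
                {"session_id": session_id, "cohort": cohort, "arm": arm, **intercepts}
            )

    if with_truth:
        return sessions, pd.DataFrame(truth_rows)
    return sessions


def write_ground_truth(config: SyntheticConfig, path) -> None:
    """GroundTruth ledger as a flat CSV (sentiment, cohort, arm, slope, ...)."""
    ground_truth(config).to_csv(path, index=False)
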