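"""Descriptive tables: hand-enumerated fixtures and internal consistency."""

import datetime as dt

import numpy as np
import pytest

from peersent.sessions import Demographics
from peersent.tabulate import (
    activity_histogram,
    demographics_summary,
    eap_flow_table,
    engagement_summary,
    resource_table,
    round_half_up,
    topic_distribution,
    write_report,
)

from conftest import build_session


def _corpus():
    """Three hand-built sessions with known tallies."""
    s1 = build_session(
        [7, 7, 7],
        session_id="s1",
        topics=("stress", "anxiety"),
        resources=[("blog", 1.0), ("video", 2.0)],
        eap_inflow=True,
        local_start=dt.datetime(2024, 1, 2, 10, 0),  # Tue, within
    )
    s1.demographics = Demographics(age=30, gender="female", race="white")
    s2 = build_session(
        [6, 6, 6],
        session_id="s2",
        topics=("stress",),
        resources=[("blog", 3.0)],
        eap_outflow=True,
        local_start=dt.datetime(2024, 1, 6, 20, 0),  # Sat, outside
    )
    s3 = build_session(
        [8, 8, 8],
        session_id="s3",
        topics=("loneliness",),
        local_start=dt.datetime(2024, 1, 2, 21, 0),  # Tue evening, outside
    )
    s3.demographics = Demographics(age=40, gender="male", race="asian")
    return [s1, s2, s3]


class TestRounding:
    @pytest.mark.parametrize(
        "value, expected", [(30.3449, 30.34), (1.355, 1.36), (2.675, 2.68), (0.005, 0.01)]
    )
    def test_half_up(self, value, expected):
        assert round_half_up(value) == expected


class TestTopicDistribution:
    def test_multi_label_counts(self):
        table = topic_distribution(_corpus()).set_index("topic")
        assert table.loc["stress", "count"] == 2
        assert table.loc["anxiety", "count"] == 1
        assert table.loc["stress", "percent"] == round_half_up(2 / 3 * 100)
        assert table.loc["depression", "count"] == 0

    def test_invariant_under_session_permutation(self):
        corpus = _corpus()
        t1 = topic_distribution(corpus)
        t2 = topic_distribution(corpus[::-1])
        assert t1.equals(t2)


class TestEapFlow:
    def test_hand_tally(self):
        table = eap_flow_table(_corpus(), "inflow").set_index("topic")
        assert table.loc["stress", "flagged_count"] == 1
        assert table.loc["stress", "percent"] == 50.0
        assert table.loc["overall", "flagged_count"] == 1
        assert table.loc["overall", "percent"] == round_half_up(1 / 3 * 100)

    def test_percent_recomputes_from_counts(self):
        table = eap_flow_table(_corpus(), "outflow")
        for _, row in table.iterrows():
            if row.total_count:
                assert row.percent == round_half_up(
                    row.flagged_count / row.total_count * 100
                )

    def test_bad_direction_raises(self):
        with pytest.raises(ValueError):
            eap_flow_table(_corpus(), "sideways")


class TestResources:
    def test_hand_tally_and_average(self):
        counts, avg = resource_table(_corpus())
        assert counts.loc["stress", "blog"] == 2  # s1 + s2
        assert counts.loc["anxiety", "blog"] == 1  # s1 counts once per topic
        assert counts.loc["stress", "video"] == 1
        assert avg == pytest.approx(3 / 3)

    def test_empty_resources(self):
        corpus = [build_session([6, 6, 6], session_id="a")]
        counts, avg = resource_table(corpus)
        assert counts["count"].sum() == 0
        assert avg == 0.0


class TestActivity:
    def test_histogram_and_split(self):
        hours, cohorts = activity_histogram(_corpus())
        assert hours[10] == 1 and hours[20] == 1 and hours[21] == 1
        assert cohorts["within"] == 1 and cohorts["outside"] == 2
        assert cohorts["outside_share_pct"] == round_half_up(2 / 3 * 100)


class TestDemographics:
    def test_percentages_over_disclosers_only(self):
        out = demographics_summary(_corpus())
        assert out["n_disclosing"] == 2
        assert out["disclosure_rate_pct"] == round_half_up(2 / 3 * 100)
        assert out["gender"].loc["female", "percent"] == 50.0
        assert out["gender"]["percent"].sum() == pytest.approx(100.0, abs=0.02)

    def test_no_disclosures(self):
        corpus = [build_session([6, 6, 6])]
        out = demographics_summary(corpus)
        assert out["disclosure_rate_pct"] == 0.0
        assert out["gender"].empty


class TestEngagementSummary:
    def test_identical_cohorts_zero_percent_difference(self):
        a = build_session([6, 6, 6], session_id="a",
                          local_start=dt.datetime(2024, 1, 2, 10, 0))
        b = build_session([6, 6, 6], session_id="b",
                          local_start=dt.datetime(2024, 1, 6, 20, 0))
        table = engagement_summary([a, a, b, b]).set_index("metric")
        assert (table["percent_difference"].abs() < 1e-12).all()

    def test_known_gap_direction(self):
        a = build_session([6, 6, 6], session_id="a", duration=30.0,
                          local_start=dt.datetime(2024, 1, 2, 10, 0))
        b = build_session([6, 6, 6], session_id="b", duration=40.0,
                          local_start=dt.datetime(2024, 1, 6, 20, 0))
        table = engagement_summary([a, a, b, b]).set_index("metric")
        row = table.loc["duration_min"]
        assert row["larger_cohort"] == "outside"
        assert row["percent_difference"] == pytest.approx((40 - 30) / 30 * 100)

    def test_empty_cohort_raises(self):
        a = build_session([6, 6, 6], local_start=dt.datetime(2024, 1, 2, 10, 0))
        with pytest.raises(ValueError):
            engagement_summary([a, a])


def test_write_report_emits_full_table_set(tmp_path):
    manifest = write_report(_corpus(), tmp_path)
    for name in manifest["tables"].values():
        assert (tmp_path / name).exists()
    assert manifest["n_sessions"] == 3
    assert (tmp_path / "manifest.json").exists()
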