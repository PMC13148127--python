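"""Binning, aggregation, OLS trend fitting, and the improvement statistic."""

import numpy as np
import pytest

from peersent.trajectory import (
    BIN_CENTERS,
    BinnedTrajectory,
    TrendFit,
    aggregate,
    fit_trend,
    improvement_percent,
    normalize_session,
    trend,
)
from peersent.synthetic import constant_truth_config, generate_sessions, ground_truth

from conftest import build_session


def _traj(values_by_bin, session_id="t", sentiment="stress"):
    arr = np.full(100, np.nan)
    for idx, v in values_by_bin.items():
        arr[idx] = v
    return BinnedTrajectory(session_id, sentiment, arr)


class TestNormalizeSession:
    def test_direct_placement_and_final_bin_clamp(self):
        s = build_session([8, 6, 4], times=[0.0, 5.0, 10.0], duration=10.0)
        traj = normalize_session(s, "stress")
        assert traj.bin_values[0] == 8
        assert traj.bin_values[50] == 6
        assert traj.bin_values[99] == 4  # t = 1.0 clamps into the last bin
        assert np.isnan(traj.bin_values).sum() == 97

    def test_within_bin_collision_averaged(self):
        s = build_session([6, 8], times=[1.20, 1.29], duration=10.0)
        traj = normalize_session(s, "stress")
        assert traj.bin_values[12] == pytest.approx(7.0)

    def test_unscored_messages_contribute_nothing(self):
        s = build_session([6, None, 8], times=[0.0, 5.0, 10.0], duration=10.0)
        traj = normalize_session(s, "stress")
        assert np.isnan(traj.bin_values[50])

    def test_zero_duration_raises(self):
        s = build_session([6], duration=1.0)
        s.duration_min = 0.0
        with pytest.raises(ValueError):
            normalize_session(s, "stress")


class TestAggregate:
    def test_single_trajectory_sem_zero(self):
        agg = aggregate([_traj({0: 6.0, 50: 4.0})])
        assert agg.mean[0] == 6.0
        assert agg.sem[0] == 0.0
        assert agg.n[0] == 1

    def test_two_trajectories_hand_sem(self):
        # sample SD of {6, 8} is sqrt(2); SEM = sqrt(2)/sqrt(2) = 1
        agg = aggregate([_traj({0: 6.0}, "a"), _traj({0: 8.0}, "b")])
        assert agg.mean[0] == pytest.approx(7.0)
        assert agg.sem[0] == pytest.approx(1.0)

    def test_unpopulated_bins_stay_missing(self):
        agg = aggregate([_traj({0: 6.0}), _traj({0: 7.0})])
        assert np.isnan(agg.mean[5])
        assert agg.n[5] == 0

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            aggregate([])


class TestFitTrend:
    def test_noiseless_line_recovered_exactly(self):
        values = {i: 7.0 - 3.0 * BIN_CENTERS[i] for i in range(100)}
        fit = fit_trend(aggregate([_traj(values)]))
        assert fit.slope == pytest.approx(-3.0, abs=1e-12)
        assert fit.intercept == pytest.approx(7.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_constant_input_gives_zero_slope_zero_r2(self):
        fit = fit_trend(aggregate([_traj({i: 5.0 for i in range(100)})]))
        assert fit.slope == pytest.approx(0.0)
        assert fit.r_squared == pytest.approx(0.0)

    def test_small_instance_matches_closed_form_ols(self):
        bins = [0, 10, 25, 60, 99]
        ys = [8.0, 7.5, 6.8, 5.0, 3.9]
        fit = fit_trend(aggregate([_traj(dict(zip(bins, ys)))]))
        x = BIN_CENTERS[bins]
        y = np.array(ys)
        slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        intercept = y.mean() - slope * x.mean()
        assert fit.slope == pytest.approx(slope, abs=1e-12)
        assert fit.intercept == pytest.approx(intercept, abs=1e-12)

    def test_single_bin_raises(self):
        with pytest.raises(ValueError):
            fit_trend(aggregate([_traj({0: 6.0})]))

    def test_weighted_variant_reduces_to_ols_on_equal_weights(self):
        values = {i: 6.0 - 2.0 * BIN_CENTERS[i] for i in range(0, 100, 2)}
        plain = fit_trend(aggregate([_traj(values)]))
        weighted = fit_trend(aggregate([_traj(values)]), weight_by_n=True)
        assert weighted.slope == pytest.approx(plain.slope, abs=1e-9)


class TestImprovementPercent:
    @pytest.mark.parametrize(
        "slope, intercept, expected",
        [
            (-3.0, 6.52, 46.0),
            (0.0, 6.0, 0.0),
            (2.39, 3.10, 77.1),
        ],
    )
    def test_formula(self, slope, intercept, expected):
        fit = TrendFit(slope, intercept, 1.0, 0.0, 0.0, 100)
        assert improvement_percent(fit) == pytest.approx(expected, abs=0.05)

    def test_nonpositive_intercept_raises(self):
        with pytest.raises(ValueError):
            improvement_percent(TrendFit(-1.0, 0.0, 1.0, 0.0, 0.0, 100))


class TestInvariants:
    def test_scale_equivariance(self):
        rng = np.random.default_rng(4)
        values = {i: float(5 + rng.normal()) for i in range(0, 100, 3)}
        shifted = {i: v + 2.0 for i, v in values.items()}
        f0 = fit_trend(aggregate([_traj(values)]))
        f1 = fit_trend(aggregate([_traj(shifted)]))
        assert f1.slope == pytest.approx(f0.slope, abs=1e-10)
        assert f1.intercept == pytest.approx(f0.intercept + 2.0, abs=1e-10)

    def test_r2_decreases_with_noise_in_expectation(self):
        base = {i: 7.0 - 3.0 * BIN_CENTERS[i] for i in range(100)}
        r2_noisy = []
        for seed in range(8):
            rng = np.random.default_rng(seed)
            noisy = {i: v + rng.normal(0, 0.5) for i, v in base.items()}
            r2_noisy.append(fit_trend(aggregate([_traj(noisy)])).r_squared)
        assert all(r < 1.0 for r in r2_noisy)
        assert np.mean(r2_noisy) < 1.0

    def test_recovery_on_synthetic_corpus(self):
        """Fitted slope within 3 SE of generator truth; improvement within 3 pts."""
        cfg = constant_truth_config(5000, seed=21, slope=-2.5, intercept=6.8)
        sessions = generate_sessions(cfg)
        result = trend(sessions, "sadness")
        truth = ground_truth(cfg)
        row = truth[
            (truth.sentiment == "sadness")
            & (truth.cohort == "outside")
            & (truth.arm == "resource")
        ].iloc[0]
        assert abs(result.fit.slope - row.slope) < 3 * result.fit.stderr
        assert result.improvement_pct == pytest.approx(row.improvement_pct, abs=3.0)
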