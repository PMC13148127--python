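"""Propensity features, logistic fit, greedy caliper matching, balance."""

import warnings

import numpy as np
import pandas as pd
import pytest

from peersent.matching import (
    _fit_logistic,
    balance_diagnostics,
    bin_duration,
    bin_engagement,
    build_features,
    fit_propensity,
    match,
    match_cohorts,
    standardized_mean_differences,
)
from peersent.sessions import split_cohorts
from peersent.inclusion import filter_corpus
from peersent.synthetic import default_config, generate_sessions

from conftest import build_session


class TestBins:
    @pytest.mark.parametrize(
        "minutes, label",
        [(4.9, "0-5"), (5.0, "5-10"), (19.99, "10-20"), (45.0, "45-60"), (75, ">60")],
    )
    def test_duration_bins_half_open(self, minutes, label):
        assert bin_duration(minutes) == label

    @pytest.mark.parametrize(
        "rate, label", [(0.0, "0-10"), (10.0, "10-20"), (49.9, "40-50"), (50.0, ">50")]
    )
    def test_engagement_bins_half_open(self, rate, label):
        assert bin_engagement(rate) == label

    def test_negative_input_raises(self):
        with pytest.raises(ValueError):
            bin_duration(-1.0)


class TestLogisticFit:
    def test_matches_irls_oracle(self):
        """Coefficients agree with an independent Newton-Raphson IRLS to 1e-6."""
        rng = np.random.default_rng(3)
        X = rng.normal(size=(80, 2))
        logits = 0.8 * X[:, 0] - 0.5 * X[:, 1] + 0.2
        y = (rng.random(80) < 1 / (1 + np.exp(-logits))).astype(float)

        # IRLS oracle: beta <- beta + (X'WX)^-1 X'(y - p)
        Xd = np.column_stack([np.ones(len(y)), X])
        beta = np.zeros(3)
        for _ in range(60):
            p = 1 / (1 + np.exp(-Xd @ beta))
            W = p * (1 - p)
            step = np.linalg.solve(Xd.T @ (W[:, None] * Xd), Xd.T @ (y - p))
            beta = beta + step
            if np.abs(step).max() < 1e-12:
                break

        coef, intercept = _fit_logistic(X, y, tol=1e-12)
        assert intercept == pytest.approx(beta[0], abs=1e-6)
        assert coef == pytest.approx(beta[1:], abs=1e-6)


class TestFitPropensity:
    def _cohorts(self, n=400, seed=2):
        sessions = generate_sessions(default_config(n, seed=seed))
        included, _ = filter_corpus(sessions, "stress")
        return split_cohorts(included, "business_hours")[:2]

    def test_no_signal_gives_near_chance_scores(self):
        """Two i.i.d. halves of one cohort: in-sample AUC stays near 0.5."""
        a, b = self._cohorts(n=1200)
        pool = a + b
        half_a, half_b = pool[::2], pool[1::2]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_propensity(half_a, half_b, "stress")
        sa = model.scores_a.to_numpy()
        sb = model.scores_b.to_numpy()
        auc = (sa[:, None] > sb[None, :]).mean()
        assert 0.4 < auc < 0.75  # overfit lifts it above 0.5, but no real signal
        assert not model.separation_flag

    def test_fully_separating_feature_flagged(self):
        a = [
            build_session([7, 7, 7], session_id=f"a{i}", device="desktop")
            for i in range(20)
        ]
        b = [
            build_session([7, 7, 7], session_id=f"b{i}", device="mobile")
            for i in range(20)
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_propensity(a, b, "stress")
        assert model.separation_flag

    def test_empty_cohort_raises(self):
        a, _ = self._cohorts(n=60)
        with pytest.raises(ValueError):
            fit_propensity(a, [], "stress")

    def test_unfiltered_session_rejected(self):
        bad = build_session([None, None, None], session_id="x")
        with pytest.raises(ValueError, match="inclusion"):
            build_features([bad], "stress")


def _naive_greedy(scores_a, scores_b, caliper):
    """Independent reference: literal greedy walk with explicit tie-breaks."""
    treated, control = (scores_a, scores_b) if len(scores_a) <= len(scores_b) else (scores_b, scores_a)
    used = set()
    pairs = []
    for t_id in sorted(treated):
        best_id, best_gap = None, None
        for c_id in sorted(control):
            if c_id in used:
                continue
            gap = abs(control[c_id] - treated[t_id])
            if gap > caliper:
                continue
            if best_gap is None or gap < best_gap:
                best_id, best_gap = c_id, gap
        if best_id is not None:
            used.add(best_id)
            pairs.append((t_id, best_id))
    return pairs


class TestMatch:
    def test_nearest_within_caliper(self):
        res = match({"t1": 0.50}, {"c1": 0.48, "c2": 0.60}, caliper_fraction=1.0)
        # caliper here = SD of {0.5, 0.48, 0.6}; 0.48 is nearest and within
        assert res.pairs[0][:2] == ("t1", "c1")

    def test_outside_caliper_unmatched(self):
        sa = pd.Series({"t1": 0.50})
        sb = pd.Series({"c1": 0.60})
        res = match(sa, sb, caliper_fraction=0.5)  # caliper = 0.5 * SD ~= 0.029 < 0.1
        assert res.pairs == []
        assert res.unmatched_treated == ["t1"]

    @pytest.mark.parametrize("seed", range(10))
    def test_greedy_equals_independent_oracle_on_5x5(self, seed):
        rng = np.random.default_rng(seed)
        sa = {f"a{i}": float(rng.random()) for i in range(5)}
        sb = {f"b{i}": float(rng.random()) for i in range(5)}
        res = match(sa, sb, caliper_fraction=0.8)
        expected = _naive_greedy(sa, sb, res.caliper)
        assert [(t, c) for t, c, _ in res.pairs] == expected

    @pytest.mark.parametrize("seed", range(5))
    def test_caliper_respected_and_controls_unique(self, seed):
        rng = np.random.default_rng(100 + seed)
        sa = {f"a{i}": float(rng.random()) for i in range(40)}
        sb = {f"b{i}": float(rng.random()) for i in range(60)}
        res = match(sa, sb)
        assert all(d <= res.caliper for _, _, d in res.pairs)
        controls = [c for _, c, _ in res.pairs]
        assert len(controls) == len(set(controls))

    def test_empty_cohort_raises(self):
        with pytest.raises(ValueError):
            match({}, {"c1": 0.5})


class TestBalance:
    def test_identical_cohorts_zero_smd(self):
        f = pd.DataFrame({"x": [1.0, 2.0, 3.0], "y": [0.0, 1.0, 0.0]})
        smd = standardized_mean_differences(f, f.copy())
        assert (smd == 0).all()

    def test_constant_feature_zero_by_convention(self):
        fa = pd.DataFrame({"x": [1.0, 1.0]})
        fb = pd.DataFrame({"x": [1.0, 1.0, 1.0]})
        assert standardized_mean_differences(fa, fb)["x"] == 0.0

    def test_matching_improves_balance_on_confounded_cohorts(self):
        """Business-hours cohorts differ in engagement covariates by design;
        matching should shrink the mean absolute SMD."""
        sessions = generate_sessions(default_config(1800, seed=13))
        included, _ = filter_corpus(sessions, "stress")
        a, b, _ = split_cohorts(included, "business_hours")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result, _, _ = match_cohorts(a, b, "stress")
        before = result.balance["smd_before"].abs().mean()
        after = result.balance["smd_after"].abs().mean()
        assert after <= before

    def test_no_pairs_raises(self):
        res = match({"t1": 0.1}, {"c1": 0.9}, caliper_fraction=0.01)
        with pytest.raises(ValueError):
            balance_diagnostics(res, [], [], "stress")
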