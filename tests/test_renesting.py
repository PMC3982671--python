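"""Renesting timing: inflection recovery, standardization, opportunity test."""

import numpy as np
import pandas as pd
import pytest

from kinfitness.config import SimulationConfig
from kinfitness.renesting import (
    InflectionEstimate,
    RenestingAnalysisError,
    analyze_attempts,
    annual_termination_date,
    opportunity_cost_test,
    relative_failure_dates,
    renesting_inflection,
    termination_dates_by_year,
)
from kinfitness.simulate import simulate_attempts_table

CFG = SimulationConfig()


class TestAnnualTermination:
    def test_recovery_within_three_days(self):
        truth = (120.0,)
        att = simulate_attempts_table(200, truth, CFG, seed=81)
        est = annual_termination_date(att)
        assert est.date == pytest.approx(120.0, abs=3.0)
        assert est.se > 0

    def test_identical_data_identical_estimate(self):
        att = simulate_attempts_table(150, (100.0,), CFG, seed=82)
        a = annual_termination_date(att)
        b = annual_termination_date(att.copy())
        assert a.date == b.date and a.se == b.se

    def test_constant_outcome_rejected(self):
        att = simulate_attempts_table(50, (100.0,), CFG, seed=83)
        att["outcome"] = "renested"
        with pytest.raises(RenestingAnalysisError, match="constant"):
            annual_termination_date(att)

    def test_separated_data_falls_back_to_penalized_fit(self):
        """A step at day d still yields an inflection within (d-1, d+1)."""
        d = 100.0
        dates = np.concatenate([np.linspace(80, 99.5, 40), np.linspace(100.5, 120, 40)])
        att = pd.DataFrame(
            {
                "male_id": [f"m{k}" for k in range(80)],
                "year": 0,
                "failure_date": dates,
                "outcome": ["renested"] * 40 + ["terminated"] * 40,
            }
        )
        est = annual_termination_date(att)
        assert est.method == "firth"
        assert d - 1 < est.date < d + 1

    def test_positive_slope_warns(self):
        rng = np.random.default_rng(84)
        dates = rng.uniform(80, 120, 100)
        # inverted: renesting MORE likely late in the season
        renest = rng.random(100) < 1 / (1 + np.exp(-(dates - 100) * 0.3))
        att = pd.DataFrame(
            {
                "male_id": "m",
                "year": 0,
                "failure_date": dates,
                "outcome": np.where(renest, "renested", "terminated"),
            }
        )
        with pytest.warns(UserWarning, match="inverted"):
            annual_termination_date(att)

    def test_early_failures_excluded_by_median_lay_date(self):
        att = simulate_attempts_table(100, (100.0,), CFG, seed=85)
        att["year_median_lay"] = 90.0
        est = annual_termination_date(att)
        assert est.n == (att["failure_date"] >= 90.0).sum()


class TestRelativeDates:
    def test_simple_offsets(self):
        att = pd.DataFrame(
            {
                "male_id": ["a", "b"],
                "year": [0, 0],
                "failure_date": [130.0, 120.0],
                "outcome": ["renested", "terminated"],
                "became_helper": [False, True],
            }
        )
        std = relative_failure_dates(att, {0: 120.0})
        assert list(std["relative_failure_date"]) == [110.0, 100.0]

    def test_missing_year_rejected(self):
        att = simulate_attempts_table(20, (100.0, 105.0), CFG, seed=86)
        with pytest.raises(RenestingAnalysisError, match="termination date"):
            relative_failure_dates(att, {0: 100.0})

    def test_group_means_shift_by_per_year_offsets(self):
        truth = (95.0, 105.0, 100.0)
        att = simulate_attempts_table(50, truth, CFG, seed=87)
        std = relative_failure_dates(att, {y: t for y, t in enumerate(truth)})
        for y, t in enumerate(truth):
            sub = std[std["year"] == y]
            raw = sub["failure_date"].mean()
            assert sub["relative_failure_date"].mean() == pytest.approx(
                raw - t + 100.0, abs=1e-9
            )

    def test_offset_invariance(self):
        """Shifting a year's dates shifts its termination date equally and
        leaves relative dates unchanged."""
        att = simulate_attempts_table(300, (100.0,), CFG, seed=88)
        est0 = annual_termination_date(att)
        shifted = att.copy()
        shifted["failure_date"] = shifted["failure_date"] + 17.0
        shifted["year_median_lay"] = shifted["year_median_lay"] + 17.0
        est1 = annual_termination_date(shifted)
        assert est1.date == pytest.approx(est0.date + 17.0, abs=1e-6)
        r0 = relative_failure_dates(att, {0: est0.date})["relative_failure_date"]
        r1 = relative_failure_dates(shifted, {0: est1.date})["relative_failure_date"]
        np.testing.assert_allclose(r0.to_numpy(), r1.to_numpy(), atol=1e-6)


class TestInflectionsAndOpportunityCost:
    def test_overall_between_groups(self):
        att = simulate_attempts_table(400, (100.0, 96.0), CFG, seed=89)
        t = termination_dates_by_year(att)
        std = relative_failure_dates(att, t)
        overall = renesting_inflection(std, "all").date
        h = renesting_inflection(std, "helpers").date
        nh = renesting_inflection(std, "non_helpers").date
        assert min(h, nh) - 0.5 <= overall <= max(h, nh) + 0.5

    def test_null_difference_not_flagged(self):
        rep = opportunity_cost_test(
            InflectionEstimate(97.2, 0.93, 0, -1, 400, "ml"),
            InflectionEstimate(96.2, 0.91, 0, -1, 450, "ml"),
        )
        assert rep.difference == pytest.approx(1.0)
        assert not rep.cost_detected
        assert rep.verdict == "no opportunity cost detected"

    def test_identical_estimates_zero_difference(self):
        e = InflectionEstimate(100.0, 0.5, 0, -1, 100, "ml")
        rep = opportunity_cost_test(e, e)
        assert rep.difference == 0.0
        assert not rep.cost_detected

    def test_clear_separation_flags_cost(self):
        rep = opportunity_cost_test(
            InflectionEstimate(95.0, 0.5, 0, -1, 100, "ml"),
            InflectionEstimate(105.0, 0.5, 0, -1, 100, "ml"),
        )
        assert rep.difference == pytest.approx(-10.0)
        assert rep.cost_detected

    def test_shifted_generator_difference_detected(self):
        att = simulate_attempts_table(400, (100.0,), CFG, seed=90, helper_shift=-10.0)
        t = termination_dates_by_year(att)
        std = relative_failure_dates(att, t)
        rep = opportunity_cost_test(
            renesting_inflection(std, "helpers"),
            renesting_inflection(std, "non_helpers"),
        )
        assert rep.cost_detected


class TestFullAnalysis:
    def test_mae_under_two_days(self):
        truth = tuple(100.0 + 5 * np.sin(k) for k in range(5))
        att = simulate_attempts_table(200, truth, CFG, seed=91)
        out = analyze_attempts(att)
        errs = [
            abs(out["termination_dates"][y]["date"] - truth[y])
            for y in out["termination_dates"]
        ]
        assert np.mean(errs) < 2.0

    def test_null_generator_yields_no_cost_verdict(self):
        att = simulate_attempts_table(300, (98.0, 102.0, 100.0), CFG, seed=92)
        out = analyze_attempts(att)
        assert out["opportunity_cost"]["verdict"] == "no opportunity cost detected"
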