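"""Cohort update: class split, mortality adjustment, cycle mechanics."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import ckdflow as ck
from ckdflow.config import UncertainParam
from ckdflow.model import (MortalitySchedule, StageStocks, adjusted_probability,
                           baseline_death_probability, class_split,
                           incident_inflow, initialize_stocks, step_cohort)
from ckdflow.stages import CLASSES, STAGES


def _uniform_schedule(value):
    return pd.DataFrame({c: [value] * 4 for c in CLASSES}, index=list(STAGES))


def _uniform_mortality(p, esrd=0.0):
    return MortalitySchedule(probability=np.full((4, 3), p), esrd_mortality=esrd)


NO_SPLIT = {"slow": 1.0, "medium": 0.0, "fast": 0.0}


class TestClassSplit:
    def test_stage_3a_composition(self):
        split = class_split(0.312, 0.355)
        assert split["fast"] == pytest.approx(0.312 * 0.355)
        assert split["medium"] == pytest.approx(0.312 * 0.645)
        assert split["slow"] == pytest.approx(0.688)

    def test_no_diabetes_means_slow(self):
        assert class_split(0.0, 0.9)["slow"] == 1.0

    def test_diabetes_with_albuminuria_means_fast(self):
        assert class_split(1.0, 1.0)["fast"] == 1.0

    @given(dm=st.floats(0, 1), alb=st.floats(0, 1))
    def test_shares_sum_to_one(self, dm, alb):
        assert sum(class_split(dm, alb).values()) == pytest.approx(1.0)

    def test_domain_enforced(self):
        with pytest.raises(ValueError, match="dm_prev"):
            class_split(1.2, 0.5)


class TestMortality:
    def test_unit_hazard_ratio_is_identity(self):
        assert adjusted_probability(0.0158, 1.0) == pytest.approx(0.0158)

    def test_stage5_uses_published_hr(self, params):
        p0 = baseline_death_probability(params)
        expected = 1.0 - (1.0 - p0) ** 4.06
        assert ck.mortality_probability(params, "5", False) == pytest.approx(expected)

    def test_small_probability_scales_linearly(self):
        # hazard-scale adjustment ~ HR * p0 for small p0; the continuous
        # two-state oracle is p = 1 - exp(-HR * rate), rate = -ln(1 - p0)
        p0, hr = 0.01, 2.27
        p = adjusted_probability(p0, hr)
        oracle = 1.0 - math.exp(-hr * -math.log1p(-p0))
        assert p == pytest.approx(oracle, rel=1e-12)
        assert p == pytest.approx(hr * p0, rel=0.05)

    def test_nonpositive_hr_rejected(self):
        with pytest.raises(ValueError, match="hazard ratio"):
            adjusted_probability(0.1, 0.0)


class TestStepCohort:
    def test_hand_worked_single_cycle(self):
        stocks = StageStocks(
            ckd=np.array([[1000.0, 0, 0], [0, 0, 0], [0, 0, 0], [0, 0, 0]]),
            eskd=0.0, eskd_dm=0.0)
        out = step_cohort(stocks, _uniform_schedule(0.052),
                          _uniform_mortality(0.01), inflow_3a=0.0,
                          entrant_split=NO_SPLIT)
        assert out.ckd[0, 0] == pytest.approx(1000 * 0.99 * (1 - 0.052))
        assert out.ckd[1, 0] == pytest.approx(1000 * 0.99 * 0.052)
        assert out.dead == pytest.approx(10.0)

    def test_fixed_point_with_no_flows(self):
        stocks = StageStocks(ckd=np.full((4, 3), 7.0), eskd=5.0, eskd_dm=2.0)
        out = step_cohort(stocks, _uniform_schedule(0.0),
                          _uniform_mortality(0.0), 0.0, NO_SPLIT)
        np.testing.assert_array_equal(out.ckd, stocks.ckd)
        assert (out.eskd, out.eskd_dm, out.dead) == (5.0, 2.0, 0.0)

    def test_persons_conserved_up_to_inflow(self):
        rng = np.random.default_rng(0)
        stocks = StageStocks(ckd=rng.uniform(0, 1000, (4, 3)), eskd=400.0,
                             eskd_dm=100.0)
        out = step_cohort(stocks, _uniform_schedule(0.1),
                          _uniform_mortality(0.03, esrd=0.1), 123.0,
                          {"slow": 0.5, "medium": 0.3, "fast": 0.2})
        assert out.total == pytest.approx(stocks.total + 123.0, rel=1e-12)

    def test_stage5_exits_reach_eskd_with_dm_accounting(self):
        ckd = np.zeros((4, 3))
        ckd[3] = [100.0, 50.0, 50.0]
        stocks = StageStocks(ckd=ckd, eskd=0.0, eskd_dm=0.0)
        out = step_cohort(stocks, _uniform_schedule(0.2),
                          _uniform_mortality(0.0), 0.0, NO_SPLIT)
        assert out.eskd == pytest.approx(0.2 * 200.0)
        assert out.eskd_dm == pytest.approx(0.2 * 100.0)   # medium+fast only

    def test_partial_rrt_uptake_keeps_remainder_in_stage5(self):
        ckd = np.zeros((4, 3))
        ckd[3, 0] = 100.0
        stocks = StageStocks(ckd=ckd, eskd=0.0, eskd_dm=0.0)
        out = step_cohort(stocks, _uniform_schedule(0.2),
                          _uniform_mortality(0.0), 0.0, NO_SPLIT,
                          rrt_uptake=0.5)
        assert out.eskd == pytest.approx(10.0)
        assert out.ckd[3, 0] == pytest.approx(90.0)

    def test_negative_inflow_rejected(self):
        stocks = StageStocks(ckd=np.zeros((4, 3)), eskd=0.0, eskd_dm=0.0)
        with pytest.raises(ValueError, match="inflow"):
            step_cohort(stocks, _uniform_schedule(0.0),
                        _uniform_mortality(0.0), -1.0, NO_SPLIT)


class TestInflow:
    def test_worked_example(self, params):
        p = dataclasses.replace(params, incidence_population=6_866_711.0)
        assert incident_inflow(p, 0) == pytest.approx(9133, abs=1)

    def test_constant_without_growth(self, params):
        p = dataclasses.replace(params, adult_growth_rate=0.0)
        assert incident_inflow(p, 17) == incident_inflow(p, 0)

    def test_compound_growth_ratio(self, params):
        ratio = incident_inflow(params, 20) / incident_inflow(params, 0)
        assert ratio == pytest.approx(1.01 ** 20, rel=1e-12)


class TestInitialization:
    def test_anchor_counts(self, params):
        stocks = initialize_stocks(params)
        assert stocks.stage_count("3a") == pytest.approx(260_935)
        assert stocks.eskd == pytest.approx(24_601)
        assert stocks.dead == 0.0

    def test_prevalence_fallback(self, params):
        p = dataclasses.replace(params, initial_stage_counts=None)
        stocks = initialize_stocks(p)
        assert stocks.stage_count("3a") == pytest.approx(0.038 * 6_866_711)

    def test_stage5_has_no_medium_class(self, params):
        stocks = initialize_stocks(params)
        assert stocks.ckd[3, CLASSES.index("medium")] == 0.0

    def test_zero_prevalence_gives_empty_stocks(self, params):
        zero = {s: UncertainParam.fixed(0.0) for s in STAGES}
        p = dataclasses.replace(params, stage_prevalence=zero,
                                initial_stage_counts=None)
        assert initialize_stocks(p).ckd.sum() == 0.0


class TestProjection:
    def test_total_ckd_grows_monotonically(self, baseline_run):
        totals = baseline_run.counts["total_ckd"].to_numpy()
        assert np.all(np.diff(totals) > 0)

    def test_conservation_each_cycle(self, params, baseline_run):
        stocks = baseline_run.stocks
        for t in range(len(stocks) - 1):
            expected = stocks[t].total + incident_inflow(params, t)
            assert stocks[t + 1].total == pytest.approx(expected, rel=1e-6)

    def test_dead_is_absorbing(self, baseline_run):
        dead = baseline_run.counts["Dead"].to_numpy()
        assert np.all(np.diff(dead) >= 0)

    def test_no_backward_flow_without_inflow(self, params, costs):
        # with inflow and mortality off, a stage can only lose to the next
        p = dataclasses.replace(
            params,
            incidence_3a=UncertainParam.fixed(0.0),
            mortality_by_age={b: 0.0 for b in params.mortality_by_age},
            esrd_mortality=UncertainParam.fixed(0.0))
        res = ck.run_projection(p, costs, horizon=5)
        assert np.all(np.diff(res.counts["3a"].to_numpy()) <= 1e-9)
        assert np.all(np.diff(res.counts["ESKD"].to_numpy()) >= -1e-9)

    def test_homogeneity_in_stocks_and_inflow(self, params, costs, baseline_run):
        doubled = dataclasses.replace(
            params,
            initial_stage_counts={s: 2 * c
                                  for s, c in params.initial_stage_counts.items()},
            esrd_initial_count=2 * params.esrd_initial_count,
            incidence_population=2 * params.incidence_population)
        res2 = ck.run_projection(doubled, costs)
        np.testing.assert_allclose(res2.counts.to_numpy(),
                                   2 * baseline_run.counts.to_numpy(),
                                   rtol=1e-9)

    def test_horizon_one_equals_single_step(self, params, costs, baseline_run):
        res = ck.run_projection(params, costs, horizon=1)
        pd.testing.assert_series_equal(res.counts.iloc[1],
                                       baseline_run.counts.iloc[1],
                                       check_names=False)

    def test_cycle_order_switch_changes_first_year_exposure(self, params, costs):
        alt = dataclasses.replace(params, cycle_order="progression_first")
        res_alt = ck.run_projection(alt, costs, horizon=5)
        res = ck.run_projection(params, costs, horizon=5)
        assert not np.allclose(res_alt.counts.to_numpy(), res.counts.to_numpy())

    def test_tidy_export_round_trips_totals(self, baseline_run):
        tidy = baseline_run.counts_tidy()
        by_year = (tidy[tidy["state"] != "Dead"]
                   .groupby("year")["count"].sum())
        np.testing.assert_allclose(by_year.to_numpy(),
                                   baseline_run.counts["total_ckd"].to_numpy(),
                                   rtol=1e-12)
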