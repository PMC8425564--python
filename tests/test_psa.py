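"""Distribution builders and the Monte Carlo uncertainty propagation."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import ckdflow as ck
from ckdflow.config import UncertainParam
from ckdflow.psa import (InfeasibleCIError, ParameterDraws, PsaConfig,
                         beta_from_mean_ci, draw_parameters, gamma_from_mean_ci,
                         normal_from_mean_ci, run_psa, sample_param)
from ckdflow.scenarios import baseline_scenario
from ckdflow.stages import STAGES

RNG = np.random.default_rng


class TestBetaBuilder:
    def test_symmetric_case_moment_match(self):
        a, b = beta_from_mean_ci(0.5, 0.25, 0.75)
        assert a == pytest.approx(b)
        assert a == pytest.approx(7.18, abs=0.05)
        # sampled moments recover the target
        draws = RNG(0).beta(a, b, size=1_000_000)
        assert draws.mean() == pytest.approx(0.5, abs=0.001)

    def test_stage_3a_prevalence_quantile_recovery(self):
        a, b = beta_from_mean_ci(0.038, 0.029, 0.049)
        draws = RNG(1).beta(a, b, size=1_000_000)
        lo, hi = np.percentile(draws, [2.5, 97.5])
        assert lo == pytest.approx(0.029, abs=0.003)
        assert hi == pytest.approx(0.049, abs=0.003)

    def test_infeasible_ci_rejected(self):
        # sigma^2 from the CI exceeds mean(1-mean): no Beta has these moments
        with pytest.raises(InfeasibleCIError):
            beta_from_mean_ci(0.01, 0.0, 0.5)

    def test_degenerate_parameter_is_point_mass(self):
        p = UncertainParam.fixed(0.3)
        assert sample_param(p, RNG(0)) == 0.3


class TestNormalBuilder:
    def test_sigma_from_ci_width(self):
        mu, sigma = normal_from_mean_ci(0.71, 0.57, 0.89)
        assert mu == 0.71
        assert sigma == pytest.approx(0.0816, abs=2e-4)

    def test_quantile_recovery(self):
        # the builder centres the normal on the printed mean, so its
        # implied 95% interval is mu +- 1.96 sigma; the printed CI is
        # asymmetric about the mean and recovered only up to that shift
        mu, sigma = normal_from_mean_ci(0.71, 0.57, 0.89)
        draws = RNG(2).normal(mu, sigma, size=1_000_000)
        lo, hi = np.percentile(draws, [2.5, 97.5])
        assert lo == pytest.approx(mu - 1.96 * sigma, abs=0.01)
        assert hi == pytest.approx(mu + 1.96 * sigma, abs=0.01)
        assert hi - lo == pytest.approx(0.89 - 0.57, abs=0.01)

    def test_draws_floored_at_positive_value(self):
        p = UncertainParam(0.01, 0.0, 1.0, family="normal")
        draws = [sample_param(p, RNG(s)) for s in range(200)]
        assert min(draws) > 0.0

    def test_disordered_ci_rejected(self):
        with pytest.raises(ValueError):
            normal_from_mean_ci(0.5, 0.9, 0.1)


class TestGammaBuilder:
    def test_twenty_percent_rule_shape_is_universal(self):
        shape, scale = gamma_from_mean_ci(48.76)
        assert shape == pytest.approx((1.96 / 0.2) ** 2, rel=1e-12)
        assert shape * scale == pytest.approx(48.76, rel=1e-12)

    def test_sampled_mean_recovers_target(self):
        shape, scale = gamma_from_mean_ci(48.76)
        draws = RNG(3).gamma(shape, scale, size=1_000_000)
        assert draws.mean() == pytest.approx(48.76, abs=0.1)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            gamma_from_mean_ci(0.0)


def _degenerate(registry):
    """Registry copy with every uncertain parameter fixed at its mean."""
    params, costs = registry

    def fix(p):
        return UncertainParam.fixed(p.mean) if p is not None else None

    params = dataclasses.replace(
        params,
        stage_prevalence={s: fix(p) for s, p in params.stage_prevalence.items()},
        albuminuria_by_stage={s: fix(p)
                              for s, p in params.albuminuria_by_stage.items()},
        dm_prevalence_ckd=fix(params.dm_prevalence_ckd),
        incidence_3a=fix(params.incidence_3a),
        mortality_hr={k: fix(p) for k, p in params.mortality_hr.items()},
        esrd_mortality=fix(params.esrd_mortality),
        sglt2_hr=fix(params.sglt2_hr),
        predialysis_hr=fix(params.predialysis_hr),
        dm_incidence=fix(params.dm_incidence))
    costs = dataclasses.replace(
        costs,
        annual_cost_by_stage={s: fix(p)
                              for s, p in costs.annual_cost_by_stage.items()},
        dm_addon=fix(costs.dm_addon), sglt2_cost=fix(costs.sglt2_cost),
        predialysis_cost_s4=fix(costs.predialysis_cost_s4),
        predialysis_cost_s5=fix(costs.predialysis_cost_s5))
    return params, costs


class TestRunPsa:
    def test_all_fixed_collapses_to_deterministic(self, registry, baseline_run):
        params, costs = _degenerate(registry)
        psa = run_psa(params, costs, baseline_scenario(),
                      PsaConfig(n_iterations=3, seed=0))
        cases = psa.summary[psa.summary["metric"] == "cases"]
        total = cases[cases["state"] == "total_ckd"].set_index("year")
        for year in (2021, 2041):
            det = baseline_run.counts.loc[year, "total_ckd"]
            row = total.loc[year]
            assert row["mean"] == pytest.approx(det, rel=1e-12)
            assert row["ui_low"] == pytest.approx(row["ui_high"], rel=1e-12)

    def test_same_seed_bitwise_identical(self, registry):
        params, costs = registry
        cfg = PsaConfig(n_iterations=20, seed=42)
        s1 = run_psa(params, costs, baseline_scenario(), cfg).summary
        s2 = run_psa(params, costs, baseline_scenario(), cfg).summary
        pd.testing.assert_frame_equal(s1, s2)
        assert (s1["mean"].to_numpy() == s2["mean"].to_numpy()).all()

    def test_ui_ordering_everywhere(self, registry):
        params, costs = registry
        psa = run_psa(params, costs, baseline_scenario(),
                      PsaConfig(n_iterations=60, seed=7))
        assert (psa.summary["ui_low"] <= psa.summary["mean"] + 1e-9).all()
        assert (psa.summary["mean"] <= psa.summary["ui_high"] + 1e-9).all()

    def test_ui_band_converges_from_below(self, registry):
        # percentile bands from a handful of draws are biased narrow;
        # the band widens toward the true 2.5-97.5 span as n grows
        params, costs = registry
        def width(n):
            psa = run_psa(params, costs, baseline_scenario(),
                          PsaConfig(n_iterations=n, seed=11))
            sub = psa.summary
            row = sub[(sub["state"] == "total_ckd") & (sub["year"] == 2041)
                      & (sub["metric"] == "cases")].iloc[0]
            return row["ui_high"] - row["ui_low"]
        assert width(8) < width(400)

    def test_shared_sglt2_draw_across_stages(self, registry):
        params, costs = registry
        spec = ck.intervention_scenario(params, costs)
        draws = draw_parameters(params, costs, spec, RNG(5))
        assert (draws.scenario_hr[("3a", "dm_only")]
                == draws.scenario_hr[("3b", "dm_only")])
        assert (draws.scenario_hr[("4", "all")]
                == draws.scenario_hr[("5", "all")])

    def test_config_validation(self):
        with pytest.raises(ValueError):
            PsaConfig(n_iterations=0)
        with pytest.raises(ValueError):
            PsaConfig(percentiles=(97.5, 2.5))
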