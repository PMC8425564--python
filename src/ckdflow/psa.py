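"""Probabilistic sensitivity analysis.

Each uncertain parameter carries a mean and 95% CI; the PSA rebuilds a
sampling distribution per parameter (Beta for probabilities/proportions,
Normal for hazard ratios, Gamma for costs), draws every parameter
independently each iteration, reruns the projection, and summarises the
pointwise mean and percentile uncertainty interval of every (year, state)
count and cost.  The CI-to-sigma conversion assumes normal-approximate
95% coverage (sigma = width / 3.92).  Each iteration consumes its own
random stream spawned from the master seed, so results are reproducible
and independent of iteration order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import CostTable, ParameterSet, UncertainParam
from .model import run_projection
from .scenarios import ScenarioSpec
from .stages import ESKD, STAGES

_HR_FLOOR = 1e-6


class InfeasibleCIError(ValueError):
    """CI implies a variance no Beta distribution can attain."""


def beta_from_mean_ci(mean: float, lo: float, hi: float) -> tuple[float, float]:
    """Beta shape parameters by moment matching of mean and CI width."""
    if not (0.0 < mean < 1.0):
        raise ValueError(f"beta mean must lie in (0, 1), got {mean}")
    if not (0.0 <= lo <= mean <= hi <= 1.0):
        raise ValueError(f"require 0 <= lo <= mean <= hi <= 1, got "
                         f"({lo}, {mean}, {hi})")
    sigma = (hi - lo) / (2 * 1.96)
    var = sigma * sigma
    if var >= mean * (1.0 - mean):
        raise InfeasibleCIError(
            f"CI width implies variance {var:.4g} >= mean(1-mean) "
            f"= {mean * (1 - mean):.4g}; no Beta matches"
        )
    nu = mean * (1.0 - mean) / var - 1.0
    alpha = mean * nu
    beta = (1.0 - mean) * nu
    return alpha, beta


def normal_from_mean_ci(mean: float, lo: float, hi: float) -> tuple[float, float]:
    """Normal (mu, sigma) from mean and a symmetric-treatment 95% CI."""
    if hi < lo:
        raise ValueError(f"require lo <= hi, got ({lo}, {hi})")
    return mean, (hi - lo) / (2 * 1.96)


def gamma_from_mean_ci(mean: float, lo: float | None = None,
                       hi: float | None = None) -> tuple[float, float]:
    """Gamma (shape, scale) from mean and CI; defaults to the +-20% rule."""
    if mean <= 0:
        raise ValueError(f"gamma mean must be > 0, got {mean}")
    if lo is None or hi is None:
        lo, hi = 0.8 * mean, 1.2 * mean
    sigma = (hi - lo) / (2 * 1.96)
    if sigma <= 0:
        raise ValueError("gamma CI must have positive width")
    shape = mean * mean / (sigma * sigma)
    scale = sigma * sigma / mean
    return shape, scale


def sample_param(p: UncertainParam, rng: np.random.Generator) -> float:
    """One draw from a parameter's PSA distribution (point mass if fixed)."""
    if p.family == "fixed" or p.is_degenerate:
        return p.mean
    if p.family == "beta":
        a, b = beta_from_mean_ci(p.mean, p.ci_low, p.ci_high)
        return float(rng.beta(a, b))
    if p.family == "normal":
        mu, sigma = normal_from_mean_ci(p.mean, p.ci_low, p.ci_high)
        draw = float(rng.normal(mu, sigma))
        # hazard ratios must stay positive: truncate at a small floor
        return max(draw, _HR_FLOOR)
    if p.family == "gamma":
        shape, scale = gamma_from_mean_ci(p.mean, p.ci_low, p.ci_high)
        return float(rng.gamma(shape, scale))
    raise ValueError(f"unknown family {p.family!r}")   # pragma: no cover


@dataclass(frozen=True)
class PsaConfig:
    n_iterations: int = 10_000
    seed: int = 0
    percentiles: tuple[float, float] = (2.5, 97.5)

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        lo, hi = self.percentiles
        if not (0.0 < lo < hi < 100.0):
            raise ValueError("percentiles must be strictly ordered within (0, 100)")


@dataclass
class ParameterDraws:
    """Sampled parameter values overriding the registry means for one run."""

    prevalence_scale: dict[str, float]
    albuminuria: dict[str, float]
    dm_prevalence: float
    incidence: float
    mortality_hr: dict[tuple[str, bool], float]
    esrd_mortality: float
    scenario_hr: dict[tuple[str, str], float]
    stage_costs: dict[str, float]
    dm_addon: float
    added_costs: dict[tuple[str, str], float]

    def cost_table(self, costs: CostTable) -> CostTable:
        fixed = UncertainParam.fixed
        return CostTable(
            annual_cost_by_stage={s: fixed(v) for s, v in self.stage_costs.items()},
            dm_addon=fixed(self.dm_addon),
            sglt2_cost=costs.sglt2_cost,
            predialysis_cost_s4=costs.predialysis_cost_s4,
            predialysis_cost_s5=costs.predialysis_cost_s5,
        )

    def scenario_with_costs(self, spec: ScenarioSpec) -> ScenarioSpec:
        if not spec.added_costs:
            return spec
        fixed = UncertainParam.fixed
        return ScenarioSpec(
            name=spec.name,
            progression_hr=dict(spec.progression_hr),
            added_costs={k: fixed(self.added_costs[k])
                         for k in spec.added_costs},
        )


def draw_parameters(params: ParameterSet, costs: CostTable,
                    scenario: ScenarioSpec,
                    rng: np.random.Generator) -> ParameterDraws:
    """Draw every non-degenerate uncertain parameter once.

    Scenario hazard ratios that share one underlying parameter (the SGLT2
    HR applies to both stage 3a and 3b) receive a single common draw.
    """
    prev_scale = {}
    for s in STAGES:
        p = params.stage_prevalence[s]
        prev_scale[s] = sample_param(p, rng) / p.mean if p.mean > 0 else 1.0
    alb = {s: sample_param(params.albuminuria_by_stage[s], rng) for s in STAGES}
    dm = sample_param(params.dm_prevalence_ckd, rng)
    incidence = sample_param(params.incidence_3a, rng)
    hr = {key: sample_param(p, rng) for key, p in params.mortality_hr.items()}
    esrd_m = sample_param(params.esrd_mortality, rng)
    shared: dict[int, float] = {}
    scen_hr = {}
    for key, p in scenario.progression_hr.items():
        if id(p) not in shared:
            shared[id(p)] = sample_param(p, rng)
        scen_hr[key] = shared[id(p)]
    stage_costs = {s: sample_param(p, rng)
                   for s, p in costs.annual_cost_by_stage.items()}
    dm_addon = sample_param(costs.dm_addon, rng)
    shared_costs: dict[int, float] = {}
    added = {}
    for key, p in scenario.added_costs.items():
        if id(p) not in shared_costs:
            shared_costs[id(p)] = sample_param(p, rng)
        added[key] = shared_costs[id(p)]
    return ParameterDraws(
        prevalence_scale=prev_scale, albuminuria=alb, dm_prevalence=dm,
        incidence=incidence, mortality_hr=hr, esrd_mortality=esrd_m,
        scenario_hr=scen_hr, stage_costs=stage_costs, dm_addon=dm_addon,
        added_costs=added,
    )


@dataclass
class PsaResult:
    """Pointwise mean and percentile UI of counts and costs."""

    scenario: str
    n_iterations: int
    seed: int
    percentiles: tuple[float, float]
    summary: pd.DataFrame    # year, scenario, state, metric, mean, ui_low, ui_high

    def metric(self, metric: str) -> pd.DataFrame:
        """Wide mean table of one metric (years x states)."""
        sub = self.summary[self.summary["metric"] == metric]
        return sub.pivot(index="year", columns="state", values="mean")


def run_psa(params: ParameterSet, costs: CostTable, scenario: ScenarioSpec,
            psa_config: PsaConfig) -> PsaResult:
    """Monte Carlo propagation of parameter uncertainty.

    Identical configuration and seed give bitwise-identical summaries.
    """
    n = psa_config.n_iterations
    streams = np.random.SeedSequence(psa_config.seed).spawn(n)
    count_states = list(STAGES) + [ESKD, "total_ckd"]
    cases = np.empty((n, params.horizon_years + 1, len(count_states)))
    cost_states = list(STAGES) + [ESKD, "total", "total_discounted"]
    cost_arr = np.empty((n, params.horizon_years + 1, len(cost_states)))
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        draws = draw_parameters(params, costs, scenario, rng)
        res = run_projection(params, costs, scenario, draws=draws)
        cases[i] = res.counts[count_states].to_numpy()
        per_state = res.costs[list(STAGES) + [ESKD]].to_numpy()
        cost_arr[i] = np.column_stack([per_state,
                                       res.cost_totals["total"].to_numpy(),
                                       res.cost_totals["total_discounted"].to_numpy()])
    years = np.arange(params.start_year, params.start_year + params.horizon_years + 1)
    lo_q, hi_q = psa_config.percentiles
    rows = []
    for arr, states, metric in ((cases, count_states, "cases"),
                                (cost_arr, cost_states, "cost_gbp")):
        mean = arr.mean(axis=0)
        low = np.percentile(arr, lo_q, axis=0)
        high = np.percentile(arr, hi_q, axis=0)
        for yi, year in enumerate(years):
            for si, state in enumerate(states):
                rows.append((int(year), scenario.name, state, metric,
                             mean[yi, si], low[yi, si], high[yi, si]))
    summary = pd.DataFrame(rows, columns=["year", "scenario", "state", "metric",
                                          "mean", "ui_low", "ui_high"])
    return PsaResult(scenario=scenario.name, n_iterations=n,
                     seed=psa_config.seed, percentiles=psa_config.percentiles,
                     summary=summary)
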