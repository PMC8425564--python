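"""Yearly stock-and-flow update of the CKD cohort.

Each 1-year cycle applies, in order: (1) mortality in every living state,
(2) one-directional stage progression of the survivors at the
class-specific exit fraction (stage-5 progressors start RRT), and
(3) the incident stage-3a inflow, split across progression classes by the
diabetes/albuminuria composition.  Stocks are real-valued compartments;
death is absorbing.  The alternative ordering (progression before
mortality) is configurable for sensitivity checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import CostTable, ParameterSet
from .egfr import EgfrDensityFit, build_transition_schedule
from .stages import CLASSES, DEAD, ESKD, STAGES

_N_STAGES = len(STAGES)
_N_CLASSES = len(CLASSES)
# Column index of the first diabetic class (medium); slow = no diabetes.
_DM_SLICE = slice(1, None)


@dataclass
class StageStocks:
    """Population counts per model state.

    ``ckd`` has shape (4 stages, 3 classes); diabetes status is encoded by
    the class (slow = no diabetes, medium/fast = diabetes), so the
    diabetic sub-stock of a stage is its medium + fast counts.  The ESKD
    stock is unclassed but keeps its diabetic sub-count for costing.
    """

    ckd: np.ndarray                  # (stage, class) persons
    eskd: float
    eskd_dm: float
    dead: float = 0.0

    def __post_init__(self) -> None:
        self.ckd = np.asarray(self.ckd, dtype=float)
        if self.ckd.shape != (_N_STAGES, _N_CLASSES):
            raise ValueError(f"ckd must have shape (4, 3), got {self.ckd.shape}")
        if np.any(self.ckd < -1e-9) or self.eskd < -1e-9 or self.dead < -1e-9:
            raise ValueError("negative stock")
        if not (0.0 - 1e-9 <= self.eskd_dm <= self.eskd + 1e-9):
            raise ValueError("eskd_dm must lie in [0, eskd]")

    def stage_count(self, stage: str) -> float:
        return float(self.ckd[STAGES.index(stage)].sum())

    def stage_dm_count(self, stage: str) -> float:
        return float(self.ckd[STAGES.index(stage), _DM_SLICE].sum())

    @property
    def total_ckd(self) -> float:
        """Living CKD burden: stages 3a-5 plus ESKD."""
        return float(self.ckd.sum() + self.eskd)

    @property
    def total(self) -> float:
        """All persons ever in the model, including the dead."""
        return self.total_ckd + self.dead

    def copy(self) -> "StageStocks":
        return StageStocks(ckd=self.ckd.copy(), eskd=self.eskd,
                           eskd_dm=self.eskd_dm, dead=self.dead)

    def as_series(self) -> pd.Series:
        data = {s: self.stage_count(s) for s in STAGES}
        data[ESKD] = self.eskd
        data[DEAD] = self.dead
        return pd.Series(data)


@dataclass(frozen=True)
class MortalitySchedule:
    """Annual death probabilities: per (stage, class) and for ESKD."""

    probability: np.ndarray          # (stage, class)
    esrd_mortality: float

    def __post_init__(self) -> None:
        p = np.asarray(self.probability, dtype=float)
        object.__setattr__(self, "probability", p)
        if p.shape != (_N_STAGES, _N_CLASSES):
            raise ValueError(f"probability must have shape (4, 3), got {p.shape}")
        if np.any(p < 0) or np.any(p > 1) or not (0 <= self.esrd_mortality <= 1):
            raise ValueError("death probabilities must lie in [0, 1]")


def class_split(dm_prev: float, alb_prev: float) -> dict[str, float]:
    """Progression-class shares from diabetes and albuminuria proportions.

    fast = DM with albuminuria, medium = DM without, slow = no DM; the
    two markers are treated as independent within the stage.
    """
    for name, v in (("dm_prev", dm_prev), ("alb_prev", alb_prev)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    fast = dm_prev * alb_prev
    medium = dm_prev * (1.0 - alb_prev)
    return {"slow": 1.0 - dm_prev, "medium": medium, "fast": fast}


def baseline_death_probability(params: ParameterSet) -> float:
    """Age-weighted general-population annual death probability.

    The per-1000 band rates are averaged with the configured 40+ age
    weights and the resulting rate converted as ``p0 = 1 - exp(-rate)``.
    """
    rate = sum(params.age_weights[b] * params.mortality_by_age[b]
               for b in params.age_weights) / 1000.0
    return 1.0 - math.exp(-rate)


def mortality_probability(params: ParameterSet, stage: str, dm: bool) -> float:
    """Stage- and diabetes-adjusted annual death probability.

    The hazard ratio acts on the hazard scale: ``p = 1 - (1 - p0)^HR``,
    which for small baseline probability is ~HR * p0 and always stays in
    [0, 1].
    """
    hr = params.mortality_hr[(stage, dm)].mean
    return adjusted_probability(baseline_death_probability(params), hr)


def adjusted_probability(p0: float, hr: float) -> float:
    if hr <= 0:
        raise ValueError(f"hazard ratio must be > 0, got {hr}")
    return 1.0 - (1.0 - p0) ** hr


def build_mortality_schedule(params: ParameterSet,
                             hr_draws: dict[tuple[str, bool], float] | None = None,
                             esrd_mortality: float | None = None
                             ) -> MortalitySchedule:
    """Assemble the (stage, class) death-probability matrix.

    Class encodes diabetes status, so the slow column uses the no-DM
    hazard ratio and medium/fast the DM one.
    """
    p0 = baseline_death_probability(params)
    prob = np.empty((_N_STAGES, _N_CLASSES))
    for i, stage in enumerate(STAGES):
        for j, cls in enumerate(CLASSES):
            dm = cls != "slow"
            hr = (hr_draws[(stage, dm)] if hr_draws is not None
                  else params.mortality_hr[(stage, dm)].mean)
            prob[i, j] = adjusted_probability(p0, hr)
    em = (esrd_mortality if esrd_mortality is not None
          else params.esrd_mortality.mean)
    return MortalitySchedule(probability=prob, esrd_mortality=em)


def incident_inflow(params: ParameterSet, year_index: int,
                    incidence: float | None = None) -> float:
    """Incident stage-3a entrants in a given cycle.

    ``incidence_population * (1 + growth)^year_index * incidence``, the
    incidence being the per-million rate expressed as a proportion.
    """
    if year_index < 0:
        raise ValueError(f"year_index must be >= 0, got {year_index}")
    inc = params.incidence_3a.mean if incidence is None else incidence
    return (params.incidence_population
            * (1.0 + params.adult_growth_rate) ** year_index * inc)


def initialize_stocks(params: ParameterSet,
                      prevalence_scale: dict[str, float] | None = None,
                      dm_prev: float | None = None,
                      alb_prev: dict[str, float] | None = None) -> StageStocks:
    """First-model-year stocks.

    Stage totals come from ``initial_stage_counts`` when configured (the
    calibration anchor), otherwise from prevalence x base population;
    either way they are split across progression classes by the stage's
    diabetes/albuminuria composition.  ``prevalence_scale`` multiplies
    each stage seed (used by the PSA to propagate prevalence draws).
    """
    dm = params.dm_prevalence_ckd.mean if dm_prev is None else dm_prev
    ckd = np.zeros((_N_STAGES, _N_CLASSES))
    for i, stage in enumerate(STAGES):
        if params.initial_stage_counts is not None:
            count = params.initial_stage_counts[stage]
        else:
            count = params.stage_prevalence[stage].mean * params.base_population_40plus
        if prevalence_scale is not None:
            count *= prevalence_scale.get(stage, 1.0)
        alb = (params.albuminuria_by_stage[stage].mean
               if alb_prev is None else alb_prev[stage])
        split = class_split(dm, alb)
        ckd[i] = [count * split[c] for c in CLASSES]
    eskd = params.esrd_initial_count
    return StageStocks(ckd=ckd, eskd=eskd, eskd_dm=eskd * dm, dead=0.0)


def step_cohort(stocks: StageStocks, schedule: pd.DataFrame,
                mortality: MortalitySchedule, inflow_3a: float,
                entrant_split: dict[str, float],
                rrt_uptake: float = 1.0,
                order: str = "mortality_first") -> StageStocks:
    """Advance the cohort by one 1-year cycle.

    Transitions are one-directional and skip no stage; death is absorbing.
    ``entrant_split`` gives the class shares of the incident stage-3a
    inflow.  With ``rrt_uptake < 1`` the complementary share of stage-5
    exits remains in stage 5 instead of starting RRT.
    """
    if inflow_3a < 0:
        raise ValueError(f"inflow must be >= 0, got {inflow_3a}")
    if order not in ("mortality_first", "progression_first"):
        raise ValueError(f"unknown cycle order {order!r}")
    exit_frac = schedule.loc[list(STAGES), list(CLASSES)].to_numpy(dtype=float)
    if np.any(exit_frac < 0) or np.any(exit_frac > 1):
        raise ValueError("exit fractions must lie in [0, 1]")

    ckd = stocks.ckd.copy()
    eskd, eskd_dm, dead = stocks.eskd, stocks.eskd_dm, stocks.dead

    def apply_mortality():
        nonlocal ckd, eskd, eskd_dm, dead
        deaths = ckd * mortality.probability
        eskd_deaths = eskd * mortality.esrd_mortality
        dead += deaths.sum() + eskd_deaths
        ckd = ckd - deaths
        eskd_dm -= eskd_dm * mortality.esrd_mortality
        eskd -= eskd_deaths

    def apply_progression():
        nonlocal ckd, eskd, eskd_dm
        moved = ckd * exit_frac
        ckd = ckd - moved
        ckd[1:] += moved[:-1]
        to_rrt = moved[-1] * rrt_uptake
        ckd[-1] += moved[-1] - to_rrt          # non-uptake stays in stage 5
        eskd += to_rrt.sum()
        eskd_dm += to_rrt[_DM_SLICE].sum()

    if order == "mortality_first":
        apply_mortality()
        apply_progression()
    else:
        apply_progression()
        apply_mortality()
    ckd[0] += inflow_3a * np.array([entrant_split[c] for c in CLASSES])

    new = StageStocks(ckd=ckd, eskd=float(eskd), eskd_dm=float(eskd_dm),
                      dead=float(dead))
    if new.dead + 1e-9 < stocks.dead:
        raise AssertionError("absorbing state decreased")   # pragma: no cover
    return new


@dataclass
class ProjectionResult:
    """Year-indexed stage counts and costs of one scenario run."""

    scenario: str
    start_year: int
    stocks: list[StageStocks]
    counts: pd.DataFrame             # index calendar year, columns states + totals
    costs: pd.DataFrame | None = None        # filled by costing.project_costs
    cost_totals: pd.DataFrame | None = None

    @property
    def years(self) -> list[int]:
        return list(self.counts.index)

    def counts_tidy(self) -> pd.DataFrame:
        """Long-format (year, scenario, state, class, dm, count) table."""
        rows = []
        for t, st in enumerate(self.stocks):
            year = self.start_year + t
            for i, stage in enumerate(STAGES):
                for j, cls in enumerate(CLASSES):
                    rows.append((year, self.scenario, stage, cls,
                                 cls != "slow", st.ckd[i, j]))
            rows.append((year, self.scenario, ESKD, "", True, st.eskd_dm))
            rows.append((year, self.scenario, ESKD, "", False,
                         st.eskd - st.eskd_dm))
            rows.append((year, self.scenario, DEAD, "", False, st.dead))
        return pd.DataFrame(rows, columns=["year", "scenario", "state",
                                           "class", "dm", "count"])


def run_projection(params: ParameterSet, costs: CostTable | None = None,
                   scenario=None, horizon: int | None = None,
                   draws=None) -> ProjectionResult:
    """Project the cohort for ``horizon`` one-year cycles.

    Records the start-of-year stocks for year indices 0..horizon (so a
    20-cycle run yields 21 calendar years) and, when a cost table is
    supplied, attaches yearly undiscounted and discounted costs.

    ``scenario`` is a :class:`ckdflow.scenarios.ScenarioSpec`; ``None``
    means baseline.  ``draws`` is the PSA hook: a
    :class:`ckdflow.psa.ParameterDraws` carrying sampled values that
    override the parameter means.
    """
    from . import costing as _costing          # deferred: avoids cycle
    from .scenarios import ScenarioSpec, apply_scenario, baseline_scenario

    if horizon is None:
        horizon = params.horizon_years
    if horizon < 1:
        raise ValueError(f"horizon must be >= 1, got {horizon}")
    if scenario is None:
        scenario = baseline_scenario()

    d = draws
    fit = EgfrDensityFit(intercept=params.egfr_intercept, slope=params.egfr_slope)
    schedule = build_transition_schedule(fit, params.decline_rates)
    schedule = apply_scenario(schedule, scenario, hr_scale=params.hr_scale,
                              hr_draws=None if d is None else d.scenario_hr)
    mortality = build_mortality_schedule(
        params,
        hr_draws=None if d is None else d.mortality_hr,
        esrd_mortality=None if d is None else d.esrd_mortality,
    )
    dm_prev = params.dm_prevalence_ckd.mean if d is None else d.dm_prevalence
    alb = ({s: params.albuminuria_by_stage[s].mean for s in STAGES}
           if d is None else d.albuminuria)
    entrant_split = class_split(dm_prev, alb["3a"])
    stocks = initialize_stocks(
        params,
        prevalence_scale=None if d is None else d.prevalence_scale,
        dm_prev=dm_prev, alb_prev=alb,
    )
    incidence = params.incidence_3a.mean if d is None else d.incidence
    trajectory = [stocks]
    for t in range(horizon):
        stocks = step_cohort(
            stocks, schedule, mortality,
            incident_inflow(params, t, incidence=incidence),
            entrant_split, rrt_uptake=params.rrt_uptake,
            order=params.cycle_order,
        )
        trajectory.append(stocks)

    years = [params.start_year + t for t in range(horizon + 1)]
    counts = pd.DataFrame([st.as_series() for st in trajectory], index=years)
    counts.index.name = "year"
    counts["total_ckd"] = [st.total_ckd for st in trajectory]
    result = ProjectionResult(scenario=scenario.name, start_year=params.start_year,
                              stocks=trajectory, counts=counts)
    if costs is not None:
        table = costs if d is None else d.cost_table(costs)
        spec = scenario if d is None else d.scenario_with_costs(scenario)
        result.costs, result.cost_totals = _costing.project_costs(
            trajectory, years, table, spec, params.discount_rate
        )
    return result
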